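# fnirsnet

Task-state cortical motor-network analysis for functional near-infrared
spectroscopy (fNIRS), built for studies that compare activation and
graph-theoretic connectivity between stroke patients (left- vs
right-hemisphere lesions) and healthy controls during a block-design hand
grasping task.  The package takes raw dual-wavelength (730/850 nm) optical
intensities from a 29-channel montage over SMA, premotor and primary
sensorimotor cortex and produces, per subject and group:

- denoised oxyhaemoglobin (HbO) series via optical density, a 0.01–0.20 Hz
  zero-phase band-pass, three-pass spline motion-artifact correction, and
  the modified Beer–Lambert law;
- channel-wise GLM activation maps (task boxcar ⊗ canonical HRF; group-level
  one-sample t-tests with Benjamini–Hochberg FDR) and the SM1 lateralization
  index LI = (Right − Left)/(Right + Left), categorised as bilateral
  (|LI| ≤ 0.1), hemisphere-dominant (0.1 < |LI| < 0.2) or
  hemisphere-lateralized (|LI| ≥ 0.2);
- a 29 × 29 task-block functional-connectivity matrix: Pearson correlations
  within each 20 s task block, averaged over the five blocks, then Fisher
  z-transformed;
- proportionally thresholded weighted graphs at nine sparsities (10–50%,
  step 5%) with four indicators — average weighted clustering coefficient
  C = (1/N) Σᵢ Σ_{j,k} (w_ij w_jk w_ki)^{1/3} / (k_i(k_i−1)), global
  efficiency E = (1/N(N−1)) Σ_{i≠j} d_ij⁻¹ on reciprocal-weight path
  lengths, inter-hemispheric density K-inter (13 × 13 midline-free node
  sets) and intra-hemispheric density K-intra (16-node sets) — each
  summarised by its area under the curve (AUC) over the sparsity range;
- group statistics: screened t / Kruskal–Wallis / chi-square / Fisher
  comparisons, Spearman correlation of AUCs with Fugl-Meyer scores (FMA-UL,
  FMA-hand), and a smooth-curve + segmented-regression threshold-effect
  analysis that locates breakpoints in the AUC–FMA relationship.

Because clinical recordings of this kind are rarely shareable, the package
includes a first-class synthetic-cohort generator (`fnirsnet.synth`) that
emulates the full acquisition — HRF-convolved responses with a configurable
hemispheric split, correlated physiological noise shaped to a ground-truth
connectivity matrix, cardiac/respiratory/drift components, motion artifacts,
and the exact inverse optical conversion — with every generating parameter
serialised, so each pipeline stage is testable against known truth.

## Worked example

```
fnirsnet simulate --config cfg.yaml --out cohort/   # cfg: n_per_group: 3, seed: 5
fnirsnet analyze cohort/ --config cfg.yaml --out results/
fnirsnet report results/
```

prints (seed 5, three subjects per group):

```
Network AUC summaries, group mean +/- SD:
  C          HS: 0.3111 +/- 0.0112 | LHS: 0.3582 +/- 0.0527 | RHS: 0.2910 +/- 0.0245
  E          HS: 0.2609 +/- 0.0090 | LHS: 0.2858 +/- 0.0360 | RHS: 0.2503 +/- 0.0211
  K-inter    HS: 0.0636 +/- 0.0355 | LHS: 0.0915 +/- 0.0205 | RHS: 0.0739 +/- 0.0228
  K-intra.L  HS: 0.1702 +/- 0.0342 | LHS: 0.1168 +/- 0.0401 | RHS: 0.1419 +/- 0.0485
  K-intra.R  HS: 0.1502 +/- 0.0306 | LHS: 0.1637 +/- 0.0704 | RHS: 0.1634 +/- 0.0166

Lateralization index, group/hand mean +/- SD:
  HS-L: +0.613 +/- nan (hemisphere-lateralized)
  HS-R: +0.143 +/- 0.074 (bilateral)
  LHS-R: +0.037 +/- 0.008 (bilateral)
  RHS-L: -0.010 +/- 0.097 (bilateral)
```

Each AUC row is one network indicator integrated over the 10–50% sparsity
range (a constant indicator v would read 0.40·v); here the synthetic LHS
scenario was configured with raised inter-hemispheric coupling and lowered
left-hemisphere intra coupling, and both show up in the K-inter / K-intra.L
columns.  Patient LIs near zero are categorised bilateral, while the healthy
left-hand task is right-lateralized, as configured.  `results/` also holds
per-subject FC matrices, metric curves, activation maps per group and hand,
AUC comparisons, FMA correlations and threshold-effect fits, all as
channel-labelled CSV/JSON with a provenance manifest.

The same stages are importable as a library (`fnirsnet.preprocess`,
`fnirsnet.activation`, `fnirsnet.connectivity`, `fnirsnet.network`,
`fnirsnet.stats`) and operate on plain numpy arrays and pandas frames.

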