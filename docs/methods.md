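# Methods

`fnirsnet` implements a task-state fNIRS motor-network analysis for a
29-channel montage over the sensorimotor cortices, together with a
synthetic-cohort generator that provides ground truth for every stage.  This
note records the models, parameter choices and numerical decisions, and what
the synthetic validation does and does not establish about real recordings.

## Montage and node sets

The montage covers three regions of interest per hemisphere — supplementary
motor area (SMA), premotor cortex (PMC) and primary sensorimotor cortex
(SM1) — with 29 channels formed by 12 sources and 8 detectors at 3 cm
separation (geometry is carried as metadata only).  Channels 1, 2 and 5 are
listed in ROIs of *both* hemispheres; they are treated operationally as
midline channels.  For the inter-hemispheric density the midline is excluded,
leaving disjoint 13-node sets per hemisphere (169 cross pairs); for the
intra-hemispheric density the midline is included in both 16-node sets (120
within pairs each).  This is the only assignment consistent with both printed
set sizes, and it means a midline–midline edge contributes to both
hemispheres' intra-density while never counting toward inter-density.

## Task paradigm and haemodynamics

The block design is 180 s rest followed by five trials of 25 s rest + 20 s
task (cued 1 Hz hand grasping), sampled at 10 Hz — 4050 samples per record.
The task regressor is the task boxcar convolved with a canonical double-gamma
haemodynamic response (positive lobe peaking at 6 s, undershoot at 16 s,
ratio 1/6), peak-normalised to 1.

## Optical model

Concentration changes are expressed in µM.  The modified Beer–Lambert law
uses a standard published extinction tabulation at 730/850 nm (in
mM⁻¹·cm⁻¹: HbO 0.450/1.058, HbR 1.102/0.691), a 3 cm source–detector
separation, and a differential pathlength factor of 6.0 at both wavelengths
(configurable; the instrument convention is not otherwise documented).
`hemo_to_intensity` and the preprocessing conversion are exact algebraic
inverses; the round trip reproduces input concentrations to ~1e-15 µM.

## Synthetic cohort

A simulated subject is

    HbO(t) = a_c · HRF-regressor(t) + band-limited correlated noise
             + cardiac (1 Hz) + respiratory (0.3 Hz) + drift + white noise,

with HbR = −⅓ of the task component plus white noise.  Defaults (µM): task
amplitude 0.4 at SM1, 0.28 elsewhere; correlated background SD 0.15;
cardiac 0.08; respiratory 0.10; drift 0.20; white 0.05.  These were chosen
once as representative of motor-task fNIRS and are not tuned per experiment.

* **Lateralization.**  The SM1 amplitude split realises a requested
  lateralization index: with the shared midline SM1 channel at the base
  amplitude and the five lateral channels per side scaled by 1 ∓ x, the
  ROI-mean LI equals 5x/6, so x = 1.2·LI.  Group scenario targets follow the
  study population (healthy left-hand task 0.436, right-hand 0.138; patients
  near zero).  The printed SDs of 0.002 for two of those group means are not
  emulated (implausible at n = 17 and immaterial to any computation here).
* **Connectivity ground truth.**  `build_target_fc` makes a correlation
  matrix with hemisphere community structure.  Midline channels couple to
  lateral channels at the mean of intra and inter levels: coupling a border
  channel at full intra strength to *both* hemispheres while the hemispheres
  decouple is not positive semidefinite (for 13-node equicorrelated blocks
  feasibility requires |inter| ≤ (1 + 12·intra)/13).  Jitter that breaks
  positive semidefiniteness triggers a nearest-PSD projection (eigenvalue
  clipping + rescaling to unit diagonal), logged loudly only when the block
  combination itself is infeasible.
* The correlated noise is **band-limited to 0.01–0.20 Hz before covariance
  shaping**, so the target structure passes the analysis band-pass
  approximately unchanged.
* **Severity maps** are explicit scenario configuration, not asserted
  biology.  The monotone preset (inter base 0.32, slope 0.004 per FMA-UL
  point) is calibrated so that the K-inter AUC correlates with FMA-UL at
  Spearman r ≈ 0.5 under the default noise; the piecewise preset (vertex
  0.20 at FMA-UL 33, slopes ∓0.015) keeps the inter level inside the regime
  where proportional thresholding is sensitive to cross edges, making the
  breakpoint recoverable at realistic cohort sizes.
* Motion artifacts are 1–3-sample spikes and persistent step shifts injected
  into the optical-density domain at shared positions, scaled by each
  trace's robust SD; positions are logged in the ground truth.
* Healthy subjects perform one task hand each (alternating across subjects)
  by default, giving 51 recordings for a 3 × 17 cohort; `hs_both_hands=True`
  restores the both-hands protocol.

## Preprocessing

Fixed order, logged in the provenance record: intensity → optical density →
0.01–0.20 Hz band-pass → spline motion correction → haemoglobin conversion.

* OD reference I₀ is the full-record mean per channel/wavelength (robust to
  single-sample glitches); the resulting constant OD offset is removed by
  the high-pass.  An explicit reference can be supplied for exact
  round-trip checks.
* The band-pass is a zero-phase (forward–backward) Butterworth of order 3
  per direction, preserving block timing.  Measured response: ≥ 20 dB
  attenuation at 1 Hz, ≤ 1 dB ripple at 0.05 Hz.
* Motion correction runs three successive passes of a MARA-style scheme per
  channel: a moving-SD detector over 2 s windows applied to the *first
  difference* of the trace (differencing targets fast transients and ignores
  smooth haemodynamics) flags samples exceeding 3.5× the global robust
  (MAD-based) SD of increments; each flagged segment is fitted with a cubic
  smoothing spline whose smoothing level comes from the noise of the
  neighbouring clean data (so the spline tracks the artifact, not the
  noise), the spline is subtracted, the segment is re-levelled to the
  preceding baseline, and any residual step after the segment is removed.
  Spikes at 10× the signal SD are suppressed below 2× background SD and step
  shifts are re-levelled to within a few percent.  On a clean series the
  stage is the identity.  A consequence of step removal is that channel
  means may shift; all downstream statistics are offset-invariant.
* No channel pruning is performed (a flag exists, default off).

With all noise sources disabled, the recovered HbO correlates with the
generated response — expressed in the analysis passband — at r > 0.999 per
channel.  The passband qualifier matters: the raw generated signal contains
an out-of-band rest-to-task envelope that any 0.01 Hz high-pass removes, so
comparing against unfiltered ground truth conflates filter design with
recovery error.

## Activation and lateralization

Per channel, ordinary least squares of the task-phase HbO (2250 samples)
against the HRF regressor plus a constant (optional linear drift);
t = β/SE(β).  Group maps are one-sample t-tests of the per-subject betas
against zero with Benjamini–Hochberg FDR across the 29 channels (α = 0.05),
computed per group and task hand.  Zero-variance betas are reported at the
smallest representable p with a warning rather than NaN.

LI = (Right − Left)/(Right + Left) over SM1, where each hemisphere's value
is the mean baseline-corrected task-block HbO (baseline: the 5 s preceding
each block); the midline SM1 channel contributes to both sides.  GLM betas
can be used instead via a switch.  Patterns: bilateral (|LI| ≤ 0.1),
hemisphere-dominant (0.1 < |LI| < 0.2), hemisphere-lateralized (|LI| ≥ 0.2);
boundaries are inclusive exactly as stated.  Mixed-sign hemisphere means are
flagged (LI can then leave [−1, 1]); an exactly zero denominator is an
explicit error.  Under default noise the single-subject LI has SD ≈ 0.09 and
a small positive ratio bias (≈ +0.06 at LI 0.44), so recovery checks are run
on group means, which is also how such indices are reported in practice.

## Functional connectivity

Pearson correlations between all channel pairs within each 20 s task block
(200 samples), the five block matrices averaged, then Fisher z = atanh(ρ̄) —
average-then-transform, with transform-then-average available as an option.
ρ̄ = ±1 is clipped to ±(1 − 1e-7) with a warning.  The diagonal is excluded.
atanh is monotone, so edge ranking — and hence proportional thresholding —
is identical on either scale (tested).

A single subject's FC estimate carries substantial finite-sample noise: a
0.01–0.20 Hz band-limited block of 200 samples has roughly 8 effective
degrees of freedom, giving a mean absolute deviation from the generating
matrix of ≈ 0.11–0.15 even for a perfect pipeline.  The recovery contract is
therefore stated at two levels: cohort-mean FC within 0.1 of the target
(isolating systematic pipeline distortion, measured ≈ 0.01) and single
subjects within 0.2.

## Graph metrics

At each sparsity s ∈ {10%, …, 50%} (nine levels) the top round(s·406)
upper-triangle z-values are retained as edge weights (signed ranking,
deterministic (i, j) tie-break).  Negative surviving weights are removed and
counted: the cube-root triple product and reciprocal edge lengths are
undefined for negative weights.  Weights are used raw — no max-normalisation
— so z > 1 weights are legal; consequently C and E are weight-scale
covariant, which is immaterial for the rank-based group statistics.

* Weighted clustering: c_i = Σ_{j,k} (w_ij w_jk w_ki)^{1/3} / (k_i(k_i − 1))
  over ordered neighbour pairs (degree < 2 ⇒ c_i = 0); C is the mean over
  all 29 nodes.  Computed as diag(M³) with M = W^(1/3).
* Global efficiency: E = mean over ordered pairs of 1/d_ij, with d_ij the
  Dijkstra shortest path on lengths 1/w; disconnected pairs contribute 0.
  A direct-edge-only distance reading is available behind a flag for
  sensitivity analysis; the shortest-path reading is the default because
  efficiency is defined through path lengths.
* K-inter: existing edges between the 13-node sets / 169.  K-intra(S):
  existing within-set edges / 120, reported for left and right (patient
  tables map affected/unaffected onto lesion side).

Both indicator families match brute-force reference implementations exactly
(1e-12) on random small graphs, and the AUC over the sparsity grid uses the
trapezoid rule on fractional sparsity (constant curve v ⇒ 0.40·v).

## Group statistics

Continuous baseline variables use a two-sample t-test when both groups pass
Shapiro normality and Levene homogeneity at α = 0.05, otherwise
Kruskal–Wallis; counts use chi-square, or Fisher's exact test when any
expected cell is ≤ 5 (the convention that reproduces the exact test on a
17-vs-17 cohort with a five-subject category).  Screening outcomes are
recorded alongside each result.  AUC comparisons between a patient group and
healthy subjects use the matching task hand.  AUC–FMA association uses
Spearman rank correlation (ties mid-ranked).

The threshold-effect analysis fits a lowess smooth for display and locates
breakpoints by segmented linear regression: continuous piecewise-linear
bases, exhaustive search over observed score values (pairs for two
breakpoints), at least four points per segment, model order (0/1/2
breakpoints) selected by AICc with searched breakpoints counted as
parameters.  An RSS floor tied to the data scale prevents exactly-linear
data from buying spurious breakpoints out of rounding error.  Per-segment
Spearman correlations use [a, b) intervals (last closed); segments with
fewer than three points are reported as undefined rather than fabricated.
Significance is two-sided α = 0.05 throughout with *no* multiplicity
correction across indicators — a deliberate mirror of common practice in
this literature and a documented limitation.

## What the synthetic validation shows — and does not

Passing tests establish that the implementation recovers known structure
through the full optical round trip: mesoscale ordering (intra- vs
inter-hemispheric density) from community-structured covariance, the sign of
a configured severity–connectivity relationship at n = 17 (≥ 90% of
replicates), a V-shaped threshold effect's breakpoint within ±8 FMA-UL
points at n = 40 (≥ 80%), and nominal type-I error (5% ± 2%) of the GLM
channel test and the AUC comparison under null simulation.  The generator
does not emulate optode-scalp coupling variation, superficial-layer
physiology, short-separation channels, non-stationary artifacts, or lesion
anatomy; real-data performance of the motion correction and the FC
estimator is therefore not certified by these tests, only their algorithmic
correctness and calibration under the stated model.

## Problem sizes

Default study conditions are used everywhere: 4050-sample recordings,
three 17-subject groups (51 recordings).  The recovery experiments use 50
replicate cohorts (17/group for the sign recovery, 40/group for the
breakpoint recovery, 3-subject cohorts for the ordering check) and 1000
replicates for the calibration checks; these sizes make the full acceptance
run complete in a few minutes on one CPU while keeping Monte-Carlo error
well inside the asserted margins.
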