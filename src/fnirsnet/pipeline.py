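"""Orchestration: simulate -> preprocess -> analyze -> report.

Every run serialises its configuration (and a hash of it) next to its
outputs, so a completed run can be re-executed identically; re-running
``run_analyze`` on an unchanged cohort/config reuses the cached results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activation import build_design, fit_channel_glm, group_activation, \
    lateralization_index
from .connectivity import subject_fc
from .io import read_recording_csv, write_fc_matrix, write_ground_truth, \
    write_recording_csv
from .montage import default_montage, load_montage
from .network import DEFAULT_SPARSITIES, INDICATORS, auc, sparsity_sweep
from .paradigm import make_paradigm
from .preprocess import preprocess_recording
from .stats import compare_auc, compare_baseline, fit_threshold_effect, \
    segment_correlations, spearman_with_fma
from .synth import ArtifactSpec, NoiseSpec, monotone_inter_map, \
    piecewise_inter_map, simulate_cohort

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "montage": None,               # path; None -> bundled default
    "seed": 0,
    "simulate": {
        "n_per_group": 17,
        "hs_both_hands": False,
        "severity_map": None,      # None | "monotone_inter" | "piecewise_inter"
        "artifacts": {"n_spikes": 0, "n_shifts": 0, "magnitude": 5.0},
        "paradigm": {},
    },
    "preprocess": {
        "low": 0.01, "high": 0.20, "filter_order": 3,
        "window_s": 2.0, "sd_threshold": 3.5, "passes": 3,
        "motion_correction": True,
    },
    "network": {
        "sparsities": [round(s, 2) for s in DEFAULT_SPARSITIES],
        "rank_by": "signed",
        "distance": "shortest_path",
        "fc_order": "average_then_z",
    },
    "stats": {"alpha": 0.05, "max_breakpoints": 2},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (v.copy() if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | dict | None = None) -> dict:
    """Merge a YAML config file (or dict) over the package defaults."""
    if path is None:
        return _merge(DEFAULT_CONFIG, {})
    if isinstance(path, dict):
        return _merge(DEFAULT_CONFIG, path)
    import yaml
    with open(path) as fh:
        return _merge(DEFAULT_CONFIG, yaml.safe_load(fh) or {})


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _severity_map(name: str | None):
    if name is None:
        return None
    if name == "monotone_inter":
        return monotone_inter_map()
    if name == "piecewise_inter":
        return piecewise_inter_map()
    raise ValueError(f"unknown severity map preset {name!r}")


def _montage(config: dict):
    return load_montage(config["montage"]) if config["montage"] else default_montage()


def run_simulate(config: dict, out_dir: str | Path) -> Path:
    """Generate a cohort and write recordings, ground truth and metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config["simulate"]
    montage = _montage(config)
    logger.info("simulating cohort: %s per group, seed=%s",
                sim["n_per_group"], config["seed"])
    subjects, records = simulate_cohort(
        n_per_group=sim["n_per_group"],
        severity_metric_map=_severity_map(sim.get("severity_map")),
        seed=config["seed"],
        paradigm=make_paradigm(**sim.get("paradigm", {})),
        artifacts=ArtifactSpec(**sim.get("artifacts", {})),
        hs_both_hands=sim.get("hs_both_hands", False),
        montage=montage,
    )
    for i, (rec, truth) in enumerate(subjects):
        stem = f"{rec.meta['subject_id']}_{rec.meta['task_hand']}"
        write_recording_csv(rec, out / f"{stem}.csv")
        write_ground_truth(truth, out / f"{stem}_truth.json")
    records.to_csv(out / "metadata.csv", index=False)
    (out / "config.json").write_text(json.dumps(
        {"config": config, "hash": config_hash(config),
         "n_recordings": len(subjects)}, indent=1, default=str))
    logger.info("wrote %d recordings to %s", len(subjects), out)
    return out


def _analyze_subject(rec, config: dict, montage, design):
    pp = config["preprocess"]
    hemo = preprocess_recording(rec, **pp)
    fit = fit_channel_glm(hemo, design)
    li = lateralization_index(hemo, montage, rec.meta.get("task_hand", "right"))
    net = config["network"]
    fc = subject_fc(hemo, order=net["fc_order"])
    curve = sparsity_sweep(fc, montage, sparsities=np.asarray(net["sparsities"]),
                           rank_by=net["rank_by"], distance=net["distance"])
    return hemo, fit, li, fc, curve, auc(curve)


def run_analyze(
    cohort_dir: str | Path, config: dict, out_dir: str | Path,
    dry_run: bool = False,
) -> Path:
    """Run preprocess -> activation -> connectivity -> network -> stats."""
    cohort = Path(cohort_dir)
    out = Path(out_dir)
    chash = config_hash(config)
    manifest_path = out / "run_report.json"
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == chash and prev.get("cohort") == str(cohort):
            logger.info("cached results match config hash %s; skipping", chash)
            return out
    stages = ["preprocess", "activation", "connectivity", "network", "group_stats"]
    if dry_run:
        print("dry run; would execute stages:", " -> ".join(stages))
        return out
    out.mkdir(parents=True, exist_ok=True)
    (out / "fc").mkdir(exist_ok=True)
    montage = _montage(config)
    logger.info(
        "analysis decisions: fc_order=%s rank_by=%s distance=%s",
        config["network"]["fc_order"], config["network"]["rank_by"],
        config["network"]["distance"])

    records = pd.read_csv(cohort / "metadata.csv")
    li_rows, auc_rows, curve_rows, skipped = [], [], [], []
    betas: dict[tuple[str, str], list[np.ndarray]] = {}
    design = None
    for _, row in records.iterrows():
        stem = f"{row.subject_id}_{row.task_hand}"
        try:
            rec = read_recording_csv(cohort / f"{stem}.csv")
            if design is None or rec.paradigm != design.paradigm:
                design = build_design(rec.paradigm)
            _, fit, li, fc, curve, aucs = _analyze_subject(
                rec, config, montage, design)
        except Exception as exc:  # corrupt input: skip, log, keep going
            logger.warning("skipping %s: %s", stem, exc)
            skipped.append({"subject": stem, "reason": str(exc)})
            continue
        write_fc_matrix(fc.z, out / "fc" / f"{stem}_fc.csv")
        betas.setdefault((row.group, row.task_hand), []).append(fit.beta_task)
        li_rows.append({"subject_id": row.subject_id, "group": row.group,
                        "task_hand": row.task_hand, "li": li.li,
                        "pattern": li.pattern, "flagged": li.flagged})
        auc_rows.append({"subject_id": row.subject_id, "group": row.group,
                         "task_hand": row.task_hand, "fma_ul": row.fma_ul,
                         "fma_hand": row.fma_hand, **aucs})
        for ind, vals in curve.values.items():
            for s, v in zip(curve.sparsities, vals):
                curve_rows.append({"subject_id": row.subject_id,
                                   "group": row.group, "indicator": ind,
                                   "sparsity": s, "value": v})

    li_df = pd.DataFrame(li_rows)
    auc_df = pd.DataFrame(auc_rows)
    pd.DataFrame(curve_rows).to_csv(out / "metric_curves.csv", index=False)
    li_df.to_csv(out / "lateralization.csv", index=False)
    auc_df.to_csv(out / "network_auc.csv", index=False)

    alpha = config["stats"]["alpha"]
    for (grp, hand), blist in betas.items():
        if len(blist) >= 2:
            gmap = group_activation(np.asarray(blist), alpha=alpha)
            gmap.to_csv(out / f"activation_{grp}_{hand}.csv", index=False)

    baseline = compare_baseline(records)
    baseline.to_csv(out / "baseline_comparison.csv", index=False)

    comp_rows = []
    hand_of = {"LHS": "right", "RHS": "left"}
    for grp, hand in hand_of.items():
        pat = auc_df[auc_df.group == grp]
        hs = auc_df[(auc_df.group == "HS") & (auc_df.task_hand == hand)]
        for ind in INDICATORS:
            if len(pat) >= 2 and len(hs) >= 2:
                c = compare_auc(pat[ind].to_numpy(), hs[ind].to_numpy(),
                                indicator=ind, groups=(grp, f"HS-{hand[0].upper()}"))
                comp_rows.append({"indicator": ind, "groups": "/".join(c.groups),
                                  "t": c.statistic, "p": c.p})
    pd.DataFrame(comp_rows).to_csv(out / "auc_comparisons.csv", index=False)

    corr_rows, threshold_results = [], {}
    for grp in ("LHS", "RHS"):
        pat = auc_df[auc_df.group == grp]
        for ind in INDICATORS:
            for score in ("fma_ul", "fma_hand"):
                if len(pat) < 3:
                    continue
                r, p = spearman_with_fma(pat[ind].to_numpy(),
                                         pat[score].to_numpy())
                corr_rows.append({"indicator": ind, "group": grp,
                                  "score": score, "r": r, "p": p})
                if len(pat) >= 8 and score == "fma_ul":
                    fit_te = fit_threshold_effect(
                        pat[ind].to_numpy(), pat[score].to_numpy(),
                        max_breakpoints=config["stats"]["max_breakpoints"],
                        score_name=score)
                    segs = segment_correlations(
                        fit_te, pat[ind].to_numpy(), pat[score].to_numpy())
                    threshold_results[f"{ind}|{grp}|{score}"] = {
                        "breakpoints": fit_te.breakpoints,
                        "slopes": fit_te.slopes,
                        "segments": segs,
                    }
    pd.DataFrame(corr_rows).to_csv(out / "fma_correlations.csv", index=False)
    (out / "threshold_effects.json").write_text(
        json.dumps(threshold_results, indent=1, default=float))

    manifest = {
        "config_hash": chash,
        "config": config,
        "cohort": str(cohort),
        "version": __version__,
        "python": platform.python_version(),
        "n_subjects": int(len(auc_df)),
        "skipped": skipped,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("analysis complete: %d subjects, %d skipped",
                len(auc_df), len(skipped))
    return out


def run_report(results_dir: str | Path, out_dir: str | Path | None = None) -> Path:
    """Human-readable summary (text + figures) of a completed analysis."""
    res = Path(results_dir)
    out = Path(out_dir) if out_dir else res
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    if (res / "run_report.json").exists():
        manifest = json.loads((res / "run_report.json").read_text())
    chash = manifest.get("config_hash", "unknown")

    lines = [f"fnirsnet run report (config hash {chash})", "=" * 46]
    auc_path = res / "network_auc.csv"
    if auc_path.exists():
        auc_df = pd.read_csv(auc_path)
        lines.append("\nNetwork AUC summaries, group mean +/- SD:")
        for ind in INDICATORS:
            if ind not in auc_df.columns:
                continue
            parts = []
            for grp, sub in auc_df.groupby("group"):
                parts.append(f"{grp}: {sub[ind].mean():.4f} +/- {sub[ind].std():.4f}")
            lines.append(f"  {ind:10s} " + " | ".join(parts))
    else:
        lines.append("\n(no network_auc.csv found; partial results)")

    li_path = res / "lateralization.csv"
    if li_path.exists():
        li_df = pd.read_csv(li_path)
        lines.append("\nLateralization index, group/hand mean +/- SD:")
        for (grp, hand), sub in li_df.groupby(["group", "task_hand"]):
            lines.append(f"  {grp}-{hand[0].upper()}: {sub.li.mean():+.3f} "
                         f"+/- {sub.li.std():.3f} "
                         f"({sub.pattern.mode().iat[0]})")

    curves_path = res / "metric_curves.csv"
    if curves_path.exists():
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        curves = pd.read_csv(curves_path)
        fig, axes = plt.subplots(1, len(INDICATORS), figsize=(4 * len(INDICATORS), 3.2))
        for ax, ind in zip(np.atleast_1d(axes), INDICATORS):
            sub = curves[curves.indicator == ind]
            for grp, g in sub.groupby("group"):
                m = g.groupby("sparsity")["value"].agg(["mean", "std"])
                ax.errorbar(m.index, m["mean"], yerr=m["std"], label=grp,
                            capsize=2)
            ax.set_title(ind)
            ax.set_xlabel("sparsity")
            ax.legend(fontsize=7)
        fig.suptitle(f"metric curves (config {chash})")
        fig.tight_layout()
        fig.savefig(out / "metric_curves.png", dpi=120)
        plt.close(fig)
        lines.append(f"\nfigure: {out / 'metric_curves.png'}")

    text = "\n".join(lines) + "\n"
    (out / "summary.txt").write_text(text)
    print(text)
    return out / "summary.txt"
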