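"""Channel-wise GLM activation mapping and the SM1 lateralization index.

The GLM is fitted over the task-phase samples of each subject's HbO series
against an HRF-convolved block regressor; group maps come from one-sample
t-tests on the per-subject task betas with Benjamini-Hochberg FDR correction
across the 29 channels.  The lateralization index

    LI = (Right - Left) / (Right + Left)

uses the mean baseline-corrected task-block HbO over each hemisphere's SM1
channels: +1 means purely right-hemisphere activation, -1 purely left.
Patterns: bilateral (|LI| <= 0.1), hemisphere dominant (0.1 < |LI| < 0.2),
hemisphere lateralized (|LI| >= 0.2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st
from statsmodels.stats.multitest import multipletests

from .hrf import convolve_hrf
from .montage import ProbeMontage
from .paradigm import TaskParadigm
from .preprocess import HemoSeries

PATTERN_BILATERAL = "bilateral"
PATTERN_DOMINANT = "hemisphere-dominant"
PATTERN_LATERALIZED = "hemisphere-lateralized"


@dataclass
class DesignMatrix:
    X: np.ndarray              # task-phase samples x columns
    names: list[str]
    paradigm: TaskParadigm

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


@dataclass
class GLMFit:
    beta_task: np.ndarray      # uM, per channel
    t_value: np.ndarray
    se: np.ndarray
    resid_var: np.ndarray
    dof: int


@dataclass
class LateralizationResult:
    li: float
    pattern: str
    side: str                  # task hand
    left_mean: float = np.nan
    right_mean: float = np.nan
    flagged: bool = False      # mixed-sign hemisphere means (LI may leave [-1,1])


def build_design(
    paradigm: TaskParadigm, drift: bool = False, **hrf_kw
) -> DesignMatrix:
    """Task regressor (boxcar over task blocks convolved with the canonical
    HRF, peak 1) restricted to the task-phase samples, plus a constant and an
    optional linear drift column."""
    reg_full = convolve_hrf(paradigm.task_boxcar(), paradigm.sampling_rate, **hrf_kw)
    start = paradigm.task_phase_start
    reg = reg_full[start:]
    cols = [reg, np.ones_like(reg)]
    names = ["task", "const"]
    if drift:
        cols.append(np.linspace(-1.0, 1.0, reg.size))
        names.append("drift")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(X=X, names=names, paradigm=paradigm)


def fit_channel_glm(hemo: HemoSeries | np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares per channel over the task-phase samples."""
    if isinstance(hemo, HemoSeries):
        start = design.paradigm.task_phase_start
        Y = hemo.hbo[:, start:]
    else:
        Y = np.atleast_2d(np.asarray(hemo, dtype=float))
    X = design.X
    n, p = X.shape
    if Y.shape[1] != n:
        raise ValueError(f"series length {Y.shape[1]} does not match design ({n})")
    dof = n - p
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T                     # channels x p
    resid = Y - beta @ X.T
    resid_var = np.einsum("ct,ct->c", resid, resid) / dof
    se = np.sqrt(np.maximum(resid_var, 0.0) * XtX_inv[0, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[:, 0] / se, np.sign(beta[:, 0]) * np.inf)
    return GLMFit(beta_task=beta[:, 0], t_value=t, se=se,
                  resid_var=resid_var, dof=dof)


def group_activation(
    betas, alpha: float = 0.05, channel_labels=None
) -> pd.DataFrame:
    """One-sample t-test of task betas against 0 per channel, BH-FDR across
    channels.  ``betas``: a subjects x channels array or a list of GLMFit.

    Channels whose betas have zero variance (degenerate but non-zero mean)
    are reported with p set to the smallest positive float, with a warning.
    """
    if not isinstance(betas, np.ndarray):
        betas = np.array([f.beta_task if isinstance(f, GLMFit) else f
                          for f in betas], dtype=float)
    if betas.ndim != 2 or betas.shape[0] < 2:
        raise ValueError("need a subjects x channels array with >= 2 subjects")
    n_sub, n_ch = betas.shape
    t, p = st.ttest_1samp(betas, 0.0, axis=0)
    mean = betas.mean(axis=0)
    zero_var = betas.std(axis=0) == 0
    if np.any(zero_var & (mean != 0)):
        warnings.warn("zero-variance betas in one-sample t-test; p set to the "
                      "smallest representable positive value", stacklevel=2)
        t = np.where(zero_var & (mean != 0), np.sign(mean) * np.inf, t)
        p = np.where(zero_var & (mean != 0), np.finfo(float).tiny, p)
    p = np.where(zero_var & (mean == 0), 1.0, p)
    t = np.where(zero_var & (mean == 0), 0.0, t)
    significant, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    labels = channel_labels if channel_labels is not None else np.arange(1, n_ch + 1)
    return pd.DataFrame({
        "channel": labels, "beta_mean": mean, "t": t, "p": p, "q": q,
        "significant": significant,
    })


def categorize_li(li: float) -> str:
    """Pattern category from |LI|: <=0.1 bilateral, <0.2 dominant, else lateralized."""
    a = abs(li)
    if a <= 0.1:
        return PATTERN_BILATERAL
    if a < 0.2:
        return PATTERN_DOMINANT
    return PATTERN_LATERALIZED


def _roi_task_means(
    hemo: HemoSeries, channels: set[int], baseline_s: float
) -> float:
    """Mean baseline-corrected task-block HbO over the given ROI channels.

    Baseline for each task block = mean over the ``baseline_s`` seconds
    immediately preceding it.
    """
    par = hemo.paradigm
    nb = int(round(baseline_s * par.sampling_rate))
    idx = [c - 1 for c in sorted(channels)]
    vals = []
    for s in par.task_block_slices():
        block = hemo.hbo[idx, s]
        base = hemo.hbo[idx, max(0, s.start - nb):s.start]
        vals.append(block.mean(axis=1) - base.mean(axis=1))
    return float(np.mean(vals))


def lateralization_index(
    hemo: HemoSeries,
    montage: ProbeMontage,
    task_hand: str,
    baseline_s: float = 5.0,
    betas: np.ndarray | None = None,
) -> LateralizationResult:
    """SM1 lateralization index with pattern categorisation.

    By default Right/Left are mean baseline-corrected task-block HbO over the
    right/left SM1 channels (the midline SM1 channel contributes to both);
    pass per-channel GLM ``betas`` to use those instead.
    """
    sm1_l = montage.roi("SM1", "left").channels
    sm1_r = montage.roi("SM1", "right").channels
    if betas is not None:
        betas = np.asarray(betas, dtype=float)
        left = float(np.mean([betas[c - 1] for c in sorted(sm1_l)]))
        right = float(np.mean([betas[c - 1] for c in sorted(sm1_r)]))
    else:
        left = _roi_task_means(hemo, sm1_l, baseline_s)
        right = _roi_task_means(hemo, sm1_r, baseline_s)
    denom = right + left
    if denom == 0:
        raise ZeroDivisionError(
            "LI undefined: Right + Left SM1 activation sums to zero")
    li = (right - left) / denom
    flagged = (left < 0) != (right < 0)
    if flagged:
        warnings.warn(
            f"mixed-sign SM1 hemisphere means (L={left:.3g}, R={right:.3g}); "
            "LI may fall outside [-1, 1]", stacklevel=2)
    return LateralizationResult(li=float(li), pattern=categorize_li(li),
                                side=task_hand, left_mean=left,
                                right_mean=right, flagged=flagged)
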