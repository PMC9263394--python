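"""Canonical double-gamma haemodynamic response function."""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma


def double_gamma_hrf(
    sampling_rate: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Sampled canonical HRF, peak normalised to 1.

    Two gamma densities (shape = delay, unit scale): a positive lobe peaking
    at ``peak_delay`` seconds minus an undershoot peaking at
    ``undershoot_delay`` seconds, weighted by ``ratio``.
    """
    t = np.arange(0.0, duration, 1.0 / sampling_rate)
    # gamma.pdf with shape a and scale 1 peaks at t = a - 1; use a = delay + 1
    h = _gamma.pdf(t, peak_delay + 1.0) - ratio * _gamma.pdf(t, undershoot_delay + 1.0)
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("degenerate HRF parameters (flat response)")
    return h / peak


def convolve_hrf(boxcar: np.ndarray, sampling_rate: float, **hrf_kw) -> np.ndarray:
    """Convolve a task indicator with the canonical HRF; peak normalised to 1.

    The output is truncated to the input length, so late-record responses are
    represented causally (no wrap-around).
    """
    h = double_gamma_hrf(sampling_rate, **hrf_kw)
    reg = np.convolve(boxcar, h)[: boxcar.size]
    peak = np.max(np.abs(reg))
    if peak > 0:
        reg = reg / peak
    return reg
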