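"""Task-block functional connectivity: per-block Pearson correlation between
channels, averaged across the task blocks, then Fisher z-transformed.

The averaging order (mean of the block correlation matrices first, atanh
second) is the package default; ``order="z_then_average"`` offers the more
common alternative convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import HemoSeries

CLIP = 1.0 - 1e-7


@dataclass
class FCMatrix:
    """Symmetric Fisher-z connectivity matrix; diagonal excluded (zeroed)."""

    z: np.ndarray
    n_blocks_used: int
    rho_mean: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.z.shape[0]


def extract_task_blocks(hemo: HemoSeries) -> list[np.ndarray]:
    """The task-block segments (channels x samples each), in trial order."""
    if hemo.paradigm is None:
        raise ValueError("HemoSeries carries no paradigm annotations")
    return [hemo.hbo[:, s] for s in hemo.paradigm.task_block_slices()]


def block_fc(segment: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of one task-block segment."""
    segment = np.asarray(segment, dtype=float)
    if segment.shape[1] < 3:
        raise ValueError("segment must have at least 3 samples")
    sd = segment.std(axis=1)
    scale = np.maximum(np.abs(segment).max(axis=1), 1.0)
    dead = np.flatnonzero(sd <= 1e-12 * scale)
    if dead.size:
        raise ValueError(f"zero-variance channel {dead[0] + 1} in task block")
    return np.corrcoef(segment)


def fisher_z_average(
    block_matrices: list[np.ndarray], order: str = "average_then_z"
) -> FCMatrix:
    """Combine per-block correlation matrices into one Fisher-z matrix.

    ``average_then_z`` (default): mean correlation across blocks, then atanh.
    ``z_then_average``: atanh per block, then mean.  Correlations of exactly
    +/-1 are clipped to +/-(1 - 1e-7) with a warning before atanh.
    """
    if not block_matrices:
        raise ValueError("need at least one block matrix")
    mats = np.asarray(block_matrices, dtype=float)

    def _z(r: np.ndarray) -> np.ndarray:
        if np.any(np.abs(r) >= 1.0 - np.finfo(float).eps):
            off = ~np.eye(r.shape[-1], dtype=bool)
            if np.any(np.abs(r[..., off]) >= 1.0 - np.finfo(float).eps):
                warnings.warn("correlation of +/-1 clipped before Fisher "
                              "transform", stacklevel=3)
        return np.arctanh(np.clip(r, -CLIP, CLIP))

    if order == "average_then_z":
        rho = mats.mean(axis=0)
        z = _z(rho)
    elif order == "z_then_average":
        z = _z(mats).mean(axis=0)
        rho = np.tanh(z)
    else:
        raise ValueError(f"unknown averaging order {order!r}")
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    np.fill_diagonal(rho, 1.0)
    return FCMatrix(z=z, n_blocks_used=len(block_matrices), rho_mean=rho)


def subject_fc(hemo: HemoSeries, order: str = "average_then_z") -> FCMatrix:
    """Convenience: task-block extraction -> per-block Pearson -> Fisher z."""
    return fisher_z_average([block_fc(seg) for seg in extract_task_blocks(hemo)],
                            order=order)
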