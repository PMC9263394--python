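"""Block task paradigm: 180 s rest, then trials of 25 s rest + 20 s task.

All timing is expressed in seconds and converted to sample indices at the
recording's sampling rate (10 Hz by default).  Sample index arithmetic is the
single source of truth for which samples are "task" downstream (GLM design,
task-block connectivity, LI baselines).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass(frozen=True)
class TaskParadigm:
    sampling_rate: float = 10.0
    rest_duration: float = 180.0
    n_trials: int = 5
    rest_block: float = 25.0
    task_block: float = 20.0
    grasp_rate: float = 1.0  # metadata only (cued grasp pace, Hz)

    @property
    def trial_duration(self) -> float:
        return self.rest_block + self.task_block

    @property
    def total_duration(self) -> float:
        return self.rest_duration + self.n_trials * self.trial_duration

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sampling_rate))

    @property
    def task_phase_start(self) -> int:
        """First sample of the trial (task-phase) portion of the record."""
        return int(round(self.rest_duration * self.sampling_rate))

    def task_block_slices(self) -> list[slice]:
        """Sample slices of the task blocks, in trial order, non-overlapping."""
        fs = self.sampling_rate
        out = []
        for trial in range(self.n_trials):
            start_s = self.rest_duration + trial * self.trial_duration + self.rest_block
            a = int(round(start_s * fs))
            b = a + int(round(self.task_block * fs))
            out.append(slice(a, b))
        return out

    def task_boxcar(self) -> np.ndarray:
        """0/1 indicator of task blocks over the full record."""
        box = np.zeros(self.n_samples)
        for s in self.task_block_slices():
            box[s] = 1.0
        return box

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def to_dict(self) -> dict:
        return asdict(self)


def make_paradigm(**overrides) -> TaskParadigm:
    """Construct a validated paradigm; defaults give 4050 samples at 10 Hz."""
    p = TaskParadigm(**overrides)
    for name in ("sampling_rate", "rest_duration", "rest_block", "task_block"):
        if getattr(p, name) <= 0:
            raise ValueError(f"{name} must be > 0, got {getattr(p, name)}")
    if p.n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {p.n_trials}")
    return p
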