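"""Probe montage: channel / ROI / hemisphere bookkeeping.

The analyses in this package treat fNIRS channels as graph nodes.  A montage
records which channels belong to which region of interest (SMA, PMC, SM1 in
each hemisphere) and, derived from that, which channels sit on the midline
(listed in a left *and* a right ROI).  Midline channels are excluded from the
inter-hemispheric density node sets (13 nodes per hemisphere) and included in
both intra-hemispheric sets (16 nodes per hemisphere).

Channel indices are 1-based at every public interface.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

ROI_NAMES = ("SMA", "PMC", "SM1")
HEMISPHERES = ("left", "right")


class MontageError(ValueError):
    """Raised when a montage configuration violates its invariants."""


@dataclass(frozen=True)
class Channel:
    """A single source-detector channel, 1-based index as printed."""

    index: int
    source_id: int | None = None
    detector_id: int | None = None


@dataclass(frozen=True)
class RegionOfInterest:
    name: str  # SMA | PMC | SM1
    hemisphere: str  # left | right
    channels: frozenset[int]

    @property
    def key(self) -> str:
        return f"{self.name}_{self.hemisphere}"


@dataclass(frozen=True)
class ProbeMontage:
    """Validated channel/ROI/hemisphere map.

    ``meta`` carries optode geometry (separation, anchor point) as metadata
    only; no positional computation is ever performed on it.
    """

    channels: tuple[Channel, ...]
    rois: tuple[RegionOfInterest, ...]
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_indices(self) -> frozenset[int]:
        return frozenset(c.index for c in self.channels)

    def roi(self, name: str, hemisphere: str) -> RegionOfInterest:
        for r in self.rois:
            if r.name == name and r.hemisphere == hemisphere:
                return r
        raise KeyError(f"no ROI {name}_{hemisphere} in montage")

    def hemisphere_union(self, hemisphere: str) -> frozenset[int]:
        """All channels listed in any ROI of the given hemisphere."""
        out: set[int] = set()
        for r in self.rois:
            if r.hemisphere == hemisphere:
                out |= r.channels
        return frozenset(out)

    @property
    def midline(self) -> frozenset[int]:
        """Channels appearing in a left AND a right ROI."""
        return self.hemisphere_union("left") & self.hemisphere_union("right")


def _validate(channels: tuple[Channel, ...], rois: tuple[RegionOfInterest, ...]) -> None:
    n = len(channels)
    indices = [c.index for c in channels]
    seen: set[int] = set()
    for idx in indices:
        if idx in seen:
            raise MontageError(f"duplicate channel index {idx}")
        seen.add(idx)
    valid = set(indices)
    union: set[int] = set()
    for r in rois:
        if r.hemisphere not in HEMISPHERES:
            raise MontageError(f"ROI '{r.key}': unknown hemisphere {r.hemisphere!r}")
        for ch in sorted(r.channels):
            if ch not in valid:
                raise MontageError(
                    f"ROI '{r.key}' channel {ch} outside 1..{n}"
                )
        union |= r.channels
    if union != valid:
        missing = sorted(valid - union)
        raise MontageError(
            f"union covers {len(union)} of {n} channels (missing: {missing})"
        )


def load_montage(config: str | Path | Mapping) -> ProbeMontage:
    """Build and validate a :class:`ProbeMontage`.

    ``config`` is a YAML file path or an equivalent mapping with keys
    ``n_channels`` and ``rois`` (``ROI_hemisphere`` -> list of 1-based channel
    indices).  Raises :class:`MontageError` naming the offending entry when an
    invariant is violated.
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if "channels" in config:
        channels = tuple(
            Channel(index=int(c)) if not isinstance(c, Mapping)
            else Channel(index=int(c["index"]),
                         source_id=c.get("source_id"),
                         detector_id=c.get("detector_id"))
            for c in config["channels"]
        )
        n = int(config.get("n_channels", len(channels)))
    else:
        n = int(config.get("n_channels", 29))
        if n < 1:
            raise MontageError("n_channels must be positive")
        channels = tuple(Channel(index=i) for i in range(1, n + 1))
    rois = []
    for key, chans in config["rois"].items():
        try:
            name, hemi = key.rsplit("_", 1)
        except ValueError:
            raise MontageError(f"ROI key {key!r} must be '<name>_<hemisphere>'")
        rois.append(RegionOfInterest(name=name, hemisphere=hemi,
                                     channels=frozenset(int(c) for c in chans)))
    rois = tuple(rois)
    _validate(channels, rois)
    meta = {k: v for k, v in config.items() if k != "rois"}
    return ProbeMontage(channels=channels, rois=rois, meta=meta)


def default_montage() -> ProbeMontage:
    """The bundled 29-channel motor montage (SMA/PMC/SM1 in each hemisphere)."""
    ref = importlib.resources.files("fnirsnet.data") / "default_montage.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_montage(path)


def hemisphere_node_sets(
    montage: ProbeMontage, mode: str
) -> tuple[frozenset[int], frozenset[int]]:
    """Left/right node sets for the mesoscale density metrics.

    ``mode="inter"`` excludes midline channels from both sets (disjoint sets;
    13 per hemisphere in the default montage), ``mode="intra"`` keeps them in
    both (16 per hemisphere).  Pure function of the montage.
    """
    left = montage.hemisphere_union("left")
    right = montage.hemisphere_union("right")
    if mode == "inter":
        mid = montage.midline
        return left - mid, right - mid
    if mode == "intra":
        return left, right
    raise ValueError(f"mode must be 'inter' or 'intra', got {mode!r}")
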