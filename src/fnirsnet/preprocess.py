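"""Raw intensity -> denoised HbO/HbR concentration series.

Fixed stage order (logged in the provenance record):

1. optical density:  OD(t) = -log10(I(t) / I0), I0 = full-record mean
2. zero-phase band-pass, 0.01-0.20 Hz (Butterworth order 3 per direction)
3. spline motion-artifact correction, three successive passes of a
   moving-SD detect / smoothing-spline subtract / re-level scheme
4. modified Beer-Lambert conversion to (dHbO, dHbR)

Oxyhaemoglobin is the analysis signal downstream; HbR is carried along.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import UnivariateSpline

from .optics import DEFAULT_DPF, DEFAULT_PATHLENGTH_CM, hemo_from_od
from .paradigm import TaskParadigm
from .synth import RawRecording


@dataclass
class OpticalDensitySeries:
    od: np.ndarray  # channels x wavelengths x time, dimensionless
    sampling_rate: float
    wavelengths: tuple[float, float]
    paradigm: TaskParadigm | None = None
    log: dict = field(default_factory=dict)


@dataclass
class HemoSeries:
    """Concentration-change series (uM) with paradigm annotations."""

    hbo: np.ndarray  # channels x time
    hbr: np.ndarray
    sampling_rate: float
    paradigm: TaskParadigm | None = None
    log: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]


def intensity_to_od(
    recording: RawRecording, i0: float | np.ndarray | str = "mean"
) -> OpticalDensitySeries:
    """Convert raw intensities to optical density.

    ``i0``: ``"mean"`` (default) references each channel/wavelength to its
    full-record mean intensity; an explicit scalar/array uses that reference
    instead (exact inverse of the simulator's forward model).
    """
    I = np.asarray(recording.intensity, dtype=float)
    bad = np.argwhere(I <= 0)
    if bad.size:
        ch, wl, t = bad[0]
        raise ValueError(
            f"non-positive intensity at channel {ch + 1}, wavelength "
            f"{recording.wavelengths[wl]:g} nm, sample {t}"
        )
    if isinstance(i0, str):
        if i0 != "mean":
            raise ValueError(f"unknown i0 mode {i0!r}")
        ref = I.mean(axis=-1, keepdims=True)
    else:
        ref = np.asarray(i0, dtype=float)
        if ref.ndim == 2:
            ref = ref[:, :, None]
    od = -np.log10(I / ref)
    return OpticalDensitySeries(
        od=od, sampling_rate=recording.paradigm.sampling_rate,
        wavelengths=recording.wavelengths, paradigm=recording.paradigm,
        log={"i0": "mean" if isinstance(i0, str) else "explicit"},
    )


def bandpass(
    x: np.ndarray,
    sampling_rate: float = 10.0,
    low: float = 0.01,
    high: float = 0.20,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    if not 0 < low < high:
        raise ValueError(f"band edges out of order: ({low}, {high})")
    nyq = sampling_rate / 2.0
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz is not below Nyquist {nyq} Hz")
    sos = sps.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def _moving_sd(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving standard deviation along the last axis, O(n)."""
    n = x.shape[-1]
    pad = w // 2
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    zeros = np.zeros(xp.shape[:-1] + (1,))
    c1 = np.cumsum(np.concatenate([zeros, xp], axis=-1), axis=-1)
    c2 = np.cumsum(np.concatenate([zeros, xp ** 2], axis=-1), axis=-1)
    s1 = c1[..., w:] - c1[..., :-w]
    s2 = c2[..., w:] - c2[..., :-w]
    var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
    return np.sqrt(var)[..., :n]


def _flags_to_segments(flags: np.ndarray, w: int) -> list[tuple[int, int]]:
    """Dilate flagged samples by half a window and merge nearby runs."""
    half = w // 2
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    segments: list[tuple[int, int]] = []
    n = flags.size
    start = max(0, idx[0] - half)
    end = min(n, idx[0] + half + 1)
    for i in idx[1:]:
        a, b = max(0, i - half), min(n, i + half + 1)
        if a <= end + w:
            end = b
        else:
            segments.append((start, end))
            start, end = a, b
    segments.append((start, end))
    return segments


def _detect_flags(x: np.ndarray, fs: float, window_s: float,
                  sd_threshold: float) -> np.ndarray:
    """Flag artifact samples via the moving SD of the first difference.

    Differencing makes the detector sensitive to fast transients (spikes,
    step shifts) while ignoring smooth haemodynamics.  A sample is flagged
    when its local (windowed) SD of increments exceeds ``sd_threshold``
    times the series' global robust SD of increments (MAD-based), i.e. when
    local variability is several-fold the typical variability.
    """
    w = max(3, int(round(window_s * fs)))
    d = np.diff(x, prepend=x[..., :1], axis=-1)
    ms = _moving_sd(d, w)
    med = np.median(d, axis=-1, keepdims=True)
    scale = 1.4826 * np.median(np.abs(d - med), axis=-1, keepdims=True)
    fallback = d.std(axis=-1, keepdims=True)
    scale = np.where(scale > 0, scale, fallback)
    with np.errstate(invalid="ignore"):
        flags = np.where(scale > 0, ms > sd_threshold * scale, False)
    return flags


def _correct_segment(x: np.ndarray, a: int, b: int, w: int) -> None:
    """Subtract a smoothing spline over [a, b), re-level to the left baseline,
    then remove any residual step across the segment (in place).

    The spline's smoothing factor is set from the noise level of the
    *neighbouring* clean data, so the spline tracks the (large) artifact and
    the residual is noise-sized.
    """
    n = x.size
    seg = x[a:b]
    neigh = np.concatenate([x[max(0, a - 2 * w):a], x[b:min(n, b + 2 * w)]])
    if neigh.size >= 4:
        d = np.diff(neigh)
        noise_sd = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
        noise_sd = max(noise_sd, 1e-12)
    else:
        noise_sd = 1e-12
    if a > 0:
        pre = float(np.mean(x[max(0, a - w):a]))
    else:
        pre = float(np.mean(x[b:min(n, b + w)])) if b < n else float(np.mean(seg))
    if seg.size >= 4:
        tt = np.arange(seg.size, dtype=float)
        spl = UnivariateSpline(tt, seg, k=3, s=seg.size * noise_sd ** 2)
        x[a:b] = seg - spl(tt) + pre
    else:
        x[a:b] = pre
    if b < n:
        post = float(np.mean(x[b:min(n, b + w)]))
        x[b:] -= post - pre


def spline_motion_correct(
    series: np.ndarray,
    sampling_rate: float = 10.0,
    window_s: float = 2.0,
    sd_threshold: float = 3.5,
    passes: int = 3,
) -> tuple[np.ndarray, list[list[dict]]]:
    """MARA-style motion-artifact correction, applied channel by channel.

    Each pass detects high-transient segments, subtracts a cubic smoothing
    spline fitted within each segment, re-levels the segment to the
    neighbouring baseline, and removes any residual step so shift artifacts
    do not persist.  A clean series passes through unchanged.  Returns the
    corrected series and a per-pass report of flagged segments.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float)).copy()
    orig_shape = np.asarray(series).shape
    flat = x.reshape(-1, x.shape[-1])
    w = max(3, int(round(window_s * sampling_rate)))
    if w >= flat.shape[-1]:
        raise ValueError("detection window must be shorter than the record")
    report: list[list[dict]] = []
    for p in range(passes):
        found: list[dict] = []
        flags = _detect_flags(flat, sampling_rate, window_s, sd_threshold)
        for row_i in np.flatnonzero(flags.any(axis=-1)):
            row = flat[row_i]
            for a, b in _flags_to_segments(flags[row_i], w):
                _correct_segment(row, a, b, w)
                found.append({"pass": p + 1, "row": int(row_i), "start": int(a),
                              "end": int(b)})
        report.append(found)
        if not found:
            break
    return flat.reshape(x.shape).reshape(orig_shape), report


def od_to_hemoglobin(
    od: OpticalDensitySeries,
    pathlength: float = DEFAULT_PATHLENGTH_CM,
    dpf=DEFAULT_DPF,
    table: dict | None = None,
) -> HemoSeries:
    """Solve the 2x2 modified Beer-Lambert system per channel and sample."""
    hbo, hbr = hemo_from_od(od.od, pathlength=pathlength, dpf=dpf,
                            wavelengths=od.wavelengths, table=table)
    log = dict(od.log)
    log.update({"pathlength_cm": pathlength, "dpf": dpf})
    return HemoSeries(hbo=hbo, hbr=hbr, sampling_rate=od.sampling_rate,
                      paradigm=od.paradigm, log=log)


def preprocess_recording(
    recording: RawRecording,
    low: float = 0.01,
    high: float = 0.20,
    filter_order: int = 3,
    window_s: float = 2.0,
    sd_threshold: float = 3.5,
    passes: int = 3,
    pathlength: float | None = None,
    dpf=None,
    motion_correction: bool = True,
    i0: float | np.ndarray | str = "mean",
) -> HemoSeries:
    """Full preprocessing chain: OD -> band-pass -> spline correction -> MBLL."""
    pathlength = pathlength if pathlength is not None else \
        recording.meta.get("pathlength", DEFAULT_PATHLENGTH_CM)
    dpf = dpf if dpf is not None else recording.meta.get("dpf", DEFAULT_DPF)
    odseries = intensity_to_od(recording, i0=i0)
    fs = odseries.sampling_rate
    od = bandpass(odseries.od, fs, low=low, high=high, order=filter_order)
    motion_report: list = []
    if motion_correction:
        od, motion_report = spline_motion_correct(
            od, fs, window_s=window_s, sd_threshold=sd_threshold, passes=passes)
    odseries.od = od
    hemo = od_to_hemoglobin(odseries, pathlength=pathlength, dpf=dpf)
    hemo.log.update({
        "order": ["intensity_to_od", "bandpass", "spline_motion_correct",
                  "od_to_hemoglobin"],
        "band_hz": [low, high],
        "filter": f"butterworth order {filter_order}, zero-phase (sosfiltfilt)",
        "motion_correction": {
            "enabled": motion_correction, "window_s": window_s,
            "sd_threshold": sd_threshold, "passes": passes,
            "n_segments_per_pass": [len(p) for p in motion_report],
        },
        "channel_pruning": False,
    })
    return hemo
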