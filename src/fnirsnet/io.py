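"""Readers and writers for recordings, metadata and result tables.

Two recording containers are supported:

- a plain CSV dialect (one file per subject: ``time`` column plus one
  ``ch<index>_<wavelength>`` column per channel/wavelength) with a JSON
  paradigm/metadata sidecar, and
- a minimal SNIRF-shaped HDF5 container (``/nirs/data1/dataTimeSeries`` with
  a measurement list, probe wavelengths and stim blocks), written with h5py.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .paradigm import TaskParadigm, make_paradigm
from .synth import GroundTruth, RawRecording


def _column_names(n_channels: int, wavelengths) -> list[str]:
    return [f"ch{c:02d}_{int(w)}" for c in range(1, n_channels + 1)
            for w in wavelengths]


def write_recording_csv(rec: RawRecording, path: str | Path) -> Path:
    """One row per sample: time, then channel x wavelength intensities.
    A ``<stem>.json`` sidecar carries paradigm and subject metadata."""
    path = Path(path)
    n_ch = rec.intensity.shape[0]
    flat = rec.intensity.reshape(n_ch * len(rec.wavelengths), -1).T
    df = pd.DataFrame(flat, columns=_column_names(n_ch, rec.wavelengths))
    df.insert(0, "time", rec.paradigm.times())
    df.to_csv(path, index=False, float_format="%.8g")
    sidecar = {
        "paradigm": rec.paradigm.to_dict(),
        "wavelengths": list(rec.wavelengths),
        "i0": rec.i0 if np.isscalar(rec.i0) else np.asarray(rec.i0).tolist(),
        "meta": {k: v for k, v in rec.meta.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording_csv(path: str | Path) -> RawRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "time"]
    wavelengths = tuple(float(w) for w in sidecar["wavelengths"])
    n_ch = len(cols) // len(wavelengths)
    intensity = df[cols].to_numpy().T.reshape(n_ch, len(wavelengths), -1)
    par = make_paradigm(**sidecar["paradigm"])
    i0 = sidecar.get("i0", 1.0)
    return RawRecording(intensity=intensity, paradigm=par,
                        wavelengths=wavelengths,
                        i0=np.asarray(i0) if not np.isscalar(i0) else i0,
                        meta=sidecar.get("meta", {}))


def write_snirf(rec: RawRecording, path: str | Path) -> Path:
    """Minimal SNIRF-shaped HDF5 container (continuous-wave intensities)."""
    path = Path(path)
    n_ch, n_wl, _ = rec.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        flat = rec.intensity.reshape(n_ch * n_wl, -1).T  # time x measurements
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=rec.paradigm.times())
        m = 0
        for ch in range(n_ch):
            for wl in range(n_wl):
                m += 1
                ml = data.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=ch + 1)
                ml.create_dataset("detectorIndex", data=ch + 1)
                ml.create_dataset("wavelengthIndex", data=wl + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths))
        stim = nirs.create_group("stim1")
        stim.create_dataset("name", data="task")
        slices = rec.paradigm.task_block_slices()
        fs = rec.paradigm.sampling_rate
        stim.create_dataset("data", data=np.array(
            [[s.start / fs, (s.stop - s.start) / fs, 1.0] for s in slices]))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("paradigm", data=json.dumps(rec.paradigm.to_dict()))
        meta.create_dataset("subject", data=json.dumps(
            {k: v for k, v in rec.meta.items()}, default=str))
    return path


def read_snirf(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        flat = np.asarray(data["dataTimeSeries"])
        wavelengths = tuple(np.asarray(f["nirs/probe/wavelengths"]).tolist())
        par = make_paradigm(**json.loads(
            f["nirs/metaDataTags/paradigm"][()].decode()))
        meta = json.loads(f["nirs/metaDataTags/subject"][()].decode())
    n_wl = len(wavelengths)
    n_ch = flat.shape[1] // n_wl
    intensity = flat.T.reshape(n_ch, n_wl, -1)
    return RawRecording(intensity=intensity, paradigm=par,
                        wavelengths=wavelengths, meta=meta)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1))
    return path


def write_fc_matrix(z: np.ndarray, path: str | Path) -> Path:
    """Channel-labelled 29x29 CSV."""
    labels = [f"ch{c:02d}" for c in range(1, z.shape[0] + 1)]
    pd.DataFrame(z, index=labels, columns=labels).to_csv(path)
    return Path(path)


def read_fc_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy()
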