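"""Modified Beer-Lambert law (MBLL) algebra shared by the simulator and the
preprocessing stage.

Conventions
-----------
- Concentration changes (dHbO, dHbR) are in micromolar (uM).
- Extinction coefficients are molar-style, expressed in mM^-1 cm^-1, from a
  standard published tabulation at 730 and 850 nm.
- dOD(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR] / 1000
                * pathlength_cm * DPF(lambda)
  (the /1000 converts uM to mM so units cancel).
- Intensity model: I(t) = I0 * 10**(-dOD(t)).

The forward map (``od_from_hemo``) and inverse (``hemo_from_od``) are exact
algebraic inverses for a non-singular 2x2 extinction system.
"""

from __future__ import annotations

import numpy as np

WAVELENGTHS = (730.0, 850.0)

# eps in mM^-1 cm^-1: {wavelength: (eps_HbO, eps_HbR)}
EXTINCTION_MM_CM: dict[float, tuple[float, float]] = {
    730.0: (0.450, 1.102),
    850.0: (1.058, 0.691),
}

DEFAULT_PATHLENGTH_CM = 3.0
DEFAULT_DPF = 6.0


class SingularExtinctionError(ValueError):
    """The 2x2 extinction system cannot be inverted."""


def extinction_matrix(
    wavelengths=WAVELENGTHS, table: dict | None = None
) -> np.ndarray:
    """Rows = wavelengths, columns = (HbO, HbR); checks invertibility."""
    table = EXTINCTION_MM_CM if table is None else table
    E = np.array([table[float(w)] for w in wavelengths], dtype=float)
    if E.shape != (2, 2):
        raise ValueError("exactly two wavelengths are required")
    if abs(np.linalg.det(E)) < 1e-6 * np.abs(E).max() ** 2:
        raise SingularExtinctionError(
            f"extinction matrix is (near-)singular: {E.tolist()}"
        )
    return E


def _dpf_vector(dpf, n_wl: int = 2) -> np.ndarray:
    v = np.broadcast_to(np.asarray(dpf, dtype=float), (n_wl,)).copy()
    if np.any(v <= 0):
        raise ValueError("DPF must be positive")
    return v


def od_from_hemo(
    hbo: np.ndarray,
    hbr: np.ndarray,
    pathlength: float = DEFAULT_PATHLENGTH_CM,
    dpf=DEFAULT_DPF,
    wavelengths=WAVELENGTHS,
    table: dict | None = None,
) -> np.ndarray:
    """MBLL forward map: (channels, time) uM pair -> (channels, 2, time) dOD."""
    E = extinction_matrix(wavelengths, table)
    dpf_v = _dpf_vector(dpf)
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    conc_mm = np.stack([hbo, hbr], axis=-2) / 1000.0  # (ch, 2, t) in mM
    od = np.einsum("wc,nct->nwt", E, conc_mm) * pathlength
    return od * dpf_v[None, :, None]


def hemo_from_od(
    od: np.ndarray,
    pathlength: float = DEFAULT_PATHLENGTH_CM,
    dpf=DEFAULT_DPF,
    wavelengths=WAVELENGTHS,
    table: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """MBLL inverse: (channels, 2, time) dOD -> (dHbO, dHbR) in uM."""
    E = extinction_matrix(wavelengths, table)
    dpf_v = _dpf_vector(dpf)
    od = np.asarray(od, dtype=float)
    scaled = od / (pathlength * dpf_v[None, :, None])
    Einv = np.linalg.inv(E)
    conc_mm = np.einsum("cw,nwt->nct", Einv, scaled)
    hbo, hbr = conc_mm[:, 0, :] * 1000.0, conc_mm[:, 1, :] * 1000.0
    return hbo, hbr
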