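"""Modified Beer-Lambert law: optical density <-> hemoglobin concentration.

The continuous-wave model per channel and wavelength is

    dOD(lambda) = [eps_HbO2(lambda) * dC_HbO2 + eps_HbR(lambda) * dC_HbR]
                  * d * DPF(lambda)

with dC in mol/L, eps in cm^-1/(mol/L), the source-detector separation d in
cm and the differential pathlength factor DPF dimensionless.  Working units
here are micromolar (uM), so a 1e-6 factor converts eps * uM to cm^-1.
Measuring at two wavelengths gives a 2x2 linear system per sample whose
inversion yields dC_HbO2 and dC_HbR; dC_HbT is their sum by definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

UM_PER_MOLAR = 1e6


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients (cm^-1 / M) by wavelength."""

    wavelengths_nm: tuple[float, ...]
    eps_hbo2: tuple[float, ...]
    eps_hbr: tuple[float, ...]

    def matrix(self, wavelengths: tuple[float, float]) -> np.ndarray:
        """2x2 matrix [[eps_hbo2, eps_hbr]] stacked over the two wavelengths."""
        rows = []
        for wl in wavelengths:
            try:
                i = self.wavelengths_nm.index(float(wl))
            except ValueError as exc:
                raise ValueError(f"no extinction entry for {wl} nm") from exc
            rows.append([self.eps_hbo2[i], self.eps_hbr[i]])
        return np.asarray(rows, dtype=float)


def load_extinction_table(path: str | Path | None = None) -> ExtinctionTable:
    if path is None:
        path = resources.files("nirspipe.data").joinpath("extinction_coefficients.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    return ExtinctionTable(
        wavelengths_nm=tuple(df["wavelength_nm"].astype(float)),
        eps_hbo2=tuple(df["eps_hbo2"].astype(float)),
        eps_hbr=tuple(df["eps_hbr"].astype(float)),
    )


def mbll_system(
    extinction: ExtinctionTable,
    wavelengths: tuple[float, float],
    distance_cm: float,
    dpf: tuple[float, float],
) -> np.ndarray:
    """Per-channel 2x2 system A with dOD = A @ [dHbO2_uM, dHbR_uM]."""
    eps = extinction.matrix(wavelengths)  # (2 wl, 2 species)
    scale = distance_cm * np.asarray(dpf, dtype=float)[:, None] / UM_PER_MOLAR
    return eps * scale


def forward_mbll(
    hbo2_um: np.ndarray,
    hbr_um: np.ndarray,
    distance_cm: float,
    extinction: ExtinctionTable,
    dpf: tuple[float, float] = (6.0, 6.0),
    wavelengths: tuple[float, float] = (690.0, 830.0),
) -> np.ndarray:
    """Concentration changes (uM) -> dOD, shape (2, n_samples).

    This is the simulator's forward model and the exact inverse of
    :func:`invert_mbll`; doubling ``distance_cm`` doubles dOD.
    """
    a = mbll_system(extinction, wavelengths, distance_cm, dpf)
    conc = np.stack([np.asarray(hbo2_um, float), np.asarray(hbr_um, float)])
    return a @ conc


def invert_mbll(
    dod: np.ndarray,
    distance_cm: float,
    extinction: ExtinctionTable,
    dpf: tuple[float, float] = (6.0, 6.0),
    wavelengths: tuple[float, float] = (690.0, 830.0),
    channel_id: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """dOD (2, n_samples) -> (dHbO2, dHbR) in uM."""
    a = mbll_system(extinction, wavelengths, distance_cm, dpf)
    det = np.linalg.det(a)
    if abs(det) < 1e-30:
        which = f" for channel {channel_id}" if channel_id is not None else ""
        raise np.linalg.LinAlgError(f"singular extinction system{which}")
    conc = np.linalg.solve(a, np.asarray(dod, dtype=float))
    return conc[0], conc[1]
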