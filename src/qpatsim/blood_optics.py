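"""Hemoglobin spectral model for dual-wavelength blood oximetry.

Blood absorption in the NIR is a concentration-weighted sum of the molar
extinction of deoxy- (Hb) and oxy-hemoglobin (HbO2),

    mu_a(lambda) = k * (eps_Hb(lambda) * C_Hb + eps_HbO2(lambda) * C_HbO2),

and the oxygen saturation is SO2 = C_HbO2 / (C_Hb + C_HbO2).  Measuring
mu_a at two wavelengths where the two chromophores differ spectrally turns
oximetry into a 2x2 linear inversion.  The packaged default extinction
coefficients are the values used for alexandrite (755 nm) and Nd:YAG
(1064 nm) illumination.

The scalar ``k`` is ln(10) when extinction coefficients follow the decadic
convention and 1 otherwise; sources rarely state which applies, so the flag
is explicit.  SO2 estimates are invariant to any scalar common to both
wavelengths, so the choice only affects absolute mu_a values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ExtinctionTable",
    "BloodState",
    "mu_a_blood",
    "invert_concentrations",
    "so2_of",
    "NO_BLOOD",
]

#: Sentinel returned by :func:`so2_of` when both concentrations are zero.
NO_BLOOD = float("nan")


def _default_extinction_rows() -> pd.DataFrame:
    with (resources.files("qpatsim") / "data" / "extinction_nir.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients (cm^-1/M) per wavelength.

    Parameters
    ----------
    eps_hb, eps_hbo2
        Mappings from wavelength in nm to the extinction coefficient of
        deoxy- and oxy-hemoglobin.
    ln10_convention
        If True, absorption is computed as ``ln(10) * eps * C`` (decadic
        extinction coefficients); if False, ``eps * C``.
    """

    eps_hb: dict[int, float]
    eps_hbo2: dict[int, float]
    ln10_convention: bool = False

    def __post_init__(self) -> None:
        for table in (self.eps_hb, self.eps_hbo2):
            for wl, eps in table.items():
                if eps <= 0:
                    raise ValueError(f"extinction coefficient at {wl} nm must be > 0")
        if set(self.eps_hb) != set(self.eps_hbo2):
            raise ValueError("eps_hb and eps_hbo2 must cover the same wavelengths")

    @property
    def scale(self) -> float:
        return math.log(10.0) if self.ln10_convention else 1.0

    @property
    def wavelengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.eps_hb))

    def matrix(self, wavelengths: tuple[int, int]) -> np.ndarray:
        """2x2 system matrix mapping (C_Hb, C_HbO2) to mu_a at two wavelengths."""
        return self.scale * np.array(
            [[self.eps_hb[wl], self.eps_hbo2[wl]] for wl in wavelengths], dtype=float
        )

    @classmethod
    def default(cls, ln10_convention: bool = False) -> "ExtinctionTable":
        """Packaged 755/1064 nm coefficients."""
        rows = _default_extinction_rows()
        return cls(
            eps_hb={int(r.wavelength_nm): float(r.eps_hb) for r in rows.itertuples()},
            eps_hbo2={int(r.wavelength_nm): float(r.eps_hbo2) for r in rows.itertuples()},
            ln10_convention=ln10_convention,
        )

    @classmethod
    def from_csv(cls, path, ln10_convention: bool = False) -> "ExtinctionTable":
        """Read columns wavelength_nm, eps_hb, eps_hbo2 from a CSV file."""
        rows = pd.read_csv(path)
        return cls(
            eps_hb={int(r.wavelength_nm): float(r.eps_hb) for r in rows.itertuples()},
            eps_hbo2={int(r.wavelength_nm): float(r.eps_hbo2) for r in rows.itertuples()},
            ln10_convention=ln10_convention,
        )


@dataclass(frozen=True)
class BloodState:
    """Oxygenation state of whole blood.

    ``so2`` is a fraction in [0, 1]; ``c_thb`` the total hemoglobin molar
    concentration in M.  The individual concentrations follow as
    ``c_hbo2 = so2 * c_thb`` and ``c_hb = (1 - so2) * c_thb``.
    """

    so2: float
    c_thb: float = 2.0e-3

    def __post_init__(self) -> None:
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError("so2 must be a fraction in [0, 1]")
        if self.c_thb < 0:
            raise ValueError("c_thb must be >= 0")

    @property
    def c_hb(self) -> float:
        return (1.0 - self.so2) * self.c_thb

    @property
    def c_hbo2(self) -> float:
        return self.so2 * self.c_thb


def mu_a_blood(state: BloodState, wavelength: int, table: ExtinctionTable) -> float:
    """Blood absorption coefficient (cm^-1) at one wavelength."""
    if wavelength not in table.eps_hb:
        raise KeyError(f"wavelength {wavelength} nm not in extinction table")
    if state.c_hb < 0 or state.c_hbo2 < 0:
        raise ValueError("negative hemoglobin concentration")
    return table.scale * (
        table.eps_hb[wavelength] * state.c_hb + table.eps_hbo2[wavelength] * state.c_hbo2
    )


def invert_concentrations(
    mu_a_755: float,
    mu_a_1064: float,
    table: ExtinctionTable,
    wavelengths: tuple[int, int] = (755, 1064),
) -> tuple[float, float]:
    """Unmix two absorption measurements into (C_Hb, C_HbO2) in M.

    The exact solution of the 2x2 linear system; negative solutions are
    returned as-is (callers flag them) rather than clipped, since clipping
    would bias downstream region averages.
    """
    mat = table.matrix(wavelengths)
    det = mat[0, 0] * mat[1, 1] - mat[0, 1] * mat[1, 0]
    if det == 0:
        raise np.linalg.LinAlgError("extinction matrix is singular")
    c_hb = (mat[1, 1] * mu_a_755 - mat[0, 1] * mu_a_1064) / det
    c_hbo2 = (mat[0, 0] * mu_a_1064 - mat[1, 0] * mu_a_755) / det
    return c_hb, c_hbo2


def so2_of(c_hb, c_hbo2):
    """Oxygen saturation in percent, 100 * C_HbO2 / (C_Hb + C_HbO2).

    Scalar inputs with zero total concentration return the :data:`NO_BLOOD`
    NaN sentinel (never a silent 0).  Array inputs are handled elementwise.
    """
    c_hb = np.asarray(c_hb, dtype=float)
    c_hbo2 = np.asarray(c_hbo2, dtype=float)
    total = c_hb + c_hbo2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total != 0, 100.0 * c_hbo2 / np.where(total != 0, total, 1.0), NO_BLOOD)
    if out.ndim == 0:
        return float(out)
    return out
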