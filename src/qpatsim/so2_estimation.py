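"""Blood SO2 recovery from dual-wavelength pressure volumes.

Three fluence-compensation approaches are compared:

* ``NONE`` — the raw pressures are treated as absorption (Phi = 1);
* ``HOMOGENEOUS`` — pressures divided by a fluence map simulated on the
  homogenized model (known contour, average breast properties);
* ``GROUND_TRUTH`` — pressures divided by the fluence simulated on the
  true labeled phantom.

At each vessel voxel the compensated absorptions at the two wavelengths
are unmixed into hemoglobin concentrations and converted to SO2.  Region
statistics reduce voxel maps to per-ROI means, and the accuracy metric is
the average absolute deviation of the ROI means from the set SO2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .blood_optics import ExtinctionTable, so2_of
from .mc_fluence import FluenceMap
from .pa_forward import PressureVolume
from .phantom_model import TissueLabelGrid, Tissue

__all__ = [
    "Approach",
    "ROI",
    "SO2Report",
    "SO2Map",
    "estimate_so2_map",
    "roi_mean_so2",
    "average_absolute_deviation",
    "vessel_mask_of",
]


class Approach(enum.Enum):
    NONE = "none"
    HOMOGENEOUS = "homogeneous"
    GROUND_TRUTH = "ground_truth"


@dataclass(frozen=True)
class ROI:
    """An axis-aligned voxel box, origin (inclusive) plus extents."""

    name: str
    origin_vox: tuple[int, int, int]
    extent_vox: tuple[int, int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + e) for o, e in zip(self.origin_vox, self.extent_vox))

    @classmethod
    def from_mm_box(cls, name, center_mm, extent_mm, origin_mm, pitch_mm, shape) -> "ROI":
        center = np.asarray(center_mm, dtype=float)
        extent = np.asarray(extent_mm, dtype=float)
        lo = np.floor((center - extent / 2 - np.asarray(origin_mm)) / pitch_mm).astype(int)
        n = np.maximum(np.round(extent / pitch_mm).astype(int), 1)
        lo = np.clip(lo, 0, np.asarray(shape) - 1)
        n = np.minimum(n, np.asarray(shape) - lo)
        return cls(name=name, origin_vox=tuple(lo), extent_vox=tuple(n))


@dataclass
class SO2Map:
    """Voxelwise SO2 estimate (%) with validity flags."""

    values: np.ndarray  # percent; NaN outside the vessel mask
    valid: np.ndarray  # vessel voxels with a usable estimate
    negative_flagged: np.ndarray  # valid voxels whose unmixing went negative


def estimate_so2_map(
    p755: PressureVolume,
    p1064: PressureVolume,
    phi755: FluenceMap | None,
    phi1064: FluenceMap | None,
    table: ExtinctionTable,
    vessel_mask: np.ndarray,
) -> SO2Map:
    """Unmix compensated dual-wavelength pressures into SO2 on the mask.

    Compensated absorption is mu_a_hat(lambda) = p0(lambda) / Phi(lambda)
    (proportional to mu_a up to the wavelength-independent Gruneisen
    factor, which cancels in the ratio).  Passing ``None`` for a fluence
    map means no compensation (Phi = 1).  Vessel voxels with nonpositive
    compensated signal at both wavelengths, or with nonpositive fluence,
    are flagged invalid rather than silently dropped.  Negative unmixed
    concentrations are kept (clipping would bias ROI means) and flagged.
    """
    if p755.values.shape != p1064.values.shape:
        raise ValueError("pressure volumes must share a grid")
    mask = np.asarray(vessel_mask, dtype=bool)

    def compensate(p: PressureVolume, phi: FluenceMap | None):
        if phi is None:
            return p.values[mask], np.ones(int(mask.sum()), dtype=bool)
        f = phi.values[mask]
        ok = f > 0
        out = np.zeros_like(f)
        out[ok] = p.values[mask][ok] / f[ok]
        return out, ok

    mu755, ok755 = compensate(p755, phi755)
    mu1064, ok1064 = compensate(p1064, phi1064)

    mat = table.matrix((755, 1064))
    inv = np.linalg.inv(mat)
    c_hb = inv[0, 0] * mu755 + inv[0, 1] * mu1064
    c_hbo2 = inv[1, 0] * mu755 + inv[1, 1] * mu1064

    usable = ok755 & ok1064 & ~((mu755 <= 0) & (mu1064 <= 0))
    total = c_hb + c_hbo2
    usable &= total != 0
    so2_lin = np.full(mu755.shape, np.nan)
    so2_lin[usable] = 100.0 * c_hbo2[usable] / total[usable]

    values = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)
    negative = np.zeros(mask.shape, dtype=bool)
    values[mask] = so2_lin
    valid[mask] = usable
    negative[mask] = usable & ((c_hb < 0) | (c_hbo2 < 0))
    return SO2Map(values=values, valid=valid, negative_flagged=negative)


def vessel_mask_of(grid: TissueLabelGrid, dilate_mm: float = 0.0) -> np.ndarray:
    """Blood-channel mask, optionally dilated by the imaging PSF radius
    (reproduces 'vessel pixel' selection without a segmentation step)."""
    mask = grid.mask(Tissue.BLOOD)
    if dilate_mm > 0:
        n_iter = int(round(dilate_mm / grid.pitch_mm))
        if n_iter > 0:
            mask = binary_dilation(mask, iterations=n_iter)
    return mask


def roi_mean_so2(so2_map: SO2Map, roi: ROI) -> float:
    """Mean SO2 (%) over valid vessel voxels inside the ROI box."""
    sl = roi.slices()
    vals = so2_map.values[sl][so2_map.valid[sl]]
    if vals.size == 0:
        raise ValueError(f"ROI {roi.name!r} contains no valid vessel voxels")
    return float(np.mean(vals))


def average_absolute_deviation(estimates, true_so2: float) -> float:
    """Mean of |estimate - true| over the ROI estimates, in percent."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("need at least one estimate")
    return float(np.mean(np.abs(estimates - true_so2)))


@dataclass
class SO2Report:
    """Tidy per-(setpoint, approach, ROI) results plus deviation column."""

    rows: pd.DataFrame  # columns: set_so2, approach, roi, mean_so2, avg_abs_dev

    @classmethod
    def from_estimates(cls, records: list[dict]) -> "SO2Report":
        df = pd.DataFrame.from_records(
            records, columns=["set_so2", "approach", "roi", "mean_so2"]
        )
        devs = []
        for _, r in df.iterrows():
            grp = df[(df.set_so2 == r.set_so2) & (df.approach == r.approach)]
            devs.append(average_absolute_deviation(grp.mean_so2.to_numpy(), r.set_so2))
        df = df.assign(avg_abs_dev=devs)
        return cls(rows=df)

    def deviation(self, set_so2: float, approach: str) -> float:
        sel = self.rows[(self.rows.set_so2 == set_so2) & (self.rows.approach == approach)]
        if sel.empty:
            raise KeyError((set_so2, approach))
        return float(sel.avg_abs_dev.iloc[0])

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def to_markdown_table(self) -> str:
        """Markdown summary, one row per (approach, setpoint)."""
        lines = ["| approach | set SO2 (%) | " + " | ".join(
            f"{roi}" for roi in self.rows.roi.unique()) + " | avg abs dev (%) |"]
        lines.append("|" + "---|" * (3 + self.rows.roi.nunique() - 1))
        for (so2, app), grp in self.rows.groupby(["set_so2", "approach"], sort=False):
            cells = " | ".join(f"{v:.1f}" for v in grp.mean_so2)
            lines.append(f"| {app} | {so2} | {cells} | {grp.avg_abs_dev.iloc[0]:.1f} |")
        return "\n".join(lines)
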