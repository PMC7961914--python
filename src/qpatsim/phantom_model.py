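"""Digital breast phantom: a voxelized two-layer breast in a water bath.

The phantom emulates a pendant breast cast from two tissue-mimicking
layers — an outer fat layer and an inner fibroglandular core separated by
an undulating interface — pierced by eight wall-less blood channels
(1.3 mm diameter, four per layer) and carrying two absorbing tumor
spheres, each traversed through its core by one channel.

Geometry conventions
--------------------
All lengths are in mm; optical coefficients are in cm^-1 (the unit
conversion happens once, inside the Monte Carlo transport).  The physical
origin sits at the breast apex (the nipple); z increases into the breast,
so the chest-wall base is at ``z = breast_height_mm``.  The breast contour
is the lower half of an ellipsoid of revolution (a hemisphere when radius
equals height); the fat/fibroglandular interface is the same cap shrunk by
the fat-layer thickness, with a radial sinusoidal undulation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Tissue",
    "PhantomSpec",
    "TissueLabelGrid",
    "TissueOpticalTable",
    "OpticalPropertyVolume",
    "build_phantom",
    "assign_properties",
    "homogeneous_model_of",
    "default_channel_paths",
    "PhantomGeometryError",
]


class PhantomGeometryError(ValueError):
    """A phantom specification that cannot be built (e.g. a channel
    leaving the breast volume, or a tumor not threaded by any channel)."""


class Tissue(enum.IntEnum):
    """Voxel labels. BREAST only appears in homogenized models."""

    WATER = 0
    FAT = 1
    FIBRO = 2
    TUMOR = 3
    BLOOD = 4
    BREAST = 5


# ---------------------------------------------------------------------------
# implicit surfaces


def _radial(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.hypot(x, y)


def _inside_breast(x, y, z, radius: float, height: float):
    """Boolean mask of the breast contour (half-ellipsoid cap, apex at z=0)."""
    rho = _radial(x, y)
    return (z >= 0) & (z <= height) & (
        (rho / radius) ** 2 + ((z - height) / height) ** 2 <= 1.0
    )


def _core_excess(x, y, z, spec: "PhantomSpec"):
    """Signed indicator for the fibroglandular core: <= 0 inside.

    The core boundary is the breast cap shrunk by the fat-layer depth,
    modulated radially by a sinusoid of the configured amplitude/period.
    """
    d = spec.interface_mean_depth_mm
    r_in = spec.breast_radius_mm - d
    h_in = spec.breast_height_mm - d
    rho = _radial(x, y)
    s = np.sqrt((rho / r_in) ** 2 + ((z - spec.breast_height_mm) / h_in) ** 2)
    undulation = (
        spec.interface_undulation_amplitude_mm
        * np.sin(2.0 * np.pi * rho / spec.interface_undulation_period_mm)
        / r_in
    )
    return np.where(z >= 0, s - (1.0 + undulation), np.inf)


def _inner_rho(z: float, spec: "PhantomSpec") -> float:
    """Unperturbed radial coordinate of the fat/fibro interface at height z."""
    d = spec.interface_mean_depth_mm
    r_in = spec.breast_radius_mm - d
    h_in = spec.breast_height_mm - d
    t = 1.0 - ((z - spec.breast_height_mm) / h_in) ** 2
    return r_in * np.sqrt(max(t, 0.0))


def _surface_rho(z: float, radius: float, height: float) -> float:
    t = 1.0 - ((z - height) / height) ** 2
    return radius * np.sqrt(max(t, 0.0))


# ---------------------------------------------------------------------------
# default channel network


def default_channel_paths(
    radius: float = 45.0,
    height: float = 40.0,
    fat_depth: float = 13.0,
    undulation_amp: float = 2.0,
    undulation_period: float = 25.0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Construct the default eight-channel network, (fat paths, fibro paths).

    Fat-layer channels are circular arcs at constant height, offset 4 mm
    outward from the fat/fibro interface so they stay inside the fat shell
    even at the undulation peaks.  Fibroglandular channels are straight
    chords through the core at staggered (y, z) offsets chosen so that no
    two channels approach within a tube diameter and each tumor sphere is
    crossed by exactly one channel.
    """
    spec_like = PhantomSpec(
        breast_radius_mm=radius,
        breast_height_mm=height,
        interface_mean_depth_mm=fat_depth,
        interface_undulation_amplitude_mm=undulation_amp,
        interface_undulation_period_mm=undulation_period,
        channel_paths=[],
        tumor_centers_mm=np.zeros((0, 3)),
        tumor_diameters_mm=[],
        _validate=False,
    )

    fat_paths = []
    phis = np.deg2rad(np.arange(-70.0, 70.0 + 1e-9, 5.0))
    for zf in (0.40, 0.625, 0.825, 0.975):
        z = zf * height
        rho = _inner_rho(z, spec_like) + 4.0
        pts = np.column_stack([rho * np.cos(phis), rho * np.sin(phis), np.full_like(phis, z)])
        fat_paths.append(pts)

    fibro_paths = []
    for y, z in ((-15.0, 22.0), (-8.0, 28.0), (5.0, 34.0), (15.0, 26.0)):
        rho_core = _inner_rho(z, spec_like) - undulation_amp - 1.0
        half = np.sqrt(max(rho_core**2 - y**2, 0.0)) - 3.0
        xs = np.linspace(-half, half, 9)
        pts = np.column_stack([xs, np.full_like(xs, y), np.full_like(xs, z)])
        fibro_paths.append(pts)
    return fat_paths, fibro_paths


def _default_spec_fields(pitch: float) -> dict:
    fat_paths, fibro_paths = default_channel_paths()
    spec_like = PhantomSpec(
        channel_paths=[], tumor_centers_mm=np.zeros((0, 3)),
        tumor_diameters_mm=[], _validate=False,
    )
    # tumor 1 threaded on the second fat arc (phi = 0 vertex); tumor 2 on
    # the second fibroglandular chord (x = 0 vertex)
    t1 = np.array([_inner_rho(0.625 * 40.0, spec_like) + 4.0, 0.0, 0.625 * 40.0])
    t2 = np.array([0.0, -8.0, 28.0])
    return dict(
        channel_paths=fat_paths + fibro_paths,
        tumor_centers_mm=np.vstack([t1, t2]),
        tumor_diameters_mm=[16.0, 16.0],
        voxel_pitch_mm=pitch,
    )


# ---------------------------------------------------------------------------
# spec and grid containers


@dataclass
class PhantomSpec:
    """Parametric description of the digital phantom and its voxel grid."""

    breast_radius_mm: float = 45.0
    breast_height_mm: float = 40.0
    interface_mean_depth_mm: float = 13.0
    interface_undulation_amplitude_mm: float = 2.0
    interface_undulation_period_mm: float = 25.0
    channel_paths: list = None
    channel_diameter_mm: float = 1.3
    tumor_centers_mm: np.ndarray = None
    tumor_diameters_mm: list = None
    voxel_pitch_mm: float = 0.5
    margin_xy_mm: float = 12.0
    margin_below_mm: float = 10.0
    margin_above_mm: float = 6.0
    rng_seed: int = 0
    _validate: bool = True

    def __post_init__(self) -> None:
        if self.channel_paths is None and self.tumor_centers_mm is None:
            defaults = _default_spec_fields(self.voxel_pitch_mm)
            self.channel_paths = defaults["channel_paths"]
            self.tumor_centers_mm = defaults["tumor_centers_mm"]
            if self.tumor_diameters_mm is None:
                self.tumor_diameters_mm = defaults["tumor_diameters_mm"]
        self.channel_paths = [np.asarray(p, dtype=float) for p in (self.channel_paths or [])]
        self.tumor_centers_mm = np.asarray(
            self.tumor_centers_mm if self.tumor_centers_mm is not None else np.zeros((0, 3)),
            dtype=float,
        ).reshape(-1, 3)
        self.tumor_diameters_mm = list(self.tumor_diameters_mm or [])
        if self.voxel_pitch_mm <= 0:
            raise ValueError("voxel_pitch_mm must be > 0")
        if self.interface_mean_depth_mm >= min(self.breast_radius_mm, self.breast_height_mm):
            raise ValueError("fat layer thicker than the breast")
        if self._validate:
            self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for d in self.tumor_diameters_mm:
            if not 15.0 <= d <= 20.0:
                raise PhantomGeometryError(f"tumor diameter {d} mm outside [15, 20] mm")
        if len(self.tumor_centers_mm) != len(self.tumor_diameters_mm):
            raise PhantomGeometryError("tumor centers and diameters differ in count")

        layers = []
        for i, path in enumerate(self.channel_paths):
            x, y, z = path[:, 0], path[:, 1], path[:, 2]
            inside = _inside_breast(x, y, z, self.breast_radius_mm, self.breast_height_mm)
            if not np.all(inside):
                raise PhantomGeometryError(f"channel {i} exits the breast volume")
            excess = _core_excess(x, y, z, self)
            if np.all(excess < 0):
                layers.append("fibro")
            elif np.all(excess > 0):
                layers.append("fat")
            else:
                raise PhantomGeometryError(f"channel {i} crosses the fat/fibro interface")
        if len(self.channel_paths) == 8:
            if layers.count("fat") != 4 or layers.count("fibro") != 4:
                raise PhantomGeometryError("expected 4 fat-layer and 4 fibro-layer channels")

        tol = self.channel_diameter_mm / 2.0
        for j, center in enumerate(self.tumor_centers_mm):
            n_hits = sum(
                1 for path in self.channel_paths
                if _point_polyline_distance(center, path) <= tol
            )
            if n_hits != 1:
                raise PhantomGeometryError(
                    f"tumor {j} must be traversed by exactly one channel (found {n_hits})"
                )

    # -- grid layout ------------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        half = self.breast_radius_mm + self.margin_xy_mm
        nx = int(round(2 * half / self.voxel_pitch_mm))
        nz = int(round((self.breast_height_mm + self.margin_below_mm + self.margin_above_mm)
                       / self.voxel_pitch_mm))
        return nx, nx, nz

    @property
    def grid_origin_mm(self) -> np.ndarray:
        """Physical coordinate of the center of voxel (0, 0, 0)."""
        half = self.breast_radius_mm + self.margin_xy_mm
        p = self.voxel_pitch_mm
        return np.array([-half + p / 2, -half + p / 2, -self.margin_below_mm + p / 2])


def _point_polyline_distance(point: np.ndarray, path: np.ndarray) -> float:
    a = path[:-1]
    b = path[1:]
    ab = b - a
    ap = point[None, :] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", ap, ab) / np.where(denom > 0, denom, 1.0), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(point[None, :] - closest, axis=1)))


@dataclass
class TissueLabelGrid:
    """Voxel volume of integer tissue labels with physical pitch and origin."""

    labels: np.ndarray
    pitch_mm: float
    origin_mm: np.ndarray

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates of voxel centers."""
        return tuple(
            self.origin_mm[k] + self.pitch_mm * np.arange(self.labels.shape[k])
            for k in range(3)
        )

    def label_counts(self) -> dict[Tissue, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {Tissue(v): int(c) for v, c in zip(values, counts)}

    def mask(self, tissue: Tissue) -> np.ndarray:
        return self.labels == int(tissue)


# ---------------------------------------------------------------------------
# optical property tables


@dataclass(frozen=True)
class TissueOpticalTable:
    """Per-tissue optical properties (mu_a, mu_s' in cm^-1; g, n unitless).

    ``rows`` maps tissue label -> wavelength (nm) -> (mu_a, mu_sp, g, n).
    Blood absorption is supplied at assignment time (it depends on the
    oxygenation state); blood scattering/anisotropy/index defaults are
    package choices since whole-blood scattering in a phantom channel is
    not part of the measured tissue table.
    """

    rows: dict
    tumor_mu_a_offset: float = 0.2  # designed tumor contrast; measured preset: 0.12
    blood_mu_sp: float = 2.0
    blood_g: float = 0.9
    blood_n: float = 1.38

    def __post_init__(self) -> None:
        for tissue, per_wl in self.rows.items():
            for wl, (mua, musp, g, n) in per_wl.items():
                if mua < 0 or musp < 0:
                    raise ValueError(f"negative coefficient for {tissue} at {wl} nm")
                if not 0.0 <= g < 1.0:
                    raise ValueError(f"anisotropy g for {tissue} must be in [0, 1)")
                if n < 1.0:
                    raise ValueError(f"refractive index for {tissue} must be >= 1")

    @classmethod
    def default(cls, **overrides) -> "TissueOpticalTable":
        """Measured tissue-mimicking-material values at 755 and 1064 nm."""
        rows = {
            Tissue.WATER: {755: (0.03, 1e-9, 0.95, 1.33), 1064: (0.12, 1e-9, 0.95, 1.33)},
            Tissue.FAT: {755: (0.38, 25.02, 0.7, 1.49), 1064: (0.56, 17.01, 0.7, 1.49)},
            Tissue.FIBRO: {755: (0.49, 18.81, 0.7, 1.74), 1064: (0.71, 10.74, 0.7, 1.74)},
            Tissue.BREAST: {755: (0.44, 21.92, 0.7, 1.62), 1064: (0.63, 13.88, 0.7, 1.62)},
        }
        return cls(rows=rows, **overrides)

    def lookup(self, tissue: Tissue, wavelength: int) -> tuple[float, float, float, float]:
        if tissue is Tissue.TUMOR:
            mua, musp, g, n = self.rows[Tissue.FIBRO][wavelength]
            return mua + self.tumor_mu_a_offset, musp, g, n
        return self.rows[tissue][wavelength]


@dataclass
class OpticalPropertyVolume:
    """Per-voxel mu_a, mu_s (cm^-1), g, n at one wavelength."""

    mu_a: np.ndarray
    mu_s: np.ndarray
    g: np.ndarray
    n: np.ndarray
    pitch_mm: float
    origin_mm: np.ndarray
    wavelength: int

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mu_a.shape


# ---------------------------------------------------------------------------
# operations


def build_phantom(spec: PhantomSpec) -> TissueLabelGrid:
    """Rasterize the phantom specification onto its voxel grid.

    Labels are painted in priority order water < fat < fibro < tumor <
    blood, so channels override every tissue they cross, and tumor voxels
    are clipped to the breast interior.  Deterministic for a fixed spec.
    """
    spec.validate()
    nx, ny, nz = spec.grid_shape
    origin = spec.grid_origin_mm
    p = spec.voxel_pitch_mm
    xs = origin[0] + p * np.arange(nx)
    ys = origin[1] + p * np.arange(ny)
    zs = origin[2] + p * np.arange(nz)
    x, y, z = np.meshgrid(xs, ys, zs, indexing="ij")

    labels = np.full((nx, ny, nz), int(Tissue.WATER), dtype=np.int8)
    breast = _inside_breast(x, y, z, spec.breast_radius_mm, spec.breast_height_mm)
    labels[breast] = int(Tissue.FAT)
    core = breast & (_core_excess(x, y, z, spec) <= 0)
    labels[core] = int(Tissue.FIBRO)

    for center, diameter in zip(spec.tumor_centers_mm, spec.tumor_diameters_mm):
        r = diameter / 2.0
        sphere = ((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2) <= r**2
        labels[sphere & breast] = int(Tissue.TUMOR)

    tube_r = spec.channel_diameter_mm / 2.0
    for path in spec.channel_paths:
        _paint_tube(labels, breast, xs, ys, zs, path, tube_r)

    return TissueLabelGrid(labels=labels, pitch_mm=p, origin_mm=origin)


def _paint_tube(labels, breast, xs, ys, zs, path, tube_r) -> None:
    """Label voxels within tube_r of the polyline as BLOOD (breast-clipped)."""
    pitch = xs[1] - xs[0]
    pad = tube_r + pitch
    for a, b in zip(path[:-1], path[1:]):
        lo = np.minimum(a, b) - pad
        hi = np.maximum(a, b) + pad
        i0, i1 = np.searchsorted(xs, (lo[0], hi[0]))
        j0, j1 = np.searchsorted(ys, (lo[1], hi[1]))
        k0, k1 = np.searchsorted(zs, (lo[2], hi[2]))
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        sx, sy, sz = np.meshgrid(xs[i0:i1], ys[j0:j1], zs[k0:k1], indexing="ij")
        ab = b - a
        denom = float(ab @ ab)
        px, py, pz = sx - a[0], sy - a[1], sz - a[2]
        t = np.clip((px * ab[0] + py * ab[1] + pz * ab[2]) / max(denom, 1e-30), 0.0, 1.0)
        d2 = (px - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (pz - t * ab[2]) ** 2
        hit = (d2 <= tube_r**2) & breast[i0:i1, j0:j1, k0:k1]
        block = labels[i0:i1, j0:j1, k0:k1]
        block[hit] = int(Tissue.BLOOD)


def assign_properties(
    grid: TissueLabelGrid,
    table: TissueOpticalTable,
    wavelength: int,
    blood_mu_a: float = 0.0,
) -> OpticalPropertyVolume:
    """Map tissue labels to per-voxel optical properties at one wavelength.

    mu_s is recovered from the reduced coefficient through the similarity
    relation mu_s = mu_s' / (1 - g).  Tumor voxels take fibroglandular
    values plus the configured absorption offset; blood voxels take the
    supplied ``blood_mu_a`` with the table's blood scattering defaults.
    """
    if blood_mu_a < 0:
        raise ValueError("blood_mu_a must be >= 0")
    shape = grid.labels.shape
    mu_a = np.zeros(shape, dtype=np.float32)
    mu_s = np.zeros(shape, dtype=np.float32)
    g = np.zeros(shape, dtype=np.float32)
    n = np.ones(shape, dtype=np.float32)

    for value in np.unique(grid.labels):
        tissue = Tissue(int(value))  # raises on unknown labels
        mask = grid.labels == value
        if tissue is Tissue.BLOOD:
            mua, musp, gv, nv = blood_mu_a, table.blood_mu_sp, table.blood_g, table.blood_n
        else:
            mua, musp, gv, nv = table.lookup(tissue, wavelength)
        mu_a[mask] = mua
        mu_s[mask] = musp / (1.0 - gv)
        g[mask] = gv
        n[mask] = nv

    return OpticalPropertyVolume(
        mu_a=mu_a, mu_s=mu_s, g=g, n=n,
        pitch_mm=grid.pitch_mm, origin_mm=grid.origin_mm, wavelength=wavelength,
    )


def homogeneous_model_of(grid: TissueLabelGrid, table: TissueOpticalTable | None = None) -> TissueLabelGrid:
    """Simplified model with the known contour but homogenized interior.

    Every non-water voxel is relabeled BREAST, whose properties are the
    fat/fibroglandular average — the model an observer with a known breast
    contour but unknown internal morphology would simulate.
    """
    labels = grid.labels.copy()
    labels[labels != int(Tissue.WATER)] = int(Tissue.BREAST)
    return TissueLabelGrid(labels=labels, pitch_mm=grid.pitch_mm, origin_mm=grid.origin_mm.copy())
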