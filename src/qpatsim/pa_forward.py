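"""Photoacoustic forward model: initial pressure and image degradation.

The initial pressure after a short laser pulse is the voxelwise product
p0 = Gamma * Phi * mu_a (Gruneisen efficiency, fluence, absorption).  The
acoustic propagation and tomographic reconstruction that would turn p0
into an image are replaced by a degradation proxy — a Gaussian
point-spread blur at the system resolution plus multiplicative noise —
which exposes the same amplitude corruption that fluence compensation
must survive, without simulating wave physics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .mc_fluence import FluenceMap
from .phantom_model import OpticalPropertyVolume

__all__ = ["PressureVolume", "DegradationModel", "initial_pressure", "degrade"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PressureVolume:
    """Per-voxel initial pressure, arbitrary units proportional to
    Gamma * J/cm^3, for one wavelength and oxygenation setpoint."""

    values: np.ndarray
    wavelength: int
    pitch_mm: float
    origin_mm: np.ndarray
    so2_setpoint: float | None = None
    degradation_applied: bool = False


@dataclass(frozen=True)
class DegradationModel:
    """Reconstruction stand-in: PSF blur plus multiplicative Gaussian noise.

    The default 0.5 mm FWHM sits inside the 0.3-1 mm resolution range of
    3D photoacoustic breast systems.
    """

    psf_fwhm_mm: float = 0.5
    noise_sigma_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm <= 0:
            raise ValueError("psf_fwhm_mm must be > 0")
        if self.noise_sigma_fraction < 0:
            raise ValueError("noise_sigma_fraction must be >= 0")


def initial_pressure(
    phi: FluenceMap,
    props: OpticalPropertyVolume,
    grueneisen: np.ndarray | float = 1.0,
    so2_setpoint: float | None = None,
) -> PressureVolume:
    """Voxelwise p0 = Gamma * Phi * mu_a.

    ``grueneisen`` may be a scalar or a per-voxel map.  A wavelength-
    independent Gamma cancels in dual-wavelength SO2 estimation, so the
    default is 1 everywhere.
    """
    if phi.values.shape != props.mu_a.shape:
        raise ValueError("fluence map and property volume shapes differ")
    values = np.asarray(grueneisen, dtype=float) * phi.values * props.mu_a
    return PressureVolume(
        values=values,
        wavelength=phi.wavelength,
        pitch_mm=phi.pitch_mm,
        origin_mm=phi.origin_mm.copy(),
        so2_setpoint=so2_setpoint,
    )


def degrade(p: PressureVolume, model: DegradationModel) -> PressureVolume:
    """Blur with the PSF, then apply multiplicative Gaussian noise.

    Deterministic for a fixed model seed; with noise_sigma_fraction = 0
    and psf_fwhm_mm -> 0 the operation approaches the identity.
    """
    sigma_vox = model.psf_fwhm_mm * _FWHM_TO_SIGMA / p.pitch_mm
    blurred = gaussian_filter(p.values, sigma=sigma_vox)
    if model.noise_sigma_fraction > 0:
        rng = np.random.default_rng(model.seed)
        blurred = blurred * (1.0 + model.noise_sigma_fraction * rng.standard_normal(blurred.shape))
    out = replace(p)
    out.values = blurred
    out.degradation_applied = True
    return out
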