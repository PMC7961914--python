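"""Volume and configuration I/O.

Volumes travel as NIfTI (axis-aligned affine built from the voxel pitch
and the physical origin, both in mm) with a JSON sidecar carrying
metadata NIfTI headers cannot: wavelength, pulse energy, seeds, and the
tissue-label legend.  Phantom specifications serialize to YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom_model import PhantomSpec, Tissue, TissueLabelGrid
from .mc_fluence import FluenceMap
from .pa_forward import PressureVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_label_grid",
    "load_label_grid",
    "save_fluence",
    "load_fluence",
    "spec_to_yaml",
    "spec_from_yaml",
]


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_volume(values: np.ndarray, pitch_mm: float, origin_mm, path, meta: dict | None = None) -> None:
    path = Path(path)
    affine = np.diag([pitch_mm, pitch_mm, pitch_mm, 1.0])
    affine[:3, 3] = np.asarray(origin_mm, dtype=float)
    img = nib.Nifti1Image(np.asarray(values), affine)
    img.header.set_zooms((pitch_mm,) * 3)
    nib.save(img, str(path))
    if meta is not None:
        _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_volume(path) -> tuple[np.ndarray, float, np.ndarray, dict]:
    path = Path(path)
    img = nib.load(str(path))
    affine = img.affine
    pitch = float(affine[0, 0])
    origin = np.asarray(affine[:3, 3], dtype=float)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return np.asarray(img.dataobj), pitch, origin, meta


def save_label_grid(grid: TissueLabelGrid, path) -> None:
    legend = {t.name: int(t) for t in Tissue}
    save_volume(grid.labels.astype(np.int16), grid.pitch_mm, grid.origin_mm, path,
                meta={"kind": "tissue_labels", "legend": legend})


def load_label_grid(path) -> TissueLabelGrid:
    values, pitch, origin, _ = load_volume(path)
    return TissueLabelGrid(labels=values.astype(np.int8), pitch_mm=pitch, origin_mm=origin)


def save_fluence(fluence: FluenceMap, path) -> None:
    save_volume(
        fluence.values.astype(np.float32), fluence.pitch_mm, fluence.origin_mm, path,
        meta={
            "kind": "fluence_J_per_cm2",
            "wavelength_nm": fluence.wavelength,
            "pulse_energy_J": fluence.pulse_energy_J,
            "photon_count": fluence.photon_count,
            "rng_seed": fluence.rng_seed,
        },
    )


def load_fluence(path) -> FluenceMap:
    values, pitch, origin, meta = load_volume(path)
    return FluenceMap(
        values=np.asarray(values, dtype=np.float64),
        wavelength=int(meta.get("wavelength_nm", 0)),
        pitch_mm=pitch,
        origin_mm=origin,
        photon_count=int(meta.get("photon_count", 0)),
        rng_seed=int(meta.get("rng_seed", 0)),
        pulse_energy_J=float(meta.get("pulse_energy_J", 1.0)),
    )


def spec_to_yaml(spec: PhantomSpec, path) -> None:
    payload = {
        "breast_radius_mm": spec.breast_radius_mm,
        "breast_height_mm": spec.breast_height_mm,
        "interface_mean_depth_mm": spec.interface_mean_depth_mm,
        "interface_undulation_amplitude_mm": spec.interface_undulation_amplitude_mm,
        "interface_undulation_period_mm": spec.interface_undulation_period_mm,
        "channel_diameter_mm": spec.channel_diameter_mm,
        "voxel_pitch_mm": spec.voxel_pitch_mm,
        "channel_paths": [p.tolist() for p in spec.channel_paths],
        "tumor_centers_mm": spec.tumor_centers_mm.tolist(),
        "tumor_diameters_mm": list(spec.tumor_diameters_mm),
        "rng_seed": spec.rng_seed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def spec_from_yaml(path) -> PhantomSpec:
    payload = yaml.safe_load(Path(path).read_text())
    return PhantomSpec(**payload)
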