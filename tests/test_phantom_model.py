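"""Digital phantom geometry, rasterization, and property assignment."""

import numpy as np
import pytest
from scipy import ndimage

from qpatsim.phantom_model import (
    PhantomGeometryError,
    PhantomSpec,
    Tissue,
    TissueOpticalTable,
    assign_properties,
    build_phantom,
    homogeneous_model_of,
)


def small_channel_spec(pitch: float) -> PhantomSpec:
    """Small breast with a single straight fibro-layer channel, for
    rasterization-accuracy checks at fine pitch."""
    path = np.array([[-8.0, 0.0, 12.0], [8.0, 0.0, 12.0]])
    return PhantomSpec(
        breast_radius_mm=20.0,
        breast_height_mm=18.0,
        interface_mean_depth_mm=6.0,
        interface_undulation_amplitude_mm=0.0,
        channel_paths=[path],
        tumor_centers_mm=np.zeros((0, 3)),
        tumor_diameters_mm=[],
        voxel_pitch_mm=pitch,
        margin_xy_mm=4.0,
        margin_below_mm=3.0,
        margin_above_mm=2.0,
    )


class TestBuildPhantom:
    def test_default_phantom_has_eight_channel_tubes(self, default_grid):
        _, n = ndimage.label(default_grid.mask(Tissue.BLOOD))
        assert n == 8

    def test_four_channels_per_layer(self, default_spec):
        from qpatsim.phantom_model import _core_excess

        layers = []
        for path in default_spec.channel_paths:
            excess = _core_excess(path[:, 0], path[:, 1], path[:, 2], default_spec)
            layers.append("fibro" if np.all(excess < 0) else "fat")
        assert layers.count("fat") == 4
        assert layers.count("fibro") == 4

    def test_each_tumor_traversed_by_exactly_one_channel(self, default_spec, default_grid):
        comp, _ = ndimage.label(default_grid.mask(Tissue.BLOOD))
        xs, ys, zs = default_grid.coords()
        x, y, z = np.meshgrid(xs, ys, zs, indexing="ij")
        for center, diameter in zip(
            default_spec.tumor_centers_mm, default_spec.tumor_diameters_mm
        ):
            sphere = (
                (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
            ) <= (diameter / 2) ** 2
            ids = np.unique(comp[sphere])
            assert len(ids[ids > 0]) == 1, "tumor must contain exactly one channel"

    def test_degenerate_spec_without_channels_or_tumors(self):
        spec = PhantomSpec(
            channel_paths=[], tumor_centers_mm=np.zeros((0, 3)), tumor_diameters_mm=[],
            voxel_pitch_mm=1.0,
        )
        grid = build_phantom(spec)
        assert set(np.unique(grid.labels)) <= {
            int(Tissue.WATER), int(Tissue.FAT), int(Tissue.FIBRO)
        }

    def test_non_water_voxels_inside_breast_contour(self, default_spec, default_grid):
        xs, ys, zs = default_grid.coords()
        x, y, z = np.meshgrid(xs, ys, zs, indexing="ij")
        rho2 = x**2 + y**2
        R, H = default_spec.breast_radius_mm, default_spec.breast_height_mm
        inside = (z >= 0) & (rho2 / R**2 + ((z - H) / H) ** 2 <= 1.0 + 1e-9)
        assert not np.any((default_grid.labels != int(Tissue.WATER)) & ~inside)

    def test_rasterized_channel_cross_section_matches_disc_area(self):
        grid = build_phantom(small_channel_spec(pitch=0.25))
        blood = grid.mask(Tissue.BLOOD)
        # per-slice count perpendicular to the channel axis (x), interior only
        counts = blood.sum(axis=(1, 2))
        interior = counts[np.nonzero(counts)[0][4:-4]]
        analytic = np.pi * 0.65**2 / 0.25**2
        assert abs(interior.mean() - analytic) / analytic < 0.20

    def test_channel_volume_converges_with_pitch(self):
        analytic = np.pi * 0.65**2 * 16.0  # tube volume, mm^3
        errors = []
        for pitch in (0.5, 0.25):
            grid = build_phantom(small_channel_spec(pitch))
            vol = grid.mask(Tissue.BLOOD).sum() * pitch**3
            errors.append(abs(vol - analytic) / analytic)
        assert errors[1] < errors[0]

    def test_build_is_deterministic(self):
        spec = small_channel_spec(0.5)
        a = build_phantom(spec)
        b = build_phantom(small_channel_spec(0.5))
        assert np.array_equal(a.labels, b.labels)

    def test_channel_leaving_breast_rejected(self):
        path = np.array([[-30.0, 0.0, 12.0], [30.0, 0.0, 12.0]])
        with pytest.raises(PhantomGeometryError):
            small = small_channel_spec(0.5)
            PhantomSpec(
                **{**small.__dict__, "channel_paths": [path], "_validate": True}
            )

    def test_tumor_off_channel_rejected(self):
        small = small_channel_spec(0.5)
        with pytest.raises(PhantomGeometryError):
            PhantomSpec(
                **{
                    **small.__dict__,
                    "tumor_centers_mm": np.array([[0.0, 8.0, 12.0]]),
                    "tumor_diameters_mm": [16.0],
                }
            )

    def test_tumor_diameter_bounds_enforced(self):
        small = small_channel_spec(0.5)
        with pytest.raises(PhantomGeometryError):
            PhantomSpec(
                **{
                    **small.__dict__,
                    "tumor_centers_mm": np.array([[0.0, 0.0, 12.0]]),
                    "tumor_diameters_mm": [12.0],
                }
            )


class TestAssignProperties:
    def test_fat_values_at_755(self, default_grid):
        props = assign_properties(default_grid, TissueOpticalTable.default(), 755)
        fat = default_grid.mask(Tissue.FAT)
        assert props.mu_a[fat][0] == pytest.approx(0.38)
        assert props.mu_s[fat][0] == pytest.approx(25.02 / (1 - 0.7), rel=1e-6)
        assert props.g[fat][0] == pytest.approx(0.7)
        assert props.n[fat][0] == pytest.approx(1.49)

    def test_tumor_offset_added_to_fibro(self, default_grid):
        props = assign_properties(default_grid, TissueOpticalTable.default(), 1064)
        tumor = default_grid.mask(Tissue.TUMOR)
        assert props.mu_a[tumor][0] == pytest.approx(0.71 + 0.2, rel=1e-6)

    def test_blood_mu_a_passed_through(self, default_grid):
        props = assign_properties(
            default_grid, TissueOpticalTable.default(), 755, blood_mu_a=2.93
        )
        blood = default_grid.mask(Tissue.BLOOD)
        assert props.mu_a[blood][0] == pytest.approx(2.93, rel=1e-6)

    def test_zero_anisotropy_keeps_reduced_scattering(self):
        grid = build_phantom(small_channel_spec(1.0))
        rows = {
            t: {wl: (mua, musp, 0.0, n) for wl, (mua, musp, _, n) in per_wl.items()}
            for t, per_wl in TissueOpticalTable.default().rows.items()
        }
        table = TissueOpticalTable(rows=rows, blood_g=0.0)
        props = assign_properties(grid, table, 755)
        fat = grid.mask(Tissue.FAT)
        assert props.mu_s[fat][0] == pytest.approx(25.02, rel=1e-6)

    def test_negative_blood_mu_a_rejected(self, default_grid):
        with pytest.raises(ValueError):
            assign_properties(default_grid, TissueOpticalTable.default(), 755, blood_mu_a=-1)


class TestHomogeneousModel:
    def test_interior_relabeled_breast_contour_kept(self, default_grid):
        homo = homogeneous_model_of(default_grid)
        assert set(np.unique(homo.labels)) == {int(Tissue.WATER), int(Tissue.BREAST)}
        assert np.array_equal(
            homo.labels != int(Tissue.WATER), default_grid.labels != int(Tissue.WATER)
        )

    def test_breast_row_values(self, default_grid):
        homo = homogeneous_model_of(default_grid)
        props = assign_properties(homo, TissueOpticalTable.default(), 755)
        breast = homo.mask(Tissue.BREAST)
        assert props.mu_a[breast][0] == pytest.approx(0.44)
        assert props.mu_s[breast][0] == pytest.approx(21.92 / 0.3, rel=1e-6)

    def test_breast_row_is_fat_fibro_average_to_table_precision(self):
        table = TissueOpticalTable.default()
        for wl in (755, 1064):
            fat = table.rows[Tissue.FAT][wl]
            fib = table.rows[Tissue.FIBRO][wl]
            breast = table.rows[Tissue.BREAST][wl]
            assert breast[0] == pytest.approx((fat[0] + fib[0]) / 2, abs=0.00501)
            assert breast[1] == pytest.approx((fat[1] + fib[1]) / 2, abs=0.00501)

    def test_water_only_grid_unchanged(self):
        from qpatsim.phantom_model import TissueLabelGrid

        grid = TissueLabelGrid(
            labels=np.zeros((4, 4, 4), dtype=np.int8),
            pitch_mm=1.0,
            origin_mm=np.zeros(3),
        )
        homo = homogeneous_model_of(grid)
        assert np.array_equal(homo.labels, grid.labels)
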