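import numpy as np
import pytest

import irepulse as ip
from irepulse.field import superlevel_area
from irepulse.geometry import SOURCE, VoxelDomain

from conftest import make_slab_domain


@pytest.fixture(scope="module")
def coarse_pipeline(study_field_coarse):
    fmap = ip.field_magnitude(study_field_coarse)
    coronal = ip.extract_plane(fmap, "coronal")
    axial = ip.extract_plane(fmap, "axial")
    return fmap, coronal, axial


class TestFieldMagnitude:
    def test_slab_uniform_field(self):
        V = 120.0
        dom = make_slab_domain(nx=6, ny=6, nz=13, voxel_mm=1.0)
        bv = np.zeros(dom.grid_shape)
        bv[dom.labels == SOURCE] = V
        field = ip.solve_potential(dom, boundary_values=bv)
        fmap = ip.field_magnitude(field)
        d = (dom.grid_shape[2] - 1) * dom.voxel_mm
        expected = V / d * 10.0  # V/cm
        assert np.allclose(fmap.e_mag, expected, rtol=1e-9)

    def test_zero_voltage_zero_field(self, study_domain_coarse):
        field = ip.solve_potential(study_domain_coarse.with_voltage(0.0))
        fmap = ip.field_magnitude(field)
        assert np.allclose(fmap.e_mag, 0.0)

    def test_field_scales_linearly_with_voltage(self, study_domain_coarse,
                                                study_field_coarse):
        f500 = ip.solve_potential(study_domain_coarse.with_voltage(500.0))
        e500 = ip.field_magnitude(f500).e_mag
        e900 = ip.field_magnitude(study_field_coarse).e_mag
        assert np.allclose(e900, 1.8 * e500, rtol=1e-7, atol=1e-6)

    def test_field_nonnegative(self, coarse_pipeline):
        fmap, _, _ = coarse_pipeline
        assert np.all(fmap.e_mag >= 0)


class TestSuperlevelArea:
    def test_cone_disc_area(self):
        # radial cone: superlevel set {f >= t} is a disc of known area
        h = 0.05
        xs = np.arange(-3, 3, h)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        f = 10.0 - 4.0 * np.hypot(X, Y)
        for level, r0 in ((2.0, 2.0), (6.0, 1.0)):
            area = superlevel_area(f, h, level)
            assert area == pytest.approx(np.pi * r0**2, rel=0.01)

    def test_matches_fine_pixel_count(self):
        rng = np.random.default_rng(7)
        h = 0.1
        xs = np.arange(0, 4, h)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        f = np.sin(1.3 * X) * np.cos(0.9 * Y) + 0.3 * X
        area = superlevel_area(f, h, 0.5)
        # pixel counting on an 8x refined bilinear interpolation
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator((xs, xs), f)
        hf = h / 8
        fx = np.arange(xs[0], xs[-1] - 1e-9, hf)
        FX, FY = np.meshgrid(fx, fx, indexing="ij")
        fine = interp(np.stack([FX, FY], axis=-1))
        ref = np.sum(fine >= 0.5) * hf * hf
        assert area == pytest.approx(ref, rel=0.02)

    def test_monotone_in_level(self):
        h = 0.1
        xs = np.arange(-2, 2, h)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        f = np.exp(-(X**2 + Y**2))
        areas = [superlevel_area(f, h, t) for t in (0.2, 0.4, 0.6, 0.8)]
        assert all(a1 >= a2 for a1, a2 in zip(areas, areas[1:]))


class TestThresholdArea:
    def test_threshold_above_max_returns_zero(self, coarse_pipeline):
        _, coronal, _ = coarse_pipeline
        huge = float(coronal.values[~coronal.electrode_mask].max()) * 10
        assert ip.threshold_area(coronal, huge) == 0.0

    def test_nonpositive_threshold_rejected(self, coarse_pipeline):
        _, coronal, _ = coarse_pipeline
        with pytest.raises(ValueError):
            ip.threshold_area(coronal, 0.0)

    def test_electrode_interiors_counted_as_ablated(self, coarse_pipeline):
        _, coronal, _ = coarse_pipeline
        # electrode cross-sections contribute ~2 x 1 mm x 15 mm
        area = ip.threshold_area(coronal, 500.0)
        elec_area = coronal.electrode_mask.sum() * coronal.spacing_mm**2
        assert elec_area > 20.0
        assert area > elec_area

    def test_scaling_identity_between_voltages(self, study_domain_coarse,
                                               study_field_coarse):
        """area(V, T) == area(V', T * V'/V), verified with two full solves."""
        f500 = ip.solve_potential(study_domain_coarse.with_voltage(500.0))
        c500 = ip.extract_plane(ip.field_magnitude(f500), "coronal")
        c900 = ip.extract_plane(ip.field_magnitude(study_field_coarse), "coronal")
        for T in (300.0, 500.0, 800.0):
            a900 = ip.threshold_area(c900, T)
            a500 = ip.threshold_area(c500, T * 500.0 / 900.0)
            assert a900 == pytest.approx(a500, rel=1e-4)


class TestIsolineSeries:
    def test_monotone_nonincreasing(self, coarse_pipeline):
        _, coronal, _ = coarse_pipeline
        res = ip.isoline_series(coronal)
        areas = list(res.areas.values())
        assert all(a >= b for a, b in zip(areas, areas[1:]))
        assert all(a >= 0 for a in areas)

    def test_area_grows_with_voltage_at_fixed_threshold(self, study_domain_coarse):
        by_voltage = {}
        for V in (500.0, 700.0, 900.0):
            f = ip.solve_potential(study_domain_coarse.with_voltage(V))
            sl = ip.extract_plane(ip.field_magnitude(f), "coronal")
            by_voltage[V] = ip.isoline_series(sl).areas
        for T in (500.0, 1000.0):
            areas = [by_voltage[V][T] for V in (500.0, 700.0, 900.0)]
            assert areas[0] < areas[1] < areas[2]

    def test_bad_threshold_lists_rejected(self, coarse_pipeline):
        _, coronal, _ = coarse_pipeline
        with pytest.raises(ValueError):
            ip.isoline_series(coronal, [])
        with pytest.raises(ValueError):
            ip.isoline_series(coronal, [500, 500, 600])


class TestPlanes:
    def test_plane_shapes_and_masks(self, coarse_pipeline):
        _, coronal, axial = coarse_pipeline
        assert coronal.values.shape == coronal.electrode_mask.shape
        assert coronal.electrode_mask.any() and axial.electrode_mask.any()
        # axial plane: electrode cross-sections are two small discs
        assert axial.electrode_mask.sum() < coronal.electrode_mask.sum()
        assert not coronal.values[~coronal.tissue_mask].any()

    def test_unknown_plane_rejected(self, coarse_pipeline):
        fmap, _, _ = coarse_pipeline
        with pytest.raises(ValueError):
            ip.extract_plane(fmap, "sagittal")

    def test_contour_area_agrees_with_superlevel_area(self, coarse_pipeline):
        _, coronal, _ = coarse_pipeline
        level = 500.0
        polys = ip.contour_polylines(coronal, level)
        assert polys
        # shoelace with even-odd orientation: outer contours positive
        total = 0.0
        for p in polys:
            x, y = p[:, 0], p[:, 1]
            total += 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        total = abs(total)
        ms = ip.threshold_area(coronal, level)
        assert total == pytest.approx(ms, rel=0.08)
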