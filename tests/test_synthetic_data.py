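"""Generators: defining laws, determinism, contour sanity, unit conversions."""

import math

import numpy as np
import pytest
from conftest import is_simple_closed, signed_area, volume_of_revolution

from aggmech import units
from aggmech.synthetic_data import (
    barrel_geometry,
    gen_compressed_aggregate,
    gen_compression_series,
    gen_doublet,
    gen_force_relaxation,
    gen_fusion_sequence,
    gen_rough_contour,
    harmonic_contour,
    render_fusion_frame,
    sphere_radius_from_volume,
)

SPHERE_V_150 = 4.0 / 3.0 * math.pi * 150.0 ** 3


class TestCompressedAggregate:
    def test_uncompressed_sphere(self):
        rec = gen_compressed_aggregate(4.5, SPHERE_V_150, 300.0, seed=0)
        assert rec.r2_um == pytest.approx(150.0, rel=1e-9)
        assert rec.r3_um == pytest.approx(150.0, rel=1e-9)
        assert rec.plateau_uN == 0.0

    def test_infeasible_gap_raises(self):
        with pytest.raises(ValueError):
            gen_compressed_aggregate(4.5, SPHERE_V_150, 301.0, seed=0)

    def test_plateau_is_laplace_force(self):
        rec = gen_compressed_aggregate(4.5, SPHERE_V_150, 210.0, seed=0)
        expected = units.laplace_force_uN(4.5, rec.r2_um, rec.r3_um)
        assert rec.plateau_uN == pytest.approx(expected, rel=1e-12)
        # and the trace ends on the plateau
        assert rec.force_trace[-1, 1] == pytest.approx(rec.plateau_uN, rel=1e-4)

    def test_volume_conserved_in_contour(self):
        """Solid of revolution of the generated profile matches the input volume."""
        for frac in (0.25, 0.4):
            gap = 300.0 * (1 - frac)
            rec = gen_compressed_aggregate(
                4.5, SPHERE_V_150, gap, seed=0, n_points=4000
            )
            v = volume_of_revolution(rec.contour)
            assert v == pytest.approx(SPHERE_V_150, rel=1e-3)

    def test_volume_drift_across_series(self):
        recs = gen_compression_series(4.5, SPHERE_V_150, [0.25, 0.4], seed=0)
        assert abs(recs[0].volume - recs[1].volume) / SPHERE_V_150 < 1e-3

    def test_contour_closed_simple_ccw(self):
        rec = gen_compressed_aggregate(4.5, SPHERE_V_150, 210.0, seed=0)
        assert signed_area(rec.contour) > 0
        assert is_simple_closed(rec.contour)

    def test_determinism(self):
        a = gen_compressed_aggregate(4.5, SPHERE_V_150, 210.0, noise_sd=1.0, seed=9)
        b = gen_compressed_aggregate(4.5, SPHERE_V_150, 210.0, noise_sd=1.0, seed=9)
        np.testing.assert_array_equal(a.contour, b.contour)
        np.testing.assert_array_equal(a.force_trace, b.force_trace)

    def test_barrel_geometry_reduces_to_sphere(self):
        r2, r3 = barrel_geometry(SPHERE_V_150, 300.0)
        assert r2 == pytest.approx(150.0, rel=1e-9)
        assert r3 == pytest.approx(150.0, rel=1e-9)
        assert sphere_radius_from_volume(SPHERE_V_150) == pytest.approx(150.0)


class TestFusionSequence:
    def test_noise_free_neck_law(self):
        fus = gen_fusion_sequence(4.5, 5.87e5, 150.0, 5.0, 12, seed=0)
        v = units.visco_capillary_velocity(4.5, 5.87e5)
        expected = np.sqrt(v * 150.0 * fus.times)
        np.testing.assert_allclose(fus.radii, expected, rtol=1e-12)
        assert np.all(fus.radii <= 0.5 * 150.0)

    def test_unit_conversion_gives_printed_velocity(self):
        """sigma = 4.5 mN/m, eta = 5.87e5 Pa·s -> v = 0.46 µm/min."""
        v = units.visco_capillary_velocity(4.5, 5.87e5)
        assert v == pytest.approx(4.5e-3 / 5.87e5 * 1e6 * 60, rel=1e-12)
        assert v == pytest.approx(0.46, abs=5e-3)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            gen_fusion_sequence(-1.0, 5.87e5, 150.0, 5.0, 12, seed=0)
        with pytest.raises(ValueError):
            gen_fusion_sequence(4.5, 5.87e5, 150.0, 5.0, 4, seed=0)
        with pytest.raises(ValueError):
            gen_fusion_sequence(4.5, 5.87e5, 150.0, -5.0, 12, seed=0)

    def test_determinism_and_noise(self):
        a = gen_fusion_sequence(4.5, 5.87e5, 150.0, 5.0, 12, noise_sd=2.0, seed=3)
        b = gen_fusion_sequence(4.5, 5.87e5, 150.0, 5.0, 12, noise_sd=2.0, seed=3)
        c = gen_fusion_sequence(4.5, 5.87e5, 150.0, 5.0, 12, noise_sd=2.0, seed=4)
        np.testing.assert_array_equal(a.radii, b.radii)
        assert not np.array_equal(a.radii, c.radii)

    def test_rendered_frame_lens_geometry(self):
        img = render_fusion_frame(100.0, 40.0, pixel_size_um=2.0)
        # total area of the union of two discs with lens half-width 40
        d = 2 * math.sqrt(100.0 ** 2 - 40.0 ** 2)
        alpha = math.acos(d / 2 / 100.0)
        lens = 2 * 100.0 ** 2 * (alpha - math.sin(alpha) * math.cos(alpha))
        expected = 2 * math.pi * 100.0 ** 2 - lens
        area = img.sum() * 4.0
        assert area == pytest.approx(expected, rel=0.01)


class TestDoublet:
    @pytest.mark.parametrize(
        "gcm, gcc, theta",
        [(3.0, 0.0, 180.0), (3.0, 3.0, 120.0), (3.0, 6.0, 0.0)],
    )
    def test_young_angle(self, gcm, gcc, theta):
        d = gen_doublet(gcm, gcc, cell_radius=50.0)
        assert d.theta == pytest.approx(theta, abs=1e-9)

    def test_no_equilibrium_raises(self):
        with pytest.raises(ValueError):
            gen_doublet(3.0, 6.1)

    def test_equal_cell_areas(self):
        d = gen_doublet(3.0, 3.0, cell_radius=50.0)
        c = d.contour
        total = signed_area(c)
        assert total == pytest.approx(2 * math.pi * 50.0 ** 2, rel=5e-3)
        # mirror symmetry about the interface implies equal halves
        np.testing.assert_allclose(
            sorted(np.round(c[:, 0], 6)), sorted(np.round(-c[:, 0], 6)), atol=1e-5
        )

    def test_gamma_cc_zero_is_circle(self):
        d = gen_doublet(3.0, 0.0, cell_radius=50.0)
        r = np.hypot(d.contour[:, 0], d.contour[:, 1])  # arcs centred at origin
        assert np.ptp(r) < 1e-9 * r.mean()

    def test_contour_simple_ccw(self):
        d = gen_doublet(3.0, 3.0, cell_radius=50.0)
        assert signed_area(d.contour) > 0
        assert is_simple_closed(d.contour)


class TestRoughContour:
    def test_zero_amplitude_is_circle(self):
        c = gen_rough_contour(100.0, 0.0, seed=0)
        r = np.hypot(c[:, 0], c[:, 1])
        np.testing.assert_allclose(r, 100.0, rtol=1e-12)

    def test_rms_amplitude_exact(self):
        for seed in (0, 1):
            c = gen_rough_contour(100.0, 2.0, n_modes=8, seed=seed)
            r = np.hypot(c[:, 0], c[:, 1])
            rms = math.sqrt(np.mean((r - 100.0) ** 2))
            assert rms == pytest.approx(2.0, rel=2e-3)

    def test_single_mode_mean_abs_deviation(self):
        """mean |a cos| over a period is 2a/pi."""
        c = harmonic_contour(100.0, 3.0, mode=7)
        r = np.hypot(c[:, 0], c[:, 1])
        assert np.mean(np.abs(r - 100.0)) == pytest.approx(2 * 3.0 / math.pi, rel=1e-3)

    def test_seeds_differ_amplitude_matches(self):
        a = gen_rough_contour(100.0, 2.0, seed=0)
        b = gen_rough_contour(100.0, 2.0, seed=1)
        assert not np.allclose(a, b)

    def test_amplitude_bound(self):
        with pytest.raises(ValueError):
            gen_rough_contour(100.0, 100.0, seed=0)

    def test_simple_closed_ccw(self):
        c = gen_rough_contour(100.0, 4.0, seed=2)
        assert signed_area(c) > 0
        assert is_simple_closed(c)


class TestForceRelaxation:
    def test_relaxes_to_plateau(self):
        trace = gen_force_relaxation(10.0, 4.0, tau=60.0, duration=600.0)
        assert trace[-1, 1] == pytest.approx(4.0, rel=1e-4)
        assert trace[0, 1] == pytest.approx(10.0)

    def test_constant_trace(self):
        trace = gen_force_relaxation(4.0, 4.0, tau=60.0, duration=600.0)
        np.testing.assert_allclose(trace[:, 1], 4.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            gen_force_relaxation(1.0, 2.0, tau=60.0, duration=600.0)
        with pytest.raises(ValueError):
            gen_force_relaxation(2.0, 1.0, tau=-1.0, duration=600.0)
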