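"""Tensiometry pipeline: contour extraction, radii fit, plateau, sigma."""

import math

import numpy as np
import pytest

from aggmech.synthetic_data import (
    gen_compressed_aggregate,
    gen_compression_series,
    gen_force_relaxation,
)
from aggmech.tensiometry import (
    AggregateProfile,
    CompressionRecord,
    detect_plateau,
    extract_contour,
    fit_profile_radii,
    sigma_single,
    sigma_slope,
)

SPHERE_V_150 = 4.0 / 3.0 * math.pi * 150.0 ** 3


def _analyze(rec):
    profile = fit_profile_radii(rec.contour, rec.plate_gap)
    plateau = detect_plateau(rec.force_trace)
    return CompressionRecord(
        profile=profile, force_trace=rec.force_trace, plateau_force=plateau.force
    )


class TestExtractContour:
    def test_disc_radius(self):
        from skimage.draw import disk

        img = np.zeros((256, 256), dtype=np.uint8)
        rr, cc = disk((128, 128), 100.0)
        img[rr, cc] = 1
        contour = extract_contour(img, pixel_size_um=1.0)
        r = np.hypot(*(contour - contour.mean(axis=0)).T)
        assert r.mean() == pytest.approx(100.0, abs=0.5)

    def test_blank_image_raises(self):
        with pytest.raises(ValueError):
            extract_contour(np.zeros((64, 64)))

    def test_multiple_objects_raise(self):
        img = np.zeros((128, 128), dtype=np.uint8)
        img[10:40, 10:40] = 1
        img[80:110, 80:110] = 1
        with pytest.raises(ValueError):
            extract_contour(img)

    def test_area_round_trip_with_generator(self):
        from skimage.draw import polygon

        rec = gen_compressed_aggregate(4.5, SPHERE_V_150, 210.0, seed=0)
        px = 2.0
        shifted = rec.contour / px + 120.0  # contour in px units on the grid
        img = np.zeros((240, 240), dtype=np.uint8)
        rr, cc = polygon(shifted[:, 1], shifted[:, 0], shape=img.shape)
        img[rr, cc] = 1
        contour = extract_contour(img, pixel_size_um=px)
        area_in = abs(
            0.5 * np.sum(
                rec.contour[:, 0] * np.roll(rec.contour[:, 1], -1)
                - np.roll(rec.contour[:, 0], -1) * rec.contour[:, 1]
            )
        )
        x, y = contour[:, 0], contour[:, 1]
        area_out = abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert area_out == pytest.approx(area_in, rel=0.01)


class TestFitProfileRadii:
    def test_barrel_round_trip(self):
        rec = gen_compressed_aggregate(4.5, SPHERE_V_150, 210.0, seed=0)
        prof = fit_profile_radii(rec.contour, rec.plate_gap)
        assert prof.R2 == pytest.approx(rec.r2_um, rel=0.01)
        assert prof.R3 == pytest.approx(rec.r3_um, rel=0.01)

    def test_sphere_limit(self):
        rec = gen_compressed_aggregate(4.5, SPHERE_V_150, 300.0, seed=0)
        prof = fit_profile_radii(rec.contour, 300.0)
        assert prof.R2 == pytest.approx(150.0, rel=0.01)
        assert prof.R3 == pytest.approx(150.0, rel=0.01)

    def test_noisy_recovery_bias(self):
        errs = []
        for seed in range(50):
            rec = gen_compressed_aggregate(
                4.5, SPHERE_V_150, 210.0, noise_sd=0.5, seed=seed
            )
            prof = fit_profile_radii(rec.contour, rec.plate_gap)
            errs.append(prof.R2 / rec.r2_um - 1.0)
        assert abs(np.mean(errs)) < 0.02

    def test_non_convex_raises(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        # peanut: side walls concave at the equator
        r = 100.0 * (1 - 0.3 * np.cos(2 * t))
        contour = np.column_stack([r * np.cos(t), r * np.sin(t)])
        with pytest.raises(ValueError):
            fit_profile_radii(contour, plate_gap=float(np.ptp(contour[:, 1])))


class TestDetectPlateau:
    def test_exponential_trace(self):
        trace = gen_force_relaxation(10.0, 4.0, tau=60.0, duration=600.0)
        res = detect_plateau(trace)
        assert res.converged
        assert res.force == pytest.approx(4.0, rel=0.01)

    def test_constant_trace(self):
        trace = np.column_stack([np.arange(100.0), np.full(100, 2.5)])
        res = detect_plateau(trace)
        assert res.force == pytest.approx(2.5)
        assert res.converged

    def test_decreasing_trace_warns_but_returns(self):
        trace = np.column_stack([np.arange(100.0), 10.0 - 0.05 * np.arange(100.0)])
        with pytest.warns(UserWarning):
            res = detect_plateau(trace)
        assert not res.converged
        assert res.force > 0

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            detect_plateau(np.zeros((10, 2)))


class TestSigma:
    def test_sigma_single_zero_force(self):
        prof = AggregateProfile(np.zeros((20, 2)), R2=100.0, R3=100.0)
        assert sigma_single(0.0, prof) == 0.0

    def test_sigma_single_closed_form(self):
        """F = 0.5 µN, R2 = R3 = 100 µm -> sigma = 0.796 mN/m."""
        prof = AggregateProfile(np.zeros((20, 2)), R2=100.0, R3=100.0)
        expected = 0.5e-6 / (math.pi * (100e-6) ** 2 * 2e4) / 1e-3
        assert expected == pytest.approx(0.7957747, rel=1e-6)
        assert sigma_single(0.5, prof) == pytest.approx(expected, rel=1e-12)

    def test_round_trip_30pc_compression(self):
        rec = gen_compressed_aggregate(4.5, SPHERE_V_150, 210.0, seed=0)
        sigma = sigma_single(detect_plateau(rec.force_trace).force,
                             fit_profile_radii(rec.contour, rec.plate_gap))
        assert sigma == pytest.approx(4.5, rel=0.02)

    def test_successive_compressions_agree(self):
        recs = gen_compression_series(4.5, SPHERE_V_150, [0.25, 0.4], seed=0)
        sigmas = [
            sigma_single(detect_plateau(r.force_trace).force,
                         fit_profile_radii(r.contour, r.plate_gap))
            for r in recs
        ]
        assert abs(sigmas[0] - sigmas[1]) / sigmas[0] < 0.05

    def test_slope_equals_single_on_exact_profiles(self):
        """With exact shape parameters the slope matches any single record."""
        recs = []
        for r in gen_compression_series(4.5, SPHERE_V_150, [0.2, 0.3, 0.4], seed=0):
            prof = AggregateProfile(r.contour, R2=r.r2_um, R3=r.r3_um)
            recs.append(CompressionRecord(
                profile=prof, force_trace=r.force_trace,
                plateau_force=r.plateau_uN,
            ))
        slope, ci = sigma_slope(recs)
        single = sigma_single(recs[0].plateau_force, recs[0].profile)
        assert slope == pytest.approx(single, rel=1e-6)
        assert ci < 1e-6

    def test_slope_through_fitted_pipeline(self):
        recs = [
            _analyze(r)
            for r in gen_compression_series(
                4.5, SPHERE_V_150, [0.2, 0.3, 0.4], seed=0
            )
        ]
        slope, ci = sigma_slope(recs)
        assert slope == pytest.approx(4.5, rel=0.02)
        assert ci < 0.05

    def test_slope_requires_two_records(self):
        recs = [_analyze(gen_compressed_aggregate(4.5, SPHERE_V_150, 210.0, seed=0))]
        with pytest.raises(ValueError):
            sigma_slope(recs)

    def test_identical_abscissae_degenerate(self):
        rec = _analyze(gen_compressed_aggregate(4.5, SPHERE_V_150, 210.0, seed=0))
        with pytest.raises(ValueError):
            sigma_slope([rec, rec])

    def test_size_independence(self):
        """Recovered sigma is flat across a 3-fold radius range."""
        sigmas = []
        for radius in (90.0, 150.0, 270.0):
            vol = 4.0 / 3.0 * math.pi * radius ** 3
            recs = [
                _analyze(r)
                for r in gen_compression_series(4.5, vol, [0.25, 0.4], seed=1)
            ]
            sigmas.append(sigma_slope(recs)[0])
        assert np.ptp(sigmas) / np.mean(sigmas) < 0.02
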