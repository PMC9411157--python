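"""Costes thresholding, thresholded Pearson, line profiles and FWHM fits."""

import numpy as np
import pytest

from conftest import make_image
from tjmesh.coloc import (
    FWHM_FACTOR,
    costes_thresholds,
    extract_profile,
    fit_line_profile,
    pearson_above_threshold,
    polyline_length,
)
from tjmesh.synth import make_line_profile


def _costes_oracle(x, y):
    """Exhaustive scan over all candidate levels (slow reference)."""
    import math

    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).mean()
    syy = ((y - ym) ** 2).mean()
    sxy = ((x - xm) * (y - ym)).mean()
    a = (syy - sxx + math.hypot(syy - sxx, 2 * sxy)) / (2 * sxy)
    b = ym - a * xm
    cands = np.unique(x)[::-1]
    for cand in cands:
        t2 = a * cand + b
        sel = (x < cand) & (y < t2)
        if sel.sum() >= 2 and x[sel].std() > 0 and y[sel].std() > 0:
            if np.corrcoef(x[sel], y[sel])[0, 1] <= 0:
                return float(cand)
    return float(cands[-1])


class TestCostesThresholds:
    def test_identical_channels_walk_to_lowest_candidate(self, rng):
        x = rng.integers(0, 50, (20, 20)).astype(float)
        t1, t2, a, b = costes_thresholds(make_image(x), make_image(x.copy()))
        assert a == pytest.approx(1.0)
        assert b == pytest.approx(0.0, abs=1e-9)
        assert t1 == x.min()

    @pytest.mark.parametrize("seed", range(20))
    def test_independent_noise_contract(self, seed):
        # uncorrelated channels: either the global r is <= 0 and the
        # thresholds fall back to the channel minima, or the sampling noise
        # left r marginally positive and the walk stops at a candidate whose
        # below-threshold Pearson is <= 0
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 100, (30, 30))
        y = rng.uniform(0, 100, (30, 30))
        t1, t2, a, b = costes_thresholds(make_image(x), make_image(y))
        r_global = np.corrcoef(x.ravel(), y.ravel())[0, 1]
        if r_global <= 0 or a <= 0:
            assert t1 == x.min() and t2 == y.min()
        else:
            sel = (x.ravel() < t1) & (y.ravel() < t2)
            assert np.corrcoef(x.ravel()[sel], y.ravel()[sel])[0, 1] <= 0

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        x = rng.uniform(0, 20, (n, n))
        y = rng.uniform(0, 20, (n, n))
        blob = np.zeros((n, n))
        blob[8:18, 8:18] = rng.uniform(60, 100, (10, 10))
        x = x + blob
        y = y + 0.8 * blob
        t1, t2, a, b = costes_thresholds(make_image(x), make_image(y))
        assert t1 == pytest.approx(_costes_oracle(x.ravel(), y.ravel()))
        # below-threshold Pearson <= 0 at T1 but > 0 one candidate higher
        xr, yr = x.ravel(), y.ravel()
        sel = (xr < t1) & (yr < a * t1 + b)
        assert np.corrcoef(xr[sel], yr[sel])[0, 1] <= 0
        cands = np.unique(xr)
        nxt = cands[cands > t1][0]
        sel_up = (xr < nxt) & (yr < a * nxt + b)
        assert np.corrcoef(xr[sel_up], yr[sel_up])[0, 1] > 0

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError):
            costes_thresholds(make_image(np.ones((20, 20))),
                              make_image(np.ones((20, 20))))


class TestPearsonAboveThreshold:
    def test_identical_channels_give_unity(self, rng):
        x = rng.integers(0, 200, (25, 25)).astype(float)
        res = pearson_above_threshold(make_image(x), make_image(x.copy()))
        assert res.pearson_above_threshold == pytest.approx(1.0)

    def test_inverted_channel_reports_minus_one_via_fallback(self, rng):
        x = rng.integers(0, 200, (25, 25)).astype(float)
        y = x.max() - x
        res = pearson_above_threshold(make_image(x), make_image(y))
        assert res.fallback
        assert res.pearson_above_threshold == pytest.approx(-1.0)
        assert res.global_pearson == pytest.approx(-1.0)

    def test_affine_rescaling_invariance_on_fallback_path(self, rng):
        x = rng.uniform(0, 100, (25, 25))
        y = rng.uniform(0, 100, (25, 25))
        r1 = pearson_above_threshold(make_image(x), make_image(y))
        r2 = pearson_above_threshold(make_image(3.0 * x + 5), make_image(y))
        assert r1.pearson_above_threshold == pytest.approx(
            r2.pearson_above_threshold, abs=1e-10
        )


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        img = make_image(np.full((60, 60), 4.0))
        prof = extract_profile(img, ((10.0, 30.0), (50.0, 30.0)), width_px=10)
        np.testing.assert_allclose(prof.intensities, 4.0)
        assert np.all(np.diff(prof.positions_nm) > 0)

    def test_width_average_equals_mean_of_single_width_profiles(self, rng):
        img = make_image(rng.random((80, 80)) * 100)
        p0, p1 = (20.0, 40.0), (60.0, 40.0)
        wide = extract_profile(img, (p0, p1), width_px=10)
        singles = []
        for off in np.arange(10) - 4.5:
            # line along +x, normal is +y
            q0 = (p0[0], p0[1] + off)
            q1 = (p1[0], p1[1] + off)
            singles.append(extract_profile(img, (q0, q1), width_px=1).intensities)
        np.testing.assert_allclose(wide.intensities, np.mean(singles, axis=0),
                                   atol=1e-10)

    def test_line_leaving_image_rejected(self):
        img = make_image(np.ones((50, 50)))
        with pytest.raises(ValueError):
            extract_profile(img, ((40.0, 25.0), (70.0, 25.0)))

    def test_length_override_recentres(self):
        img = make_image(np.ones((100, 100)), pixel_size_nm=20.0)
        prof = extract_profile(img, ((30.0, 50.0), (70.0, 50.0)),
                               length_nm=300.0, width_px=1)
        # 300 nm at 20 nm/px = 15 px -> 16 samples
        assert prof.intensities.size == 16
        assert prof.positions_nm[-1] == pytest.approx(300.0)


class TestGaussianFit:
    def test_noiseless_profile_recovers_sigma_and_declared_factor(self):
        prof = make_line_profile(sigma_nm=56.7, amplitude=80.0, offset=5.0,
                                 noise_sd=0.0, n_points=61, spacing_nm=10.0)
        fit = fit_line_profile(prof)
        assert fit.converged
        assert fit.sigma_nm == pytest.approx(56.7, rel=1e-6)
        assert fit.fwhm_nm == pytest.approx(FWHM_FACTOR * 56.7, rel=1e-9)
        assert fit.fwhm_nm == pytest.approx(133.245, abs=1e-3)

    def test_constant_profile_does_not_converge(self):
        prof = make_line_profile(sigma_nm=50.0, amplitude=0.0, offset=3.0,
                                 noise_sd=0.0)
        fit = fit_line_profile(prof)
        assert not fit.converged

    def test_mean_recovery_under_noise(self):
        # 5% noise relative to amplitude; mean of fitted sigmas within 2%
        sigmas = []
        for seed in range(300):
            prof = make_line_profile(sigma_nm=25.0, amplitude=100.0,
                                     offset=10.0, noise_sd=5.0, n_points=41,
                                     spacing_nm=5.0, seed=seed)
            fit = fit_line_profile(prof)
            if fit.converged:
                sigmas.append(fit.sigma_nm)
        assert abs(np.mean(sigmas) - 25.0) / 25.0 < 0.02

    def test_too_few_samples_rejected(self):
        from tjmesh.coloc import LineProfile

        prof = LineProfile(np.arange(5.0), np.ones(5), ((0, 0), (0, 0)), 1)
        with pytest.raises(ValueError):
            fit_line_profile(prof)


class TestPolylineLength:
    def test_three_four_five_triangle(self):
        assert polyline_length([(0, 0), (3, 4)], 20.0) == pytest.approx(100.0)

    def test_collinear_midpoint_does_not_change_length(self):
        a = polyline_length([(0, 0), (2, 2), (4, 4)], 10.0)
        b = polyline_length([(0, 0), (4, 4)], 10.0)
        assert a == pytest.approx(b)

    def test_random_path_matches_stepwise_resummation(self, rng):
        pts = rng.random((10, 2)) * 50
        total = sum(
            float(np.hypot(*(pts[i + 1] - pts[i]))) for i in range(9)
        )
        assert polyline_length(pts, 18.9) == pytest.approx(total * 18.9)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            polyline_length([(1, 1)], 20.0)
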