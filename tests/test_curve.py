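"""Boundary binning, smoothing, spline fitting and optimum detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fluxresp import (
    PipelineConfig,
    ResponseCurve,
    SyntheticSiteConfig,
    bin_and_boundary,
    detect_optimum,
    fit_gam,
    generate_site,
    running_average,
    site_pipeline,
    tent_response,
)
from fluxresp.errors import CurveFitError


class TestBinAndBoundary:
    def test_interpolated_quantile_example(self):
        # bin [10.00, 10.05) holds ER {1, 3}: q90 = 1 + 0.9*2 = 2.8
        pts = bin_and_boundary([10.00, 10.02, 10.07], [1, 3, 2], 0.05, 0.9)
        assert list(pts["sm_center"].round(3)) == [10.025, 10.075]
        assert pts["er_boundary"].iloc[0] == pytest.approx(2.8)
        assert pts["er_boundary"].iloc[1] == pytest.approx(2.0)
        assert list(pts["n_obs"]) == [2, 1]

    def test_single_observation(self):
        pts = bin_and_boundary([12.3], [4.2], 0.05, 0.9)
        assert len(pts) == 1
        assert pts["er_boundary"].iloc[0] == pytest.approx(4.2)

    def test_identical_sm_one_bin(self):
        pts = bin_and_boundary([20.01] * 5, [1, 2, 3, 4, 5], 0.05, 0.9)
        assert len(pts) == 1
        assert pts["n_obs"].iloc[0] == 5

    def test_no_finite_pairs_empty(self):
        pts = bin_and_boundary([np.nan, np.nan], [1.0, 2.0], 0.05, 0.9)
        assert pts.empty

    def test_bin_edges_anchored_at_zero(self):
        # 10.0 sits exactly on an edge; float division must not leak it into
        # the lower bin
        pts = bin_and_boundary([10.0], [1.0], 0.05, 0.9)
        assert pts["sm_center"].iloc[0] == pytest.approx(10.025)

    @given(
        st.integers(10, 200),
        st.floats(0.5, 0.95),
        st.integers(0, 2**31 - 1),
    )
    def test_boundary_quantile_invariant(self, n, q, seed):
        """Within each bin the fraction of ER strictly above the boundary is
        at most (1 - q) + 1/n_obs."""
        rng = np.random.default_rng(seed)
        sm = rng.uniform(0, 5, n)
        er = rng.lognormal(0, 0.5, n)
        pts = bin_and_boundary(sm, er, 0.5, q)
        idx = np.floor(sm / 0.5 + 1e-9).astype(int)
        for _, row in pts.iterrows():
            k = int(np.floor(row["sm_center"] / 0.5))
            vals = er[idx == k]
            frac_above = (vals > row["er_boundary"]).mean()
            assert frac_above <= (1 - q) + 1.0 / len(vals) + 1e-12
            assert vals.min() <= row["er_boundary"] <= vals.max()

    def test_within_bin_screen_drops_extremes(self):
        er = [1.0, 1.1, 0.9, 1.05, 0.95, 50.0]
        no_screen = bin_and_boundary([5.01] * 6, er, 0.05, 0.9)
        screened = bin_and_boundary([5.01] * 6, er, 0.05, 0.9, screen_k=2.0)
        assert screened["n_obs"].iloc[0] == 5
        assert screened["er_boundary"].iloc[0] < no_screen["er_boundary"].iloc[0]

    def test_screen_skips_tiny_bins(self):
        pts = bin_and_boundary([5.01, 5.02], [1.0, 100.0], 0.05, 0.9, screen_k=2.0)
        assert pts["n_obs"].iloc[0] == 2


class TestRunningAverage:
    def _pts(self, er):
        n = len(er)
        return pd.DataFrame(
            {"sm_center": np.arange(n, dtype=float), "er_boundary": er, "n_obs": [1] * n}
        )

    def test_window3_means(self):
        out = running_average(self._pts([1, 2, 3, 4]), window=3)
        assert list(out["er_boundary"]) == [2.0, 3.0]
        assert list(out["sm_center"]) == [1.0, 2.0]

    def test_constant_series_unchanged_values(self):
        out = running_average(self._pts([5.0] * 6), window=3)
        assert len(out) == 4
        assert (out["er_boundary"] == 5.0).all()

    def test_window_one_is_identity(self):
        pts = self._pts([1.0, 7.0, 2.0])
        out = running_average(pts, window=1)
        pd.testing.assert_frame_equal(out, pts)

    def test_short_input_empty_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="fluxresp.curve"):
            out = running_average(self._pts([1.0, 2.0]), window=3)
        assert out.empty
        assert any("window" in r.message for r in caplog.records)

    @given(st.lists(st.floats(-10, 10), min_size=5, max_size=30))
    def test_output_length_and_means(self, er):
        pts = self._pts(er)
        out = running_average(pts, window=3)
        assert len(out) == len(er) - 2
        expected = np.convolve(er, np.ones(3) / 3, mode="valid")
        assert np.allclose(out["er_boundary"], expected, atol=1e-9)


def _curve_from_xy(x, y, **kw):
    pts = pd.DataFrame({"sm_center": x, "er_boundary": y, "n_obs": [10] * len(x)})
    return fit_gam(pts, **kw)


class TestFitGam:
    def test_parabola_recovered(self):
        x = np.linspace(10, 40, 80)
        y = 8 - 0.02 * (x - 25.0) ** 2
        curve = _curve_from_xy(x, y)
        assert curve.gam_r2 >= 0.99
        vertex = x[np.argmax(curve.gam_fitted)]
        assert abs(vertex - 25.0) <= (x[1] - x[0])  # within one grid step

    def test_constant_points_flat_fit(self):
        x = np.linspace(0, 10, 20)
        curve = _curve_from_xy(x, np.full(20, 3.0))
        assert curve.gam_r2 == pytest.approx(0.0)
        assert np.allclose(curve.gam_fitted, 3.0, atol=1e-6)

    def test_monotone_input_keeps_argmax_at_boundary(self):
        rng = np.random.default_rng(3)
        x = np.linspace(5, 45, 120)
        y = 0.1 * x + rng.normal(0, 0.02, x.size)
        curve = _curve_from_xy(x, y)
        assert np.argmax(curve.gam_fitted) == len(x) - 1

    def test_too_few_points_raises(self):
        with pytest.raises(CurveFitError):
            _curve_from_xy(np.arange(5.0), np.arange(5.0))

    def test_basis_reduced_for_few_points(self):
        x = np.linspace(0, 1, 8)
        curve = _curve_from_xy(x, -(x - 0.5) ** 2)
        assert len(curve.gam_fitted) == 8


def _manual_curve(fitted, x=None):
    n = len(fitted)
    x = np.arange(n, dtype=float) if x is None else np.asarray(x, float)
    pts = pd.DataFrame({"sm_center": x, "er_boundary": fitted, "n_obs": [10] * n})
    return ResponseCurve(points=pts, gam_fitted=np.asarray(fitted, float), gam_r2=0.9)


class TestDetectOptimum:
    def test_tent_detected_with_strong_slopes(self):
        rng = np.random.default_rng(0)
        x = np.linspace(10, 40, 100)
        y = tent_response(x, 25, 8, 0.3, 0.15) + rng.normal(0, 0.05, 100)
        curve = _curve_from_xy(x, y)
        res = detect_optimum(curve)
        assert res.detected
        assert abs(res.smer_opt - 25.0) <= 1.0
        assert res.p_below < 1e-3 and res.p_above < 1e-3
        assert res.sen_below > res.sen_above > 0

    def test_monotone_curve_rejected_as_boundary_max(self):
        res = detect_optimum(_manual_curve(np.arange(10.0)))
        assert not res.detected
        assert res.reason == "boundary_max"

    def test_too_few_points_above(self):
        fitted = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 4.5])
        res = detect_optimum(_manual_curve(fitted))
        assert not res.detected
        assert res.reason == "too_few_points"

    def test_nonadjacent_ties_abort(self):
        fitted = np.array([1.0, 5.0, 2.0, 5.0, 1.0])
        res = detect_optimum(_manual_curve(fitted))
        assert not res.detected
        assert res.reason == "multiple_maxima"

    def test_adjacent_ties_collapse_to_midpoint(self):
        fitted = np.array([1.0, 2.0, 3.0, 5.0, 5.0, 3.0, 2.0, 1.0])
        x = np.arange(8.0)
        pts = pd.DataFrame({"sm_center": x, "er_boundary": fitted, "n_obs": [10] * 8})
        curve = ResponseCurve(points=pts, gam_fitted=fitted, gam_r2=0.9)
        res = detect_optimum(curve)
        assert res.smer_opt == pytest.approx(3.5)

    def test_never_detects_at_first_or_last_point(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            fitted = rng.normal(size=12)
            res = detect_optimum(_manual_curve(fitted))
            if res.detected:
                assert 0 < np.argmax(fitted) < 11


class TestSitePipeline:
    def test_recovers_generator_truth(self, config):
        site, truth = generate_site(SyntheticSiteConfig(true_opt=20.0, seed=99))
        curve, res = site_pipeline(site, config)
        assert res.detected
        assert abs(res.smer_opt - 20.0) <= 2.0

    def test_monotone_site_not_detected(self, config):
        from fluxresp import generate_monotone_site

        site, truth = generate_monotone_site(
            SyntheticSiteConfig(seed=101), mode="truncated"
        )
        _, res = site_pipeline(site, config)
        assert not res.detected
        assert res.reason in ("boundary_max", "nonsig_above", "too_few_points")
        assert np.isnan(truth["true_opt"])

    def test_deterministic(self, default_site, config):
        site, _ = default_site
        _, r1 = site_pipeline(site, config)
        _, r2 = site_pipeline(site, config)
        assert r1 == r2

    def test_quality_empty_reported_as_outcome(self, config):
        from conftest import make_series

        s = make_series(n=20, er_qc=2)
        curve, res = site_pipeline(s, config)
        assert curve is None
        assert not res.detected
        assert res.reason == "empty_after_quality"


@pytest.fixture(scope="module")
def quiet_site():
    return generate_site(SyntheticSiteConfig(noise_sd_log=0.15, q10=1.0, seed=11))


class TestConfigurationStability:
    """Bin-width and quantile choices move the optimum by less than a point
    of soil moisture on a noise-controlled site."""

    def test_bin_width_robustness(self, quiet_site):
        site, truth = quiet_site
        opts = []
        for w in (0.01, 0.05, 0.1):
            _, res = site_pipeline(site, PipelineConfig(bin_width=w))
            assert res.detected
            opts.append(res.smer_opt)
        assert max(opts) - min(opts) <= 1.0

    def test_quantile_robustness(self, quiet_site):
        site, truth = quiet_site
        opts = []
        for q in (0.85, 0.90, 0.95):
            _, res = site_pipeline(site, PipelineConfig(quantile=q))
            assert res.detected
            opts.append(res.smer_opt)
        assert max(opts) - min(opts) <= 1.0
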