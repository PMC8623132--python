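"""Least-squares fitting, curve stripping, segmented regression, comparison."""

import numpy as np
import pytest

from decorpkin import (
    BiCompartmentParams,
    RetentionModel,
    bicompartment_blood,
    bicompartment_total,
    compare_models,
    fit_model,
    fit_two_phase,
    r_squared,
    sqrt_retention,
    SqrtLawParams,
    strip_initialize,
)
from decorpkin.exceptions import (
    ConfigError,
    DataValidationError,
    FitError,
    UndefinedRSquaredError,
)
from decorpkin.fitting import strip_initialize_arrays

from conftest import make_series


class TestRSquared:
    def test_perfect_and_null_predictions(self):
        obs = np.array([3.0, 1.0, 4.0, 1.5])
        assert r_squared(obs, obs) == pytest.approx(1.0)
        assert r_squared(obs, np.full(4, obs.mean())) == pytest.approx(0.0)

    def test_worse_than_mean_goes_negative(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, np.array([3.0, 2.0, 1.0])) < 0

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedRSquaredError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        obs = rng.normal(50, 10, 20)
        pred = obs + rng.normal(0, 2, 20)
        a, b = 3.7, -12.0
        assert r_squared(a * obs + b, a * pred + b) == pytest.approx(
            r_squared(obs, pred), rel=1e-12
        )


class TestStripInitialize:
    def test_recovers_exact_biexponential(self):
        t = np.arange(0.0, 12.0)
        y = 60.0 * np.exp(-2.0 * t) + 40.0 * np.exp(-0.1 * t)
        macro, info = strip_initialize_arrays(t, y, tail_points=4)
        assert not info["fallback"]
        assert macro.beta == pytest.approx(0.1, rel=0.01)
        assert macro.coeff_b == pytest.approx(40.0, rel=0.01)
        assert macro.alpha == pytest.approx(2.0, rel=0.01)
        assert macro.coeff_a == pytest.approx(60.0, rel=0.01)
        assert macro.alpha > macro.beta

    def test_monoexponential_data_flags_fallback(self):
        t = np.arange(0.0, 10.0)
        macro, info = strip_initialize_arrays(t, 100.0 * np.exp(-0.2 * t))
        assert info["fallback"]
        assert macro.alpha > macro.beta

    def test_too_few_points(self):
        with pytest.raises(DataValidationError):
            strip_initialize_arrays(np.arange(3.0), np.array([3.0, 2.0, 1.0]))

    def test_series_wrapper(self, noiseless_treated_series):
        macro, _ = strip_initialize(noiseless_treated_series, (0, 10))
        assert macro.alpha > macro.beta > 0


class TestFitModel:
    def test_noiseless_monoexp_recovery(self):
        t = np.arange(0.0, 11.0)
        series = make_series(t, 100.0 * np.exp(-0.3 * t))
        res = fit_model("monoexp", series)
        assert res.params["k"] == pytest.approx(0.3, abs=1e-6)
        assert res.params["r0"] == pytest.approx(100.0, rel=1e-6)
        assert res.r2 == pytest.approx(1.0)
        assert res.derived["t_half"] == pytest.approx(np.log(2) / 0.3, rel=1e-6)

    def test_noiseless_bicompartment_recovery(self, noiseless_treated_series):
        res = fit_model(
            "bicompartment", noiseless_treated_series,
            options={"observable": "blood"},
        )
        assert res.params["k_bd"] == pytest.approx(1.77, rel=1e-3)
        assert res.params["k_db"] == pytest.approx(1.21, rel=1e-3)
        assert res.params["k_e"] == pytest.approx(0.19, rel=1e-3)
        assert res.derived["t_half_e"] == pytest.approx(np.log(2) / 0.19, rel=1e-3)

    def test_monte_carlo_ke_bias_is_small(self):
        """Median relative error of k_e stays below 10% under 2% noise."""
        from decorpkin.simulate import default_truth, get_design, simulate_group

        design = get_design("exp2_high")
        errs = []
        for rep in range(40):
            truth = default_truth("exp2_high", noise_sigma=0.02, seed=7000 + rep)
            _, series = simulate_group(design, truth)
            res = fit_model("bicompartment", series,
                            options={"observable": "blood"}, seed=rep)
            errs.append(abs(res.params["k_e"] - 0.19) / 0.19)
        assert np.median(errs) < 0.10

    def test_too_few_points_is_design_error(self):
        series = make_series([0, 1, 2, 3], 100.0 * np.exp(-0.3 * np.arange(4.0)))
        with pytest.raises(FitError, match="points"):
            fit_model("bicompartment", series)

    def test_unknown_model_id(self, noiseless_treated_series):
        with pytest.raises(ConfigError):
            fit_model("triexp", noiseless_treated_series)

    def test_weighted_equals_unweighted_for_equal_sems(self):
        t = np.arange(0.0, 11.0)
        rng = np.random.default_rng(11)
        y = 100.0 * np.exp(-0.3 * t) * np.exp(rng.normal(0, 0.02, t.size))
        y[0] = 100.0
        series = make_series(t, y, sem=np.full(t.size, 2.0))
        a = fit_model("monoexp", series, weights="none")
        b = fit_model("monoexp", series, weights="inverse-sem")
        assert a.params["k"] == pytest.approx(b.params["k"], rel=1e-6)

    def test_results_object_api(self, noiseless_treated_series):
        model = RetentionModel(noiseless_treated_series, "monoexp", window=(2, 10))
        res = model.fit()
        assert res.n_obs == 9
        assert "std err" in res.summary()
        assert res.stderr["k"] >= 0
        np.testing.assert_allclose(
            res.predict(noiseless_treated_series.times[3:]),
            res.params["r0"]
            * np.exp(-res.params["k"] * noiseless_treated_series.times[3:]),
        )
        d = res.to_dict()
        assert d["model_id"] == "monoexp" and d["window"] == [2.0, 10.0]


def _piecewise_log_linear(t, break_day, s1, s2, start=100.0):
    """Continuous piecewise log-linear retention with a slope change."""
    t = np.asarray(t, dtype=float)
    logy = np.where(
        t <= break_day,
        np.log(start) + s1 * (t - t[0]),
        np.log(start) + s1 * (break_day - t[0]) + s2 * (t - break_day),
    )
    return np.exp(logy)


class TestTwoPhase:
    def test_recovers_constructed_breakpoint(self):
        t = np.arange(1.0, 11.0)
        series = make_series(t, _piecewise_log_linear(t, 2.5, -0.8, -0.1))
        seg = fit_two_phase(series)
        assert 2.0 < seg.breakpoint < 3.0
        assert seg.phase1.slope == pytest.approx(-0.8, abs=1e-6)
        assert seg.phase2.slope == pytest.approx(-0.1, abs=1e-6)
        assert seg.pooled_sse < 1e-12

    def test_recovers_delayed_style_breakpoint(self):
        t = np.arange(13.0, 24.0)
        series = make_series(t, _piecewise_log_linear(t, 17.0, -0.9, -0.05))
        seg = fit_two_phase(series)
        assert 16.0 < seg.breakpoint < 18.0

    def test_single_slope_degenerate_earliest_tie(self):
        t = np.arange(0.0, 9.0)
        series = make_series(t, 100.0 * np.exp(-0.25 * t))
        seg = fit_two_phase(series)
        assert seg.phase1.slope == pytest.approx(seg.phase2.slope, abs=1e-9)
        # flat SSE profile: the tie resolves to the earliest candidate
        assert seg.breakpoint == pytest.approx(1.5)

    def test_never_worse_than_single_phase(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 11.0)
        y = 100.0 * np.exp(-0.4 * t) * np.exp(rng.normal(0, 0.05, t.size))
        y[0] = 100.0
        series = make_series(t, y)
        seg = fit_two_phase(series)
        slope, intercept = np.polyfit(t, np.log(series.mean_retention), 1)
        single_sse = np.sum((np.log(series.mean_retention) - slope * t - intercept) ** 2)
        assert seg.pooled_sse <= single_sse + 1e-12

    def test_nonpositive_retention_named(self):
        series = make_series([0, 1, 2, 3, 4], [100, 50, 25, 12, 6])
        series.mean_retention[3] = -1.0
        with pytest.raises(DataValidationError, match="day 3"):
            fit_two_phase(series)

    def test_min_points_contract(self):
        series = make_series([0, 1, 2], [100, 50, 25])
        with pytest.raises(DataValidationError):
            fit_two_phase(series, min_points_per_phase=2)


class TestCompareModels:
    def test_true_model_wins_at_zero_noise(self):
        t = np.arange(0.0, 11.0)
        series = make_series(t, 100.0 * np.exp(-0.3 * t))
        cmp_ = compare_models(series, ["sqrtlaw", "monoexp"])
        assert cmp_.ranking[0] == "monoexp"
        entry = {e["model_id"]: e for e in cmp_.entries}["monoexp"]
        assert entry["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_sqrt_truth_prefers_sqrtlaw(self):
        t = np.arange(1.0, 11.0)
        series = make_series(
            t, sqrt_retention(SqrtLawParams(110.0, 20.0), t), ref_index=0
        )
        cmp_ = compare_models(series, ["sqrtlaw", "monoexp"])
        assert cmp_.ranking[0] == "sqrtlaw"

    def test_single_model(self, noiseless_treated_series):
        cmp_ = compare_models(noiseless_treated_series, ["monoexp"])
        assert cmp_.ranking == ["monoexp"]

    def test_unknown_id_fails_fast(self, noiseless_treated_series):
        with pytest.raises(ConfigError):
            compare_models(noiseless_treated_series, ["monoexp", "nope"])

    def test_partial_comparison_on_failure(self):
        t = np.arange(0.0, 4.0)
        series = make_series(t, 100.0 * np.exp(-0.3 * t))
        cmp_ = compare_models(series, ["monoexp", "bicompartment"])
        assert "bicompartment" in cmp_.failures
        assert cmp_.ranking == ["monoexp"]
        assert "FAILED" in cmp_.summary()


@pytest.mark.parametrize(
    "model_id,truth_fn,options",
    [
        ("monoexp", lambda t: 100.0 * np.exp(-0.3 * t), None),
        (
            "biexp_macro",
            lambda t: 62.0 * np.exp(-3.1 * t) + 38.0 * np.exp(-0.074 * t),
            None,
        ),
        (
            "bicompartment",
            lambda t: bicompartment_total(
                BiCompartmentParams(0.8, 0.5, 0.3, 100.0), t
            ),
            None,
        ),
        ("sqrtlaw", lambda t: 120.0 - 25.0 * np.sqrt(t), None),
        ("diffusion", lambda t: 120.0 - 25.0 * np.sqrt(t), None),
    ],
)
def test_zero_noise_self_recovery(model_id, truth_fn, options):
    """Fitting data generated by a registered model returns a perfect fit."""
    t = np.arange(0.0, 11.0) if model_id != "sqrtlaw" else np.arange(1.0, 11.0)
    if model_id == "diffusion":
        t = np.arange(1.0, 11.0)
    y = truth_fn(t)
    series = make_series(t, y, ref_index=0)
    scale = 100.0 / y[0]
    res = fit_model(model_id, series, options=options, seed=2)
    pred = res.predict(t)
    np.testing.assert_allclose(pred, y * scale, rtol=1e-4, atol=1e-4)
    assert res.r2 == pytest.approx(1.0, abs=1e-7)
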