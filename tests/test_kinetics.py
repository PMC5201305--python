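import math

import numpy as np
import pandas as pd
import pytest

from demicell.errors import DegenerateDataError, ParameterError
from demicell.kinetics import (
    LN2,
    BootstrapConfig,
    GrowthRateModel,
    background_subtract,
    bootstrap_medians,
    estimate_half_life,
    evaluate_growth_model,
    fit_decay,
    fit_growth_model,
    stratified_half_lives,
)
from demicell.synthdata import ChaseSpec, Subpopulation, generate_chase

CHASE_TIMES = (0, 1, 2, 4, 8, 16, 32, 64)


def chase(t_half, seed, n=500, cv=0.3, background=0.0):
    return generate_chase(
        ChaseSpec(
            time_points_min=CHASE_TIMES,
            n_cells_per_timepoint=n,
            subpopulations=(Subpopulation("all", 1.0, t_half),),
            cell_noise_cv=cv,
            background_level=background,
            seed=seed,
        )
    )


def two_pop_chase(t_half_neg, t_half_pos, seed, n=500):
    return generate_chase(
        ChaseSpec(
            time_points_min=CHASE_TIMES,
            n_cells_per_timepoint=n,
            subpopulations=(
                Subpopulation("no_cluster", 0.5, t_half_neg, cluster=False),
                Subpopulation("cluster", 0.5, t_half_pos, cluster=True),
            ),
            cell_noise_cv=0.3,
            seed=seed,
        )
    )


class TestBackgroundSubtract:
    def test_simple(self):
        out, n = background_subtract(np.array([100.0]), 10.0)
        assert out[0] == 90.0 and n == 0

    def test_floor(self):
        out, n = background_subtract(np.array([5.0, 20.0]), 10.0)
        assert out.tolist() == [0.0, 10.0]
        assert n == 1

    def test_all_below_background_warns(self):
        with pytest.warns(UserWarning, match="all zero"):
            background_subtract(np.array([1.0, 2.0]), 10.0)

    def test_negative_background_rejected(self):
        with pytest.raises(ParameterError):
            background_subtract(np.array([1.0]), -1.0)

    def test_subtraction_removes_half_life_bias(self):
        bg = 100.0
        df = chase(10.0, seed=2, background=bg)
        conf = BootstrapConfig(seed=0)
        biased = estimate_half_life(df, conf).t_half
        corrected = df.copy()
        corrected["fluorescence"], _ = background_subtract(
            corrected["fluorescence"].to_numpy(), bg
        )
        unbiased = estimate_half_life(corrected, conf).t_half
        assert abs(unbiased - 10.0) < 1.0
        assert biased > unbiased + 1.0  # additive background inflates t_half


class TestBootstrapMedians:
    def test_constant_values(self):
        df = pd.DataFrame({"time_min": [0.0] * 10 + [1.0] * 10, "fluorescence": 7.0})
        with pytest.warns(UserWarning, match="resampling"):
            out = bootstrap_medians(df, BootstrapConfig(seed=1))
        assert np.allclose(out["median"], 7.0)
        assert np.allclose(out["sd"], 0.0)

    def test_seeded_determinism(self):
        df = chase(10.0, seed=5)
        a = bootstrap_medians(df, BootstrapConfig(seed=9))
        b = bootstrap_medians(df, BootstrapConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_lognormal_sd_matches_analytic(self):
        # analytic approximation: sd(median) ~ 1 / (2 sqrt(n) f(median))
        rng = np.random.default_rng(3)
        vals = rng.lognormal(mean=1.0, sigma=0.5, size=2000)
        df = pd.DataFrame({"time_min": 0.0, "fluorescence": vals})
        df = pd.concat([df, df.assign(time_min=1.0)], ignore_index=True)
        conf = BootstrapConfig(n_rounds=50, n_cells_per_round=500, seed=4)
        out = bootstrap_medians(df, conf)
        med = math.exp(1.0)
        f_med = math.exp(-(0.0**2) / (2 * 0.25)) / (med * 0.5 * math.sqrt(2 * math.pi))
        analytic = 1.0 / (2 * math.sqrt(500) * f_med)
        assert analytic / 2 < out["sd"].iloc[0] < analytic * 2

    def test_empty_time_point_error(self):
        df = pd.DataFrame({"time_min": [], "fluorescence": []})
        df = pd.concat([df, pd.DataFrame({"time_min": [0.0], "fluorescence": [np.nan]})])
        df = df.dropna()
        with pytest.raises((DegenerateDataError, Exception)):
            estimate_half_life(df, BootstrapConfig(seed=0))


class TestFitDecay:
    def test_exact_exponential(self):
        t = np.array(CHASE_TIMES, dtype=float)
        y = 100.0 * np.exp(-0.0693147 * t)
        fit = fit_decay(t, y)
        assert fit.t_half == pytest.approx(10.0, abs=1e-5)
        assert fit.t_half * fit.lam == pytest.approx(LN2, rel=1e-12)

    def test_constant_flagged_infinite(self):
        t = np.array(CHASE_TIMES, dtype=float)
        fit = fit_decay(t, np.full_like(t, 5.0))
        assert fit.non_decaying
        assert math.isinf(fit.t_half)

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            fit_decay([0, 1], [1.0, 0.5])

    def test_recovery_at_10_9_min(self):
        estimates = [
            estimate_half_life(chase(10.9, seed=s), BootstrapConfig(seed=1000 + s)).t_half
            for s in range(20)
        ]
        med = float(np.median(estimates))
        assert abs(med - 10.9) / 10.9 < 0.10

    def test_time_axis_stretch_scales_half_life(self):
        t = np.array(CHASE_TIMES, dtype=float)
        y = np.exp(-LN2 / 8.0 * t)
        base = fit_decay(t, y).t_half
        stretched = fit_decay(3.0 * t, y).t_half
        assert stretched == pytest.approx(3.0 * base, rel=1e-6)

    def test_half_life_lambda_identity(self):
        for t_half in (2.5, 4.6, 10.9, 22.4):
            t = np.array(CHASE_TIMES, dtype=float)
            fit = fit_decay(t, np.exp(-LN2 / t_half * t))
            assert fit.t_half * fit.lam == pytest.approx(LN2, rel=1e-12)


class TestEstimateHalfLife:
    def test_seed_stability(self):
        df = chase(10.0, seed=7)
        fits = [estimate_half_life(df, BootstrapConfig(seed=s)).t_half for s in range(6)]
        sd = estimate_half_life(df, BootstrapConfig(seed=0)).bootstrap_sd
        assert np.ptp(fits) < 6 * sd  # across seeds, spread < a few bootstrap sd

    def test_bootstrap_sd_positive(self):
        fit = estimate_half_life(chase(10.0, seed=8), BootstrapConfig(seed=1))
        assert fit.bootstrap_sd > 0


class TestStratified:
    def test_null_case_same_half_life(self):
        df = two_pop_chase(9.0, 9.0, seed=3)
        out = stratified_half_lives(df, BootstrapConfig(seed=5))
        a, b = out[False], out[True]
        spread = math.hypot(a.bootstrap_sd, b.bootstrap_sd)
        assert abs(a.t_half - b.t_half) < 4 * spread

    def test_recovery_and_ordering(self):
        ests = {False: [], True: []}
        for s in range(8):
            out = stratified_half_lives(two_pop_chase(4.6, 16.1, seed=s),
                                        BootstrapConfig(seed=100 + s))
            for k in (False, True):
                ests[k].append(out[k].t_half)
        neg, pos = np.median(ests[False]), np.median(ests[True])
        assert abs(neg - 4.6) / 4.6 < 0.15
        assert abs(pos - 16.1) / 16.1 < 0.15
        assert pos > neg

    def test_shuffled_flags_collapse_difference(self):
        rng = np.random.default_rng(11)
        df = two_pop_chase(4.6, 16.1, seed=21)
        shuffled = df.copy()
        shuffled["cluster_flag"] = rng.permutation(shuffled["cluster_flag"].to_numpy())
        out = stratified_half_lives(shuffled, BootstrapConfig(seed=2))
        a, b = out[False].t_half, out[True].t_half
        assert 4.6 < a < 16.1 and 4.6 < b < 16.1
        assert abs(a - b) < 0.25 * (16.1 - 4.6)

    def test_missing_time_point_skips_stratum(self):
        df = two_pop_chase(5.0, 15.0, seed=4)
        df = df[~((df.cluster_flag) & (df.time_min == 64.0))]
        with pytest.warns(UserWarning, match="skipped"):
            out = stratified_half_lives(df, BootstrapConfig(seed=0))
        assert True not in out and False in out


class TestGrowthModel:
    def test_printed_values_at_mu_055(self):
        assert round(evaluate_growth_model(GrowthRateModel(-2.0, 0.1, 2.4), 0.55), 1) == 6.4
        assert round(evaluate_growth_model(GrowthRateModel(-5.2, 3.3, 2.2), 0.55), 1) == 11.5

    def test_constant_model(self):
        model = GrowthRateModel(0.0, 0.0, 1.5)
        for mu in (0.0, 0.3, 1.2):
            assert evaluate_growth_model(model, mu) == pytest.approx(math.exp(1.5))

    def test_negative_mu_rejected(self):
        with pytest.raises(ParameterError):
            evaluate_growth_model(GrowthRateModel(0, 0, 1), -0.1)

    def test_exact_interpolation_three_points(self):
        truth = GrowthRateModel(-2.3, 0.6, 2.7)
        pts = [(mu, evaluate_growth_model(truth, mu)) for mu in (0.11, 0.51, 0.80)]
        fit = fit_growth_model(pts)
        assert fit.a == pytest.approx(truth.a, abs=1e-6)
        assert fit.b == pytest.approx(truth.b, abs=1e-6)
        assert fit.c == pytest.approx(truth.c, abs=1e-6)

    def test_flat_line(self):
        pts = [(mu, math.exp(2.0)) for mu in (0.1, 0.5, 0.9)]
        fit = fit_growth_model(pts)
        assert fit.a == pytest.approx(0.0, abs=1e-9)
        assert fit.b == pytest.approx(0.0, abs=1e-9)
        assert fit.c == pytest.approx(2.0, abs=1e-9)

    def test_noisy_regression_recovery(self):
        rng = np.random.default_rng(6)
        truth = GrowthRateModel(-2.3, 0.6, 2.7)
        mus = np.linspace(0.1, 0.9, 10)
        noise_sd = 0.05
        pts = [
            (mu, math.exp(math.log(evaluate_growth_model(truth, mu)) + rng.normal(0, noise_sd)))
            for mu in mus
        ]
        fit = fit_growth_model(pts)
        pred = np.array([math.log(evaluate_growth_model(fit, mu)) for mu in mus])
        target = np.array([math.log(evaluate_growth_model(truth, mu)) for mu in mus])
        rmse = np.sqrt(np.mean((pred - target) ** 2))
        assert rmse < 2 * noise_sd

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            fit_growth_model([(0.1, 10.0), (0.5, 12.0)])


@pytest.mark.parametrize("t_half", [2.5, 4.6, 6.2, 7.1, 10.9, 16.1, 19.7, 22.4])
def test_recovery_suite(t_half):
    """Median absolute recovery error < 10% at n=500 cells/time point."""
    errors = []
    for s in range(20):
        fit = estimate_half_life(chase(t_half, seed=s * 7 + 1), BootstrapConfig(seed=s))
        errors.append(abs(fit.t_half - t_half) / t_half)
    assert float(np.median(errors)) < 0.10
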