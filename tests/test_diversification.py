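"""Diversification likelihoods, ML fits, AIC selection and the shift test."""

import numpy as np
import pytest
from scipy import optimize

from bathyrad import BranchingTimes
from bathyrad.diversification import (
    aic,
    div_loglik,
    fit_birth_death,
    fit_div_model,
    fit_pure_birth,
    fit_weibull_window,
    fit_yule_2rate,
    fit_yule_3rate,
    fits_to_dataframe,
    loglik_birth_death,
    loglik_pure_birth,
    loglik_weibull_window,
    loglik_yule_multirate,
    model_selection_table,
    shift_test,
)
from bathyrad.simulate import (
    RateInterval,
    SimConfig,
    constant_rate_config,
    mussel_preset,
    simulate_branching_times,
)

from oracles import quadrature_pure_birth_family, quadrature_birth_death


def random_bt(rng, n=9, T=30.0, lam=0.1):
    return simulate_branching_times(constant_rate_config(T, lam, n_tips=n), rng)


class TestLoglik:
    def test_pure_birth_hand_computed(self, toy_bt):
        lam = 2 / 29
        expected = np.log(2 * lam) + np.log(3 * lam) - lam * 29
        assert loglik_pure_birth(toy_bt, lam) == pytest.approx(expected, abs=1e-12)

    def test_birth_death_reduces_to_pure_birth(self, rng):
        bt = random_bt(rng)
        lam = 0.09
        assert loglik_birth_death(bt, lam, 1e-14) == pytest.approx(
            loglik_pure_birth(bt, lam), abs=1e-9
        )

    def test_degenerate_multirate_equals_constant(self, rng):
        bt = random_bt(rng)
        lam = 0.07
        assert loglik_yule_multirate(bt, [20.0, 10.0], [lam, lam, lam]) == (
            pytest.approx(loglik_pure_birth(bt, lam), abs=1e-9)
        )

    def test_quadrature_oracle_all_models(self, rng):
        """Closed-form likelihoods agree with adaptive quadrature of the
        event-intensity integral on small trees."""
        bt = random_bt(rng, n=8)
        cases = [
            ("pure_birth", {"r1": 0.08}, lambda t, N: 0.08, ()),
            ("DDL", {"r1": 0.2, "k": 15.0}, lambda t, N: 0.2 * (1 - N / 15.0), ()),
            ("DDX", {"r1": 0.1, "xp": 0.4}, lambda t, N: 0.1 * N ** -0.4, ()),
            (
                "yule_2rate",
                {"r1": 0.02, "r2": 0.11, "s1": 12.0},
                lambda t, N: 0.02 if t >= 12.0 else 0.11,
                (12.0,),
            ),
            (
                "weibull_decline",
                {"eta": 18.0, "beta": 1.5, "window_start": bt.crown},
                lambda t, N: (1.5 / 18.0) * (t / 18.0) ** 0.5,
                (),
            ),
        ]
        for name, params, rate, brk in cases:
            expected = quadrature_pure_birth_family(bt, rate, brk)
            assert div_loglik(bt, name, params) == pytest.approx(
                expected, abs=1e-6
            ), name
        r, a = 0.06, 0.35
        lam = r / (1 - a)
        assert loglik_birth_death(bt, r, a) == pytest.approx(
            quadrature_birth_death(bt, lam, a * lam), abs=1e-6
        )


class TestFits:
    def test_closed_form_yule_mle(self, toy_bt):
        fit = fit_pure_birth(toy_bt)
        assert fit.params["r1"] == pytest.approx(2 / 29, abs=1e-12)

    def test_yule_mle_matches_grid_search(self, rng):
        bt = random_bt(rng, n=12)
        fit = fit_pure_birth(bt)
        grid = np.linspace(1e-4, 1.0, 20001)
        lnls = [loglik_pure_birth(bt, g) for g in grid]
        assert abs(fit.params["r1"] - grid[int(np.argmax(lnls))]) < 1e-4

    def test_nesting_monotonicity(self, rng):
        for _ in range(10):
            bt = random_bt(rng, n=25, T=50, lam=0.07)
            l_pb = fit_pure_birth(bt).lnl
            l_bd = fit_birth_death(bt).lnl
            l_y2 = fit_yule_2rate(bt).lnl
            l_y3 = fit_yule_3rate(bt).lnl
            assert l_bd >= l_pb - 1e-6
            assert l_y2 >= l_pb - 1e-6
            assert l_y3 >= l_y2 - 1e-6

    def test_multirate_profile_matches_naive_enumeration(self, rng):
        """The vectorized profile must agree with a naive loop that, for
        every candidate shift age (and pair of ages), plugs closed-form
        per-segment rate MLEs into the full likelihood."""
        bt = random_bt(rng, n=14, T=40, lam=0.09)
        cand = bt.ages[1:]

        def naive_best(breaks_list):
            best = -np.inf
            for breaks in breaks_list:
                E, LT = [], []
                bounds = [np.inf] + list(breaks) + [0.0]
                for m in range(len(breaks) + 1):
                    older, younger = bounds[m], bounds[m + 1]
                    E.append(np.sum((cand >= younger) & (cand < older)))
                    # lineage-time by brute-force integration on a fine grid
                    grid = np.linspace(younger, min(older, bt.crown), 40001)
                    N = 1 + np.searchsorted(-bt.ages, -grid, side="left")
                    LT.append(np.trapezoid(N, grid))
                rates = [e / l if l > 0 else 0.0 for e, l in zip(E, LT)]
                if any(r == 0 and e > 0 for r, e in zip(rates, E)):
                    continue
                best = max(best, loglik_yule_multirate(bt, breaks, rates))
            return best

        fit2 = fit_yule_2rate(bt)
        assert fit2.lnl == pytest.approx(
            naive_best([[s] for s in cand]), abs=1e-3
        )
        pairs = [[a, b] for a in cand for b in cand if a > b]
        fit3 = fit_yule_3rate(bt)
        assert fit3.lnl == pytest.approx(naive_best(pairs), abs=1e-3)

    def test_fit_reports_consistent_likelihood(self, rng):
        """Every fitted model's stored lnL must equal the likelihood function
        evaluated at its own fitted parameters."""
        bt = random_bt(rng, n=18, T=40, lam=0.08)
        for fit in model_selection_table(bt):
            assert fit.lnl == pytest.approx(
                div_loglik(bt, fit.name, fit.params), abs=1e-6
            ), fit.name

    def test_yule_rate_recovery(self, rng):
        lams = []
        for _ in range(500):
            bt = simulate_branching_times(
                constant_rate_config(85.0, 0.05, n_tips=62), rng
            )
            lams.append(fit_pure_birth(bt).params["r1"])
        assert np.mean(lams) == pytest.approx(0.05, rel=0.10)

    def test_three_rate_shift_age_recovery(self, rng):
        s1s, s2s = [], []
        for _ in range(100):
            bt = simulate_branching_times(mussel_preset(62), rng)
            fit = fit_yule_3rate(bt)
            s1s.append(fit.params["s1"])
            s2s.append(fit.params["s2"])
        assert abs(np.median(s1s) - 41.2) < 5.0
        assert abs(np.median(s2s) - 33.8) < 5.0


class TestAic:
    @pytest.mark.parametrize(
        "lnl,k,expected",
        [(-54.49, 1, 111.0), (-54.44, 2, 112.9), (-54.45, 2, 112.9),
         (-54.03, 2, 112.1), (-50.30, 3, 106.6), (-44.29, 5, 98.6),
         (0.0, 0, 0.0)],
    )
    def test_aic_values(self, lnl, k, expected):
        assert aic(lnl, k)[0] == pytest.approx(expected, abs=0.05)

    def test_aicc_correction_and_domain(self):
        a, ac = aic(-10.0, 2, n_obs=10)
        assert ac == pytest.approx(a + 2 * 2 * 3 / 7)
        with pytest.raises(ValueError):
            aic(-10.0, 2, n_obs=3)

    def test_model_fit_identity(self, rng):
        bt = random_bt(rng, n=15)
        for fit in model_selection_table(bt):
            assert fit.aic == pytest.approx(-2 * fit.lnl + 2 * fit.k, abs=1e-9)


class TestModelSelection:
    def test_best_daic_is_zero(self, rng):
        fits = model_selection_table(random_bt(rng, n=20))
        assert min(f.daic for f in fits) == 0.0
        assert all(f.daic >= 0 for f in fits)

    def test_constant_rate_data_prefers_pure_birth(self, rng):
        # small-sample-corrected criterion: the shift models profile over many
        # candidate break ages, so AICc is the right yardstick here
        wins = 0
        nrep = 200
        for _ in range(nrep):
            bt = random_bt(rng, n=30, T=40, lam=0.08)
            fits = model_selection_table(bt)
            best = min(fits, key=lambda f: aic(f.lnl, f.k, bt.n - 1)[1])
            if best.name == "pure_birth":
                wins += 1
        assert wins > nrep / 2

    def test_dataframe_shape(self, rng):
        df = fits_to_dataframe(model_selection_table(random_bt(rng, n=15)))
        assert list(df["model"]) == [
            "pure_birth", "birth_death", "DDL", "DDX", "yule_2rate",
            "yule_3rate",
        ]
        assert {"L", "AIC", "dAIC", "type"} <= set(df.columns)


class TestWeibullWindow:
    def test_shape_one_is_constant_rate(self, rng):
        bt = random_bt(rng, n=15)
        assert loglik_weibull_window(bt, 1 / 0.08, 1.0, bt.crown) == (
            pytest.approx(loglik_pure_birth(bt, 0.08), abs=1e-9)
        )

    def test_full_window_equals_unwindowed(self, rng):
        bt = random_bt(rng, n=15)
        wfit_full, cfit_full, _, _ = fit_weibull_window(bt, bt.crown)
        assert cfit_full.lnl == pytest.approx(fit_pure_birth(bt).lnl, abs=1e-9)
        wfit_none, _, _, _ = fit_weibull_window(bt)
        assert wfit_full.lnl == pytest.approx(wfit_none.lnl, abs=1e-9)

    def test_decelerating_rates_recover_beta_above_one(self, rng):
        config = SimConfig(
            crown_age=40.0,
            schedule=[
                RateInterval(40.0, 25.0, 0.20),
                RateInterval(25.0, 10.0, 0.08),
                RateInterval(10.0, 0.0, 0.02),
            ],
            n_tips=40,
        )
        hits = 0
        for _ in range(50):
            bt = simulate_branching_times(config, rng)
            wfit, _, _, _ = fit_weibull_window(bt)
            hits += wfit.params["beta"] > 1
        assert hits > 40

    def test_too_few_events_in_window(self, toy_bt):
        with pytest.raises(ValueError, match="< 3"):
            fit_weibull_window(toy_bt, 1.0)


class TestShiftTest:
    def test_p_value_definition_and_reproducibility(self, rng):
        bt = random_bt(rng, n=25, T=40, lam=0.08)
        res = shift_test(bt, replicates=199, seed=11)
        res2 = shift_test(bt, replicates=199, seed=11)
        assert res.p_value == res2.p_value
        expected = (1 + np.sum(res.null_statistics >= res.statistic)) / 200
        assert res.p_value == pytest.approx(expected)

    def test_power_against_strong_burst(self, rng):
        """A pronounced mid-history burst is detected reliably; at the
        mussel-preset burst strength the statistic is still stochastically
        inflated relative to the constant-rate null."""
        strong = SimConfig(
            crown_age=85.0,
            schedule=[
                RateInterval(85.0, 41.2, 0.01),
                RateInterval(41.2, 33.8, 0.8),
                RateInterval(33.8, 0.0, 0.05),
            ],
            n_tips=62,
        )
        ps = []
        for _ in range(20):
            bt = simulate_branching_times(strong, rng)
            res = shift_test(
                bt, replicates=199, seed=rng,
                constant_names=("pure_birth",),
                variable_names=("yule_2rate", "yule_3rate"),
            )
            ps.append(res.p_value)
        assert np.mean(np.asarray(ps) <= 0.05) >= 0.8
        preset_stats, null_stats = [], []
        for _ in range(15):
            bt = simulate_branching_times(mussel_preset(62), rng)
            preset_stats.append(
                shift_test(bt, replicates=100, seed=rng,
                           constant_names=("pure_birth",),
                           variable_names=("yule_2rate", "yule_3rate")).statistic
            )
            bt0 = random_bt(rng, n=62, T=85.0, lam=0.04)
            null_stats.append(
                shift_test(bt0, replicates=100, seed=rng,
                           constant_names=("pure_birth",),
                           variable_names=("yule_2rate", "yule_3rate")).statistic
            )
        assert np.median(preset_stats) > np.median(null_stats)

    def test_subsampled_null_still_runs(self, rng):
        bt = random_bt(rng, n=30, T=40, lam=0.08)
        res = shift_test(
            bt, replicates=100, fraction_missing=0.25, seed=rng,
            constant_names=("pure_birth",),
            variable_names=("yule_2rate",),
        )
        assert 0 < res.p_value <= 1
        assert res.fraction_missing == 0.25
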