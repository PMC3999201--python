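import json

import numpy as np
import pytest

from lineaburst import simdata, treekit
from lineaburst.divshift import (RateFit, _bd_loglik, critical_delta_aic,
                                 delta_aic_rc, ensemble_shift_analysis,
                                 fit_bd_constant, fit_pure_birth,
                                 fit_yule_k_rate, magallon_sanderson)
from lineaburst.treekit import BranchingTimes, branching_times
from oracles import pure_birth_mle_numeric


class TestPureBirth:
    def test_hand_example(self, toy_chronogram):
        bt = branching_times(toy_chronogram)
        fit = fit_pure_birth(bt)
        assert bt.lineage_time() == pytest.approx(29.0)
        assert fit.params["lambda"] == pytest.approx(2 / 29)
        assert fit.aic == pytest.approx(-2 * fit.logL + 2)

    def test_scale_equivariance(self, toy_chronogram):
        bt = branching_times(toy_chronogram)
        doubled = BranchingTimes(bt.ages * 2)
        assert fit_pure_birth(doubled).params["lambda"] == pytest.approx(
            fit_pure_birth(bt).params["lambda"] / 2)

    def test_closed_form_equals_numeric_maximizer(self, random_trees):
        for ch in random_trees:
            bt = branching_times(ch)
            lam_num, _ = pure_birth_mle_numeric(bt)
            assert fit_pure_birth(bt).params["lambda"] == pytest.approx(
                lam_num, abs=1e-8)

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            fit_pure_birth(BranchingTimes(np.array([5.0])))


class TestBdConstant:
    def test_zero_extinction_limit_equals_pure_birth(self, random_trees):
        for ch in random_trees:
            bt = branching_times(ch)
            pb = fit_pure_birth(bt)
            ll0 = _bd_loglik(pb.params["lambda"], 0.0, bt.ages,
                             bt.lineage_time())
            assert ll0 == pytest.approx(pb.logL, abs=1e-9)

    def test_fit_at_least_as_good_as_pure_birth(self, random_trees):
        for ch in random_trees[:8]:
            bt = branching_times(ch)
            assert fit_bd_constant(bt).logL >= fit_pure_birth(bt).logL - 1e-6

    def test_grid_search_oracle(self):
        for s in range(5):
            ch = simdata.sim_bd(30, 0.4, 0.2, seed=700 + s)
            bt = branching_times(ch)
            fit = fit_bd_constant(bt)
            r0 = fit_pure_birth(bt).params["lambda"]
            grid_best = -np.inf
            for r in np.linspace(0.2 * r0, 3.0 * r0, 200):
                for a in np.linspace(0.0, 0.99, 200):
                    grid_best = max(grid_best,
                                    _bd_loglik(r, a, bt.ages,
                                               bt.lineage_time()))
            assert fit.logL >= grid_best - 1e-3

    def test_extinction_fraction_recovery_median(self):
        a_hats = []
        for s in range(40):
            ch = simdata.sim_bd(100, 0.3, 0.15, seed=800 + s)
            a_hats.append(fit_bd_constant(branching_times(ch)).params["a"])
        assert 0.3 <= np.median(a_hats) <= 0.7


class TestYuleKRate:
    def test_toy_epoch_mle_brute_grid(self, toy_chronogram):
        # ages 10, 6, 3, shift fixed at 6: old epoch has event {6},
        # LT = 2*(10-6) = 8; young epoch event {3}, LT = 3*3 + 4*3 = 21
        bt = branching_times(toy_chronogram)
        fit = fit_yule_k_rate(bt, 2)
        candidates = {}
        for shift in (6.0, 3.0):
            if shift == 6.0:
                d = (1, 1)
                lt = (8.0, 21.0)
            else:
                d = (2, 0)
                lt = (8.0 + 3 * 3, 12.0)
            ll = 0.0
            grid = np.linspace(1e-4, 2.0, 20000)
            for de, lte in zip(d, lt):
                # rate 0 is the boundary MLE for an epoch with no events
                ll += max((de * np.log(l) - l * lte for l in grid)) \
                    if de else 0.0
            candidates[shift] = ll
        best_shift = max(candidates, key=candidates.get)
        assert fit.params["shift_ages"][0] == best_shift
        assert fit.logL == pytest.approx(candidates[best_shift], abs=1e-3)
        assert fit.n_params == 3 and fit.aic == pytest.approx(
            -2 * fit.logL + 6)

    def test_nested_in_pure_birth(self, random_trees):
        for ch in random_trees:
            bt = branching_times(ch)
            if bt.n < 5:
                continue
            assert fit_yule_k_rate(bt, 2).logL >= fit_pure_birth(bt).logL - 1e-9
            assert fit_yule_k_rate(bt, 3).logL >= \
                fit_yule_k_rate(bt, 2).logL - 1e-9

    def test_constant_rate_rarely_gains_much(self):
        close = 0
        for s in range(50):
            ch = simdata.sim_yule(40, 0.4, seed=1200 + s)
            bt = branching_times(ch)
            gain = fit_yule_k_rate(bt, 2).aic - fit_pure_birth(bt).aic
            close += gain > -3  # yule2 rarely wins by 3+ AIC units
        assert close >= 40

    def test_shift_recovery(self):
        hits = 0
        for s in range(15):
            ch = simdata.sim_yule_shift(100, [0.05, 0.5], [7.0],
                                        seed=1300 + s)
            fit = fit_yule_k_rate(branching_times(ch), 2)
            hits += 4 <= fit.params["shift_ages"][0] <= 10
        assert hits >= 8

    def test_shift_ages_inside_crown(self, random_trees):
        for ch in random_trees:
            bt = branching_times(ch)
            if bt.n < 5:
                continue
            for k in (2, 3):
                ages = fit_yule_k_rate(bt, k).params["shift_ages"]
                assert all(0 < a < bt.crown_age for a in ages)
                assert ages == sorted(ages, reverse=True)


class TestDeltaAic:
    def test_aic_arithmetic(self, random_trees):
        bt = branching_times(random_trees[0])
        delta, const, var = delta_aic_rc(bt)
        for fit in (const, var):
            assert fit.aic == pytest.approx(-2 * fit.logL + 2 * fit.n_params)
        assert delta == pytest.approx(const.aic - var.aic)

    def test_strong_shift_gives_positive_delta(self):
        pos = 0
        for s in range(15):
            ch = simdata.sim_yule_shift(100, [0.05, 0.5], [7.0],
                                        seed=1400 + s)
            pos += delta_aic_rc(branching_times(ch))[0] > 0
        assert pos >= 14

    def test_null_delta_small(self):
        deltas = [delta_aic_rc(branching_times(
            simdata.sim_yule(25, 0.4, seed=1500 + s)))[0] for s in range(40)]
        assert np.median(deltas) <= 2

    def test_null_deltas_stochastically_below_shift_deltas(self):
        null = np.median([delta_aic_rc(branching_times(
            simdata.sim_yule(30, 0.4, seed=1600 + s)))[0]
            for s in range(25)])
        shifted = np.median([delta_aic_rc(branching_times(
            simdata.sim_yule_shift(100, [0.05, 0.5], [7.0],
                                   seed=1650 + s)))[0] for s in range(25)])
        assert null < shifted


class TestCriticalDeltaAic:
    def test_deterministic_under_seed(self):
        bt = branching_times(simdata.sim_yule(20, 0.4, seed=42))
        c1 = critical_delta_aic(bt, n_sim=50, seed=9)
        c2 = critical_delta_aic(bt, n_sim=50, seed=9)
        assert c1 == c2

    def test_nonnegative_on_yule_trees(self):
        bt = branching_times(simdata.sim_yule(20, 0.4, seed=43))
        assert critical_delta_aic(bt, n_sim=100, seed=3) >= 0


class TestEnsemble:
    def test_identical_trees_give_zero_width_cis(self):
        # with yule2 each tree carries one shift, so an ensemble of copies
        # must collapse to a point estimate
        ch = simdata.sim_yule_shift(60, [0.05, 0.5], [7.0], seed=2000)
        report = ensemble_shift_analysis([ch] * 30, n_sample=20, seed=1,
                                         n_sim=50, variable_model="yule2")
        for mean, ci in ((report.increase_shift_mean,
                          report.increase_shift_ci),
                         (report.decrease_shift_mean,
                          report.decrease_shift_ci)):
            if ci is not None:
                assert ci[0] == pytest.approx(ci[1])
                assert mean == pytest.approx(ci[0])
        assert report.exceedance_fraction in (0.0, 1.0)

    def test_exceedance_identity_and_bounds(self):
        trees = [simdata.sim_yule_shift(50, [0.05, 0.5], [7.0],
                                        seed=2100 + s) for s in range(25)]
        report = ensemble_shift_analysis(trees, n_sample=20, seed=2, n_sim=50)
        n_over = sum(d > report.critical_delta_aic
                     for d in report.delta_aic_rc)
        assert report.exceedance_fraction == pytest.approx(n_over / 20)
        assert 0 <= report.exceedance_fraction <= 1
        ci = report.increase_shift_ci
        if ci is not None:
            assert ci[0] <= ci[1]

    def test_report_deterministic_and_serializable(self):
        trees = [simdata.sim_yule_shift(40, [0.05, 0.5], [7.0],
                                        seed=2200 + s) for s in range(12)]
        r1 = ensemble_shift_analysis(trees, n_sample=10, seed=3, n_sim=30)
        r2 = ensemble_shift_analysis(trees, n_sample=10, seed=3, n_sim=30)
        assert json.dumps(r1.to_dict(), sort_keys=True) == \
            json.dumps(r2.to_dict(), sort_keys=True)


class TestMagallonSanderson:
    def test_crown_zero_extinction_closed_form(self):
        for n, t in ((10, 5.0), (47, 140.0), (200, 30.0)):
            est = magallon_sanderson(n, t, 0.0, mode="crown")
            assert est.r == pytest.approx(np.log(n / 2) / t, rel=1e-12)

    def test_printed_study_rates(self):
        r0 = magallon_sanderson(47, 140.0, 0.0, mode="crown").r
        r9 = magallon_sanderson(47, 140.0, 0.9, mode="crown").r
        assert float(f"{r0:.2g}") == 0.023
        assert float(f"{r9:.2g}") == 0.012

    def test_stem_mode(self):
        est = magallon_sanderson(47, 140.0, 0.0, mode="stem")
        assert est.r == pytest.approx(np.log(47) / 140)

    def test_monotone_in_epsilon_and_n(self):
        eps_grid = np.linspace(0, 0.95, 12)
        rates = [magallon_sanderson(47, 140.0, e, mode="crown").r
                 for e in eps_grid]
        assert all(a > b for a, b in zip(rates, rates[1:]))
        n_grid = [5, 10, 20, 50, 100]
        rates_n = [magallon_sanderson(n, 140.0, 0.5, mode="crown").r
                   for n in n_grid]
        assert all(a < b for a, b in zip(rates_n, rates_n[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            magallon_sanderson(47, 140.0, 1.0)
        with pytest.raises(ValueError):
            magallon_sanderson(1, 140.0, 0.5)
        with pytest.raises(ValueError):
            magallon_sanderson(47, 0.0, 0.5)


def test_rate_fit_aic_consistency():
    fit = RateFit("pureBirth", {"lambda": 0.1}, logL=-12.5, n_params=1)
    assert fit.aic == pytest.approx(27.0)
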