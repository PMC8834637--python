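"""One-step global regression: recovery, statistics, model selection."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from storekin import FitConfig, NoiseSpec
from storekin.fitting import (
    FitError,
    fit_one_step,
    fit_statistics,
    select_model,
    _runs_test_p,
)
from storekin.kinetics import KELVIN_OFFSET, R_GAS, ModelSpec, ParamSet, arrhenius_k, predict
from storekin.simulate import dark_design, generate

from conftest import small_table


def two_step_oracle(table, order, tref=25.0):
    """Independent classical estimate: per-temperature fits, then ln k vs 1/T.

    Deliberately built from scipy.optimize.curve_fit and a hand-written
    Arrhenius regression so it shares no code with the one-step fitter.
    """
    t, x, y = table.arrays()
    ks, inv_t = [], []
    for temp in sorted(set(t.tolist())):
        xs, ys = x[t == temp], y[t == temp]
        if order == "zero":
            popt, _ = optimize.curve_fit(lambda xx, c0, k: c0 - k * xx, xs, ys, p0=[ys.max(), 1e-3])
        elif order == "first":
            popt, _ = optimize.curve_fit(
                lambda xx, c0, k: c0 * np.exp(-k * xx), xs, ys, p0=[ys.max(), 1e-2]
            )
        else:
            popt, _ = optimize.curve_fit(
                lambda xx, c0, k, ci: ci + (c0 - ci) * np.exp(-k * xx),
                xs,
                ys,
                p0=[ys.max(), 1e-1, 0.5 * ys.min()],
            )
        ks.append(popt[1])
        inv_t.append(1.0 / (temp + KELVIN_OFFSET))
    slope, intercept = np.polyfit(inv_t, np.log(ks), 1)
    ea_kj = -slope * R_GAS / 1e3
    kref = math.exp(intercept + slope / (tref + KELVIN_OFFSET))
    return kref, ea_kj


class TestFitOneStep:
    @pytest.mark.parametrize("order", ["zero", "first", "fractional"])
    def test_noiseless_closure_recovers_truth(self, order):
        cinf = 0.72 if order == "fractional" else None
        kref = 0.64e-2 if order == "zero" else 1.7e-2 if order == "first" else 7.5e-2
        truth = ParamSet(C0=1.2, kref=kref, Ea=35.48, Cinf=cinf)
        model = ModelSpec(order)
        table = generate(model, truth, dark_design())
        fit = fit_one_step(table, model)
        assert fit.converged
        assert fit.ssq < 1e-12
        assert fit.estimates.kref == pytest.approx(truth.kref, rel=1e-6)
        assert fit.estimates.Ea == pytest.approx(truth.Ea, rel=1e-6)
        assert fit.estimates.C0 == pytest.approx(truth.C0, rel=1e-6)
        if order == "fractional":
            assert fit.estimates.Cinf == pytest.approx(cinf, rel=1e-5)

    def test_temperature_independent_data_gives_zero_ea(self):
        truth = ParamSet(C0=1.0, kref=1.5e-2, Ea=0.0)
        model = ModelSpec("zero")
        table = generate(model, truth, dark_design())
        fit = fit_one_step(table, model)
        assert fit.estimates.Ea <= 1e-3
        assert fit.estimates.kref == pytest.approx(1.5e-2, rel=1e-5)

    def test_one_step_matches_two_step_oracle_on_noiseless_data(self, zero_truth):
        model, truth = zero_truth
        table = generate(model, truth, dark_design())
        fit = fit_one_step(table, model)
        kref_o, ea_o = two_step_oracle(table, "zero")
        assert fit.estimates.kref == pytest.approx(kref_o, rel=1e-4)
        assert fit.estimates.Ea == pytest.approx(ea_o, rel=1e-4)

    def test_derived_k_matches_forward_arrhenius_exactly(self, noisy_zero_table, fast_cfg):
        model = ModelSpec("zero")
        fit = fit_one_step(noisy_zero_table, model, fast_cfg)
        for temp, (k, se) in fit.k_by_temperature.items():
            assert k == pytest.approx(arrhenius_k(fit.estimates, temp), rel=1e-14)
            assert se > 0

    def test_invariant_to_observation_order_and_replicate_labels(self, noisy_zero_table, fast_cfg):
        model = ModelSpec("zero")
        ref = fit_one_step(noisy_zero_table, model, fast_cfg)
        df = noisy_zero_table.df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        df["replicate"] = df["replicate"] + 10  # uniform relabeling
        from storekin.data_io import StudyTable

        shuffled = StudyTable(df, noisy_zero_table.axis)
        alt = fit_one_step(shuffled, model, fast_cfg)
        # agreement is limited by the optimiser's ftol, not by the data order
        assert alt.estimates.kref == pytest.approx(ref.estimates.kref, rel=1e-6)
        assert alt.estimates.Ea == pytest.approx(ref.estimates.Ea, rel=1e-6)
        assert alt.ssq == pytest.approx(ref.ssq, rel=1e-9)

    def test_objective_never_exceeds_any_start(self, noisy_zero_table, fast_cfg):
        fit = fit_one_step(noisy_zero_table, ModelSpec("zero"), fast_cfg)
        assert fit.start_costs  # every start recorded its final cost
        assert fit.ssq <= min(fit.start_costs) + 1e-15

    def test_too_few_observations_is_an_error(self):
        table = small_table([1.0, 0.9, 0.8])
        with pytest.raises(FitError, match="m="):
            fit_one_step(table, ModelSpec("zero"))

    def test_axis_mismatch_is_an_error(self, noisy_zero_table):
        with pytest.raises(ValueError, match="axis"):
            fit_one_step(noisy_zero_table, ModelSpec("zero", "dose_Mluxh"))


class TestFitStatistics:
    def test_hand_computed_example(self):
        obs = np.array([1.0, 0.9, 0.8, 0.7])
        pred = np.array([0.95, 0.95, 0.75, 0.75])
        r2adj, see, _ = fit_statistics(obs - pred, obs, p=2)
        assert see == pytest.approx(0.0707, abs=5e-5)
        assert r2adj == pytest.approx(0.70, abs=1e-12)

    def test_perfect_fit(self):
        obs = np.array([1.0, 0.9, 0.8, 0.7])
        r2adj, see, runs_p = fit_statistics(np.zeros(4), obs, p=2)
        assert r2adj == 1.0
        assert see == 0.0

    def test_constant_observations_raise(self):
        with pytest.raises(ValueError, match="constant"):
            fit_statistics(np.array([0.1, -0.1, 0.0]), np.array([1.0, 1.0, 1.0]), p=1)

    def test_runs_test_flags_sign_clustering(self):
        alternating = np.array([1, -1] * 10, dtype=float)
        clustered = np.array([1] * 10 + [-1] * 10, dtype=float)
        assert _runs_test_p(np.sign(clustered)) < 0.01
        assert _runs_test_p(np.sign(alternating)) < 0.01  # too regular is also non-random
        rng = np.random.default_rng(0)
        assert _runs_test_p(np.sign(rng.normal(size=40))) > 0.05

    def test_runs_test_matches_statsmodels(self):
        from statsmodels.sandbox.stats.runs import runstest_1samp

        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        _, p_sm = runstest_1samp(x, cutoff=0, correction=False)
        assert _runs_test_p(np.sign(x)) == pytest.approx(p_sm, abs=1e-10)


class TestSelectModel:
    def test_fractional_truth_with_plateau_selected(self, fractional_truth, fast_cfg):
        model, truth = fractional_truth
        table = generate(model, truth, dark_design(), NoiseSpec(sd=0.02, seed=11))
        comparison = select_model(table, config=fast_cfg)
        assert comparison.best.model.order == "fractional"

    def test_strictly_linear_decline_selects_zero_order(self, fast_cfg):
        truth = ParamSet(C0=1.07, kref=0.64e-2, Ea=35.48)
        table = generate(ModelSpec("zero"), truth, dark_design(), NoiseSpec(sd=0.02, seed=12))
        comparison = select_model(table, config=fast_cfg)
        assert comparison.best.model.order == "zero"

    def test_constant_data_selects_zero_order_by_parsimony(self, fast_cfg):
        table = small_table(
            [1.0] * 14,
            exposures=list(range(7)) * 2,
            temperature=10.0,
        )
        # second temperature block so the group is fittable
        df = table.df.copy()
        df.loc[7:, "temperature_C"] = 20.0
        from storekin.data_io import StudyTable

        comparison = select_model(StudyTable(df, "time_days"), config=fast_cfg)
        assert comparison.best.model.order == "zero"
        assert comparison.best.estimates.kref == pytest.approx(0.0, abs=1e-8)

    def test_selection_reports_all_candidate_criteria(self, noisy_zero_table, fast_cfg):
        comparison = select_model(noisy_zero_table, config=fast_cfg)
        assert {c["order"] for c in comparison.criteria} == {"zero", "first", "fractional"}
        assert all(c["see"] > 0 for c in comparison.criteria)
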