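import numpy as np
import pandas as pd
import pytest

from cartmac.io_cli import PatientTimecourse
from cartmac.model_core import CartTumorParams, DoseRegimen
from cartmac.parameter_estimation import (
    PERFECT_FIT_LR,
    FitConfig,
    FitResult,
    fit_cytokine_layer,
    fit_layer1,
    fix_cytokine_params,
    il6_weights,
    lr_objective,
    top_fit_correlations,
    wls_objective_layer1,
)


def _tc_from_points(cart, tumor, il6=(), dose=1e8, **kw):
    rows = []
    for t, v in cart:
        rows.append({"series": "cart", "time": t, "value": v,
                     "unit": "cells", "censored": False})
    for t, v in tumor:
        rows.append({"series": "tumor", "time": t, "value": v,
                     "unit": "cells", "censored": False})
    for t, v in il6:
        rows.append({"series": "il6", "time": t, "value": v,
                     "unit": "ng/L", "censored": False})
    return PatientTimecourse("toy", pd.DataFrame(rows),
                             DoseRegimen.single(dose), **kw)


class TestWlsObjective:
    def test_hand_computed_weighted_sum(self):
        # pure decay: C_T(t) = D exp(-mu_I t) exactly (no antigen, eta=0);
        # observations offset by known residuals
        p = CartTumorParams(eta=0.0, mu_I=0.5, rho=0.0, gamma=0.0)
        D = 1e8
        sim = lambda t: D * np.exp(-0.5 * t)
        cart = [(0.0, sim(0.0)), (2.0, sim(2.0) - 1e6), (4.0, sim(4.0) + 3e6)]
        # one exactly-matched tumor point: T stays at its initial 1e7 (rho=0)
        tc = _tc_from_points(cart, [(0.0, 1e7)], dose=D,
                             initial_tumor_burden=1e7)
        value = wls_objective_layer1(tc, p)
        w = 1.0 / max(v for _, v in cart) ** 2
        expected = w * ((1e6) ** 2 + (3e6) ** 2)
        assert value == pytest.approx(expected, rel=1e-3)

    def test_zero_for_generating_parameters(self, cr_patient_noiseless):
        pt = cr_patient_noiseless
        value = wls_objective_layer1(pt.timecourse, pt.params,
                                     T_N0=pt.extras["T_N0"])
        assert value < 1e-4

    def test_reordering_invariance(self, cr_patient_noiseless):
        pt = cr_patient_noiseless
        tc = pt.timecourse
        shuffled = PatientTimecourse(
            tc.patient_id, tc.data.sample(frac=1, random_state=0),
            tc.regimen, horizon=tc.horizon,
            initial_tumor_burden=tc.initial_tumor_burden)
        a = wls_objective_layer1(tc, pt.params)
        b = wls_objective_layer1(shuffled, pt.params)
        assert a == pytest.approx(b, rel=1e-12)

    def test_requires_points_above_detection(self):
        tc = _tc_from_points([(0.0, 1e4), (1.0, 1e4), (2.0, 1e4)],
                             [(0.0, 1e7)])
        with pytest.raises(ValueError, match="detection"):
            wls_objective_layer1(tc, CartTumorParams())


class TestIl6Weights:
    def test_formula_values(self):
        w = il6_weights([0.0, 50.0, 100.0], w0=0.15)
        assert w == pytest.approx([0.15, 0.575, 1.0])

    def test_peak_weight_is_one(self):
        assert il6_weights([3.0, 9.0], 0.15)[-1] == 1.0

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError):
            il6_weights([0.0, 0.0])

    def test_peak_to_floor_ratio_near_seven(self):
        w = il6_weights([0.0, 100.0], w0=0.15)
        assert w[1] / w[0] == pytest.approx(1 / 0.15, rel=1e-9)


class TestLrObjective:
    def test_single_point(self):
        assert lr_objective([5.0], [7.0], w0=1.0) == pytest.approx(np.log(4.0))

    def test_two_unit_residuals(self):
        assert lr_objective([1.0, 1.0], [2.0, 2.0], w0=1.0) == \
            pytest.approx(np.log(2.0))

    def test_perfect_fit_sentinel(self):
        assert lr_objective([3.0, 5.0], [3.0, 5.0]) == PERFECT_FIT_LR


class TestFixCytokineParams:
    def test_rule_application(self):
        tc = _tc_from_points([(0, 1e6), (1, 1e6), (2, 1e6)], [(0, 1e7)],
                             il6=[(0.0, 5.0), (3.0, 30.0), (7.0, 8.0)])
        fixed = fix_cytokine_params(tc)
        assert fixed["M_a0"] == 0.0
        assert fixed["IL6_0"] == 5.0
        assert fixed["il6_min"] == 5.0       # sigma_I = delta_I * 5
        assert fixed["C"] == 1e10


class TestFitLayer1:
    def test_noise_free_recovery(self, cr_patient_noiseless):
        pt = cr_patient_noiseless
        fit = fit_layer1(pt.timecourse, FitConfig())
        truth = pt.params.to_dict()
        errs = [abs(fit.params[k] - truth[k]) / truth[k]
                for k in ("mu_I", "kappa", "mu_E", "mu_P", "gamma", "rho",
                          "eta", "epsilon", "A", "B")]
        # single-patient smoke bound; the cohort-level recovery criterion
        # is asserted in test_acceptance
        assert np.median(errs) < 0.20
        assert fit.objective < 1e-3

    def test_point_bounds_return_that_point(self, cr_patient_noiseless):
        pt = cr_patient_noiseless
        cfg = FitConfig(maxiter=5)
        truth = pt.params.to_dict()
        for k in ("mu_I", "kappa", "mu_E", "mu_P", "gamma", "rho", "eta",
                  "epsilon", "A", "B"):
            cfg.bounds[k] = (truth[k], truth[k])
        fit = fit_layer1(pt.timecourse, cfg)
        for k in ("mu_I", "gamma", "A"):
            assert fit.params[k] == pytest.approx(truth[k], rel=1e-9)

    def test_best_so_far_trace_monotone(self, cr_patient_noiseless):
        fit = fit_layer1(cr_patient_noiseless.timecourse,
                         FitConfig(maxiter=150))
        assert all(b <= a + 1e-15 for a, b in zip(fit.trace, fit.trace[1:]))


@pytest.fixture(scope="module")
def truth_layer1(hcrs_patient_noiseless):
    pt = hcrs_patient_noiseless
    return FitResult(
        params={**pt.params.to_dict(), "T_N0": pt.extras["T_N0"]},
        free_names=(), objective=0.0, layer=1,
        fixed={"T_P0": pt.extras["T_P0"]})


class TestFitCytokineLayer:

    def test_beats_truth_and_recovers_identifiable_products(
            self, hcrs_patient_noiseless, truth_layer1):
        from cartmac.parameter_estimation import (
            _layer1_drivers, simulate_cytokine_given)
        pt = hcrs_patient_noiseless
        tc = pt.timecourse
        cfg = FitConfig(n_mc=1500, n_refine=8, seed=7)
        drv, p1 = _layer1_drivers(tc, truth_layer1, tc.horizon, cfg)
        t_i, y_i = tc.series("il6")
        fixed = fix_cytokine_params(tc)
        truth_q = pt.cytokine.to_dict()
        truth_q["M_i0"] = pt.extras["M_i0"]
        lr_truth = lr_objective(
            y_i, simulate_cytokine_given(drv, p1, truth_q, fixed, t_i), cfg.w0)
        fit = fit_cytokine_layer(tc, truth_layer1, cfg)
        # optimizer sanity: at least as good as the generating parameters
        assert fit.objective <= lr_truth + 1e-6
        # the scale-invariant combinations are identifiable
        est_prod_alpha = fit.params["alpha"] * fit.params["M_i0"]
        true_prod_alpha = truth_q["alpha"] * truth_q["M_i0"]
        assert abs(est_prod_alpha - true_prod_alpha) / true_prod_alpha < 0.5
        est_prod_bc = fit.params["beta_C"] * fit.params["M_i0"]
        true_prod_bc = truth_q["beta_C"] * truth_q["M_i0"]
        assert abs(est_prod_bc - true_prod_bc) / true_prod_bc < 0.5

    def test_same_seed_is_deterministic(self, hcrs_patient_noiseless,
                                        truth_layer1):
        tc = hcrs_patient_noiseless.timecourse
        cfg = FitConfig(n_mc=60, n_refine=2, refine_maxiter=30, seed=21)
        a = fit_cytokine_layer(tc, truth_layer1, cfg)
        b = fit_cytokine_layer(tc, truth_layer1, cfg)
        assert a.objective == b.objective
        assert a.params == b.params


class TestTopFitCorrelations:
    def test_collinear_pair(self):
        refined = [({"a": x, "b": 2 * x, "c": 5.0}, 0.0)
                   for x in (1.0, 2.0, 3.0, 4.0)]
        corr, _ = top_fit_correlations(refined)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_constant_parameter_reported_missing(self):
        refined = [({"a": x, "c": 5.0}, 0.0) for x in (1.0, 2.0, 3.0)]
        corr, _ = top_fit_correlations(refined)
        assert np.isnan(corr.loc["a", "c"])

    def test_independent_draws_have_small_median(self):
        rng = np.random.default_rng(0)
        refined = [({f"p{j}": rng.normal() for j in range(6)}, 0.0)
                   for _ in range(100)]
        _, median = top_fit_correlations(refined)
        assert abs(median) < 0.3

    def test_needs_three_fits(self):
        with pytest.raises(ValueError):
            top_fit_correlations([({"a": 1.0}, 0.0)] * 2)
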