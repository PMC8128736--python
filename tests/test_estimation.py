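"""Estimation: conditional likelihood, Laplace vs quadrature, fitting,
model comparison, post hoc etas, standard errors and diagnostics."""

import numpy as np
import pytest

from iwspkpd.cohort import CohortDataset, Patient
from iwspkpd.estimation import (CohortEvaluator, _central_hessian,
                                compare_models, diagnostics, fit,
                                individual_loglik, marginal_loglik,
                                posthoc_eta)
from iwspkpd.params import DrugEffectParams, IWSParams
from iwspkpd.scores import gp_truncated_pmf, markov_inflate
from iwspkpd.synthetic import (CohortConfig, DrugTemplate,
                               default_pk_parameters, generate_cohort,
                               recovery_template)


def drug_free_patient(scores, times=None, pid="P1"):
    times = np.asarray(times if times is not None else
                       8.0 * (1 + np.arange(len(scores))), dtype=float)
    return Patient(pid, 10.0, [], times, np.asarray(scores, dtype=int))


def small_cohort(seed, n=4, interval=12.0):
    tpl = DrugTemplate("fentanyl", probability=1.0, rate_per_kg_median=1.0,
                       treatment_days_min=3.0, treatment_days_max=6.0,
                       follow_up_h=48.0)
    cfg = CohortConfig(n_patients=n, seed=seed, templates=(tpl,),
                       obs_interval_h=interval, min_stay_h=96.0)
    return generate_cohort(cfg)


class TestIndividualLoglik:
    def test_single_drug_free_observation_matches_pmf_oracle(self, reference_params, pk_defaults):
        pat = drug_free_patient([0])
        ll = individual_loglik(pat, reference_params, pk_defaults, eta=0.0)
        expected = np.log(gp_truncated_pmf(0.564, 0.428)[0])
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_sequence_composes_inflated_distributions(self, reference_params, pk_defaults):
        p = reference_params
        pat = drug_free_patient([0, 2, 2])
        ll = individual_loglik(pat, p, pk_defaults, eta=0.3)
        lam = 0.564 * np.exp(0.3)
        base = gp_truncated_pmf(lam, p.delta)
        infl = p.inflation()
        expected = (
            np.log(base[0])
            + np.log(markov_inflate(base, 0, infl)[2])
            + np.log(markov_inflate(base, 2, infl)[2])
        )
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_repeating_scores_favoured_by_inflation(self, reference_params, pk_defaults):
        from dataclasses import replace
        pat = drug_free_patient([2, 2, 2, 2])
        with_pi = individual_loglik(pat, reference_params, pk_defaults)
        no_pi = replace(reference_params, pi_same_prev0=0.0,
                        pi_same_prevx=0.0, pi_pm=0.0)
        without = individual_loglik(pat, no_pi, pk_defaults)
        assert with_pi > without

    def test_analytic_severity_derivatives_match_finite_differences(
            self, reference_params, pk_defaults):
        """The inner Newton's d/dlam, d2/dlam2 agree with numeric FD."""
        ds = small_cohort(5)
        ev = CohortEvaluator(ds, pk_defaults, drug_ids=["fentanyl"])
        params = reference_params.with_drugs(["fentanyl"])
        E = ev.effects_total(params)
        Pi, add = ev._inflation_terms(params)
        lam = 0.7 + E
        logp, d1, d2 = ev.obs_logp(lam, params, Pi, add, derivs=True)
        h = 1e-6
        lp_p = ev.obs_logp(lam + h, params, Pi, add)
        lp_m = ev.obs_logp(lam - h, params, Pi, add)
        np.testing.assert_allclose(d1, (lp_p - lp_m) / (2 * h), rtol=5e-4, atol=1e-7)
        h2 = 1e-4  # larger step: the second difference amplifies roundoff
        lp_p2 = ev.obs_logp(lam + h2, params, Pi, add)
        lp_m2 = ev.obs_logp(lam - h2, params, Pi, add)
        np.testing.assert_allclose(d2, (lp_p2 - 2 * logp + lp_m2) / h2**2,
                                   rtol=5e-3, atol=1e-6)


class TestMarginalLoglik:
    def test_omega_zero_degenerates_to_eta_zero(self, reference_params, pk_defaults):
        from dataclasses import replace
        ds = small_cohort(7)
        params = replace(reference_params.with_drugs(["fentanyl"]),
                         omega_baseline=0.0)
        marg = marginal_loglik(params, ds, pk_defaults)
        cond = sum(
            individual_loglik(p, params, pk_defaults, eta=0.0)
            for p in ds.patients
        )
        assert marg == pytest.approx(cond, rel=1e-10)

    def test_laplace_close_to_adaptive_quadrature(self, reference_params, pk_defaults):
        params = reference_params.with_drugs(["fentanyl"])
        for seed in (1, 2, 3):
            ds = small_cohort(seed)
            L = marginal_loglik(params, ds, pk_defaults, method="laplace")
            Q = marginal_loglik(params, ds, pk_defaults,
                                method="adaptive-quadrature")
            assert abs(L - Q) / abs(Q) < 1e-3

    def test_ofv_invariant_to_patient_order(self, reference_params, pk_defaults):
        params = reference_params.with_drugs(["fentanyl"])
        ds = small_cohort(11)
        rev = CohortDataset(list(reversed(ds.patients)))
        a = marginal_loglik(params, ds, pk_defaults)
        b = marginal_loglik(params, rev, pk_defaults)
        assert a == pytest.approx(b, rel=1e-12)


class TestPosthocEta:
    def test_zero_variance_gives_zero(self, reference_params, pk_defaults):
        from dataclasses import replace
        ds = small_cohort(3, n=2)
        params = replace(reference_params.with_drugs(["fentanyl"]),
                         omega_baseline=0.0)
        np.testing.assert_allclose(posthoc_eta(params, ds, pk_defaults), 0.0)

    def test_matches_grid_argmax(self, reference_params, pk_defaults):
        params = reference_params.with_drugs(["fentanyl"])
        ds = small_cohort(13, n=3)
        etas = posthoc_eta(params, ds, pk_defaults)
        ev = CohortEvaluator(ds, pk_defaults, drug_ids=["fentanyl"])
        w2 = params.omega_baseline**2
        for i, pat in enumerate(ds.patients):
            grid = np.linspace(etas[i] - 0.05, etas[i] + 0.05, 1001)
            vals = [
                ev.patient_loglik(params, np.where(np.arange(ev.n_pat) == i,
                                                   e, etas))[i]
                - e**2 / (2 * w2)
                for e in grid
            ]
            assert abs(grid[int(np.argmax(vals))] - etas[i]) < 1.5e-4


class TestFit:
    def test_all_parameters_fixed_reports_ofv_only(self, reference_params, pk_defaults):
        ds = small_cohort(17)
        params = reference_params.with_drugs(["fentanyl"])
        res = fit(ds, pk_defaults, params, free=[])
        assert res.n_free == 0
        assert res.aic == pytest.approx(res.ofv)
        assert res.ofv == pytest.approx(
            -2 * marginal_loglik(params, ds, pk_defaults), rel=1e-10
        )

    def test_baseline_model_fit_on_drug_free_data(self, pk_defaults, reference_params,
                                                  neutral_start):
        from dataclasses import replace
        truth = replace(reference_params, drug_effects={})
        cfg = CohortConfig(n_patients=12, seed=23, templates=(
            DrugTemplate("fentanyl", probability=0.0),), obs_interval_h=8.0,
            min_stay_h=14 * 24.0, iws=truth)
        ds = generate_cohort(cfg)
        res = fit(ds, pk_defaults, neutral_start, n_starts=1, seed=0)
        assert res.converged
        # loose sanity at this small n: right order of magnitude
        assert 0.2 < res.estimates["baseline"] < 1.5
        assert res.aic == pytest.approx(res.ofv + 2 * res.n_free)

    def test_fitted_maximum_at_least_truth_likelihood(self, reference_params,
                                                      pk_defaults, neutral_start):
        ds = small_cohort(29, n=6)
        truth = reference_params.with_drugs(["fentanyl"])
        start = IWSParams(
            typical_baseline=neutral_start.typical_baseline,
            omega_baseline=neutral_start.omega_baseline,
            delta=neutral_start.delta,
            pi_same_prev0=neutral_start.pi_same_prev0,
            pi_same_prevx=neutral_start.pi_same_prevx,
            pi_pm=neutral_start.pi_pm,
            drug_effects={"fentanyl": DrugEffectParams(0.05, 1.0, "ng/mL")},
        )
        res = fit(ds, pk_defaults, start, n_starts=1, seed=1)
        ll_truth = marginal_loglik(truth, ds, pk_defaults)
        assert -res.ofv / 2 >= ll_truth - 1e-6


class TestCompareModels:
    def test_identical_fits(self, reference_params, pk_defaults):
        ds = small_cohort(31, n=2)
        params = reference_params.with_drugs(["fentanyl"])
        a = fit(ds, pk_defaults, params, free=[])
        cmp = compare_models(a, a)
        assert cmp.delta_ofv == 0.0
        assert cmp.p_value == 1.0

    def test_chi_square_tail_frozen_value(self, reference_params, pk_defaults):
        """dOFV = 6.63 on 1 df corresponds to p ~ 0.01."""
        ds = small_cohort(37, n=2)
        params = reference_params.with_drugs(["fentanyl"])
        null = fit(ds, pk_defaults, params, free=[])
        alt_res = fit(ds, pk_defaults, params, free=[])
        alt_res.ofv = null.ofv - 6.63
        alt_res.n_free = 1
        alt_res.free_names = ["kdep_fentanyl"]
        cmp = compare_models(null, alt_res)
        assert cmp.p_value == pytest.approx(0.01003, abs=2e-4)

    def test_non_nested_request_gets_aic_only(self, reference_params, pk_defaults):
        ds = small_cohort(41, n=2)
        params = reference_params.with_drugs(["fentanyl"])
        a = fit(ds, pk_defaults, params, free=[])
        b = fit(ds, pk_defaults, params, free=[])
        a.free_names = ["kdep_fentanyl"]
        a.n_free = 1
        b.free_names = ["slope_fentanyl"]
        b.n_free = 1
        cmp = compare_models(a, b)
        assert not cmp.nested
        assert cmp.p_value is None


class TestStandardErrors:
    def test_central_hessian_on_quadratic(self):
        Q = np.array([[2.0, 0.3], [0.3, 1.0]])

        def f(x):
            return 0.5 * x @ Q @ x

        H = _central_hessian(f, np.array([0.4, -1.2]), step=1e-4)
        np.testing.assert_allclose(H, Q, rtol=1e-5, atol=1e-6)

    def test_fit_with_se_reports_cis_for_free_parameters_only(
            self, reference_params, pk_defaults):
        ds = small_cohort(43, n=6)
        params = reference_params.with_drugs(["fentanyl"])
        res = fit(ds, pk_defaults, params, free=["baseline", "delta"],
                  n_starts=1, seed=0, compute_se=True)
        assert res.cov_ok
        assert set(res.se) == {"baseline", "delta"}
        for name, (lo, hi) in res.ci.items():
            assert lo < res.estimates[name] < hi
        assert "omega" not in res.se


class TestDiagnostics:
    def test_calibrated_on_true_model(self, reference_params, pk_defaults):
        ds = small_cohort(47, n=8)
        params = reference_params.with_drugs(["fentanyl"])
        res = fit(ds, pk_defaults, params, free=[])  # post hoc etas at truth
        tables = diagnostics(res, ds, pk_defaults)
        resid = tables["residuals"]["residual"].to_numpy()
        se = resid.std(ddof=1) / np.sqrt(resid.size)
        assert abs(resid.mean()) < 4 * se
        freq = tables["score_frequencies"]
        assert freq["predicted"].sum() == pytest.approx(ds.n_observations, rel=1e-9)
        assert freq["observed"].sum() == ds.n_observations
        tr = tables["transition_frequencies"]
        n_tr = ds.n_observations - ds.n_patients
        assert tr["observed"].sum() == n_tr
        assert tr["predicted"].sum() == pytest.approx(n_tr, rel=1e-9)
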