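"""Interval-censored parametric survival model tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hs
from scipy import integrate, optimize

import drscreen as d
from drscreen.icsurv import FamilyFit, fit_family, log_survival


def _fit(p, beta0, beta=(), names=()):
    return d.WeibullPHFit(p=p, beta0=beta0, beta=np.array(beta), covariate_names=names)


def _records(left, right, **cov):
    df = pd.DataFrame({"left": left, "right": right})
    for k, v in cov.items():
        df[k] = v
    return df


def _quadrature_loglik(fit, records):
    """Independent oracle: adaptive quadrature of p*lam*t^(p-1)*exp(-lam t^p)."""
    total = 0.0
    X = records[list(fit.covariate_names)].to_numpy() if fit.covariate_names else np.zeros((len(records), 0))
    for (l, r), x in zip(records[["left", "right"]].to_numpy(), X):
        lam = np.exp(fit.beta0 + x @ fit.beta)

        def dens(t):
            return fit.p * lam * t ** (fit.p - 1.0) * np.exp(-lam * t**fit.p)

        if np.isinf(r):
            total += -lam * l**fit.p
        else:
            mass, _ = integrate.quad(dens, l, r, epsabs=1e-14, epsrel=1e-12, limit=200)
            total += np.log(mass)
    return total


class TestIntervalLoglik:
    def test_pure_right_censoring_at_zero_contributes_nothing(self):
        fit = _fit(1.3, -2.0)
        assert d.interval_loglik(fit, _records([0.0], [np.inf])) == 0.0

    def test_exponential_closed_form(self):
        # p=1, lam=0.1, interval (2, 4): ln(e^-0.2 - e^-0.4)
        fit = _fit(1.0, np.log(0.1))
        expected = np.log(np.exp(-0.2) - np.exp(-0.4))
        assert d.interval_loglik(fit, _records([2.0], [4.0])) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-1.90777, abs=1e-4)

    def test_agrees_with_quadrature_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(0.6, 2.5)
            beta0 = rng.uniform(-3.0, -0.5)
            beta = rng.normal(scale=0.3, size=2)
            n = 30
            x1, x2 = rng.normal(size=n), rng.normal(size=n)
            left = rng.uniform(0, 3, size=n)
            right = left + rng.uniform(0.2, 2.0, size=n)
            right[rng.random(n) < 0.3] = np.inf
            rec = _records(left, right, x1=x1, x2=x2)
            fit = _fit(p, beta0, beta, ("x1", "x2"))
            ours = d.interval_loglik(fit, rec)
            oracle = _quadrature_loglik(fit, rec)
            assert ours == pytest.approx(oracle, abs=1e-8 * max(1.0, abs(oracle)))

    def test_zero_probability_interval_gives_minus_inf(self):
        # hazard underflows to zero: S(left) == S(right) == 1 exactly, so the
        # interval carries no probability mass -> diagnosable -inf, no crash
        fit = _fit(1.0, -760.0)
        val = d.interval_loglik(fit, _records([5.0], [6.0]))
        assert val == -np.inf

    def test_invalid_record_rejected(self):
        fit = _fit(1.0, 0.0)
        with pytest.raises(ValueError, match="left >= right"):
            d.interval_loglik(fit, _records([2.0], [2.0]))


def _simulate_records(rng, n, p, beta0, betas=(), sd=1.0, interval=1.0, followup=10.0):
    k = len(betas)
    X = rng.normal(scale=sd, size=(n, k))
    lam = np.exp(beta0 + X @ np.asarray(betas)) if k else np.full(n, np.exp(beta0))
    t = (-np.log(rng.uniform(size=n)) / lam) ** (1.0 / p)
    grid = np.arange(0, followup + interval, interval)
    left = np.empty(n)
    right = np.empty(n)
    for i in range(n):
        after = grid[grid >= t[i]]
        if after.size and t[i] <= followup:
            right[i] = after[0]
            left[i] = grid[grid < t[i]][-1] if np.any(grid < t[i]) else 0.0
        else:
            left[i] = grid[-1]
            right[i] = np.inf
    rec = _records(left, right)
    for j in range(k):
        rec[f"x{j}"] = X[:, j]
    return rec


class TestFitIntervalWeibull:
    def test_narrow_intervals_match_exact_time_mle(self):
        """With near-degenerate intervals the interval MLE converges to the
        exact-time Weibull MLE (independently coded oracle)."""
        rng = np.random.default_rng(3)
        n = 2000
        p_true, lam_true = 1.5, 0.12
        t = (-np.log(rng.uniform(size=n)) / lam_true) ** (1.0 / p_true)
        eps = 1e-6
        rec = _records(np.maximum(t - eps, 0.0), t + eps)
        fit = d.fit_interval_weibull(rec, n_restarts=2)

        # oracle: exact-time likelihood, coarse grid then polish
        logt = np.log(t)

        def nll_exact(theta):
            p, lam = np.exp(theta)
            return -(n * np.log(p * lam) + (p - 1) * logt.sum() - lam * np.sum(t**p))

        best = min(
            ((np.log(pg), np.log(lg)) for pg in np.linspace(0.5, 3, 26) for lg in np.geomspace(0.01, 1, 26)),
            key=lambda th: nll_exact(np.array(th)),
        )
        res = optimize.minimize(nll_exact, np.array(best), method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        p_oracle, lam_oracle = np.exp(res.x)
        assert fit.p == pytest.approx(p_oracle, abs=1e-3)
        assert np.exp(fit.beta0) == pytest.approx(lam_oracle, abs=1e-3)

    def test_narrow_intervals_match_lifelines(self):
        """Cross-check against lifelines' exact-time Weibull fitter."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        n = 3000
        t = (-np.log(rng.uniform(size=n)) / 0.2) ** (1.0 / 0.9)
        eps = 1e-6
        fit = d.fit_interval_weibull(_records(np.maximum(t - eps, 0), t + eps), n_restarts=2)
        wf = lifelines.WeibullFitter().fit(t)
        # lifelines: S(t)=exp(-(t/lambda_)^rho_)
        assert fit.p == pytest.approx(wf.rho_, rel=2e-3)
        assert np.exp(fit.beta0) == pytest.approx(wf.lambda_**-wf.rho_, rel=5e-3)

    def test_duplicating_records_halves_variances(self):
        rng = np.random.default_rng(5)
        rec = _simulate_records(rng, 400, 1.2, -2.0, (0.4,))
        fit1 = d.fit_interval_weibull(rec, ("x0",), n_restarts=2)
        fit2 = d.fit_interval_weibull(
            pd.concat([rec, rec], ignore_index=True), ("x0",), n_restarts=2
        )
        np.testing.assert_allclose(fit2.params, fit1.params, rtol=1e-3, atol=1e-4)
        np.testing.assert_allclose(np.diag(fit2.vcov), np.diag(fit1.vcov) / 2, rtol=0.02)

    def test_shape_ci_covers_true_value(self):
        """95% CI for p (log scale) covers p=1 in most replicates."""
        hits = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            rec = _simulate_records(rng, 1000, 1.0, -2.0)
            fit = d.fit_interval_weibull(rec, n_restarts=2)
            se_logp = fit.se()[0] / fit.p
            lo, hi = np.log(fit.p) - 1.96 * se_logp, np.log(fit.p) + 1.96 * se_logp
            hits += lo <= 0.0 <= hi
        assert hits >= reps - 2

    def test_all_right_censored_rejected(self):
        rec = _records([1.0, 2.0], [np.inf, np.inf])
        with pytest.raises(ValueError, match="no interval-censored"):
            d.fit_interval_weibull(rec)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(1)
        rec = _simulate_records(rng, 200, 1.0, -1.5, (0.3,))
        rec["x_dup"] = rec["x0"]
        with pytest.raises(ValueError, match="rank deficient"):
            d.fit_interval_weibull(rec, ("x0", "x_dup"))


class TestFamilySelection:
    def test_better_loglik_wins_at_equal_complexity(self):
        a = FamilyFit("gompertz", {}, loglik=-100.0, n_params=2)
        b = FamilyFit("lognormal", {}, loglik=-90.0, n_params=2)
        assert d.compare_aic([a, b]) is b

    def test_ties_break_to_fewer_params_then_weibull(self):
        a = FamilyFit("lognormal", {}, loglik=-91.0, n_params=2)
        b = FamilyFit("gompertz", {}, loglik=-90.0, n_params=3)
        assert d.compare_aic([a, b]) is a  # equal AIC 186, fewer params wins
        c = FamilyFit("weibull", {}, loglik=-91.0, n_params=2)
        assert d.compare_aic([a, c]) is c  # exact tie -> weibull

    def test_single_candidate_returned_unchanged(self):
        a = FamilyFit("weibull", {}, loglik=-50.0, n_params=2)
        assert d.compare_aic([a]) is a

    def test_nonconverged_excluded_with_warning(self):
        a = FamilyFit("weibull", {}, loglik=-10.0, n_params=2, converged=False)
        b = FamilyFit("gompertz", {}, loglik=-90.0, n_params=2)
        with pytest.warns(UserWarning, match="did not converge"):
            assert d.compare_aic([a, b]) is b

    def test_weibull_data_selects_weibull(self):
        """Family selection is consistent on clearly Weibull (p=2) data."""
        wins = 0
        reps = 8
        for r in range(reps):
            rng = np.random.default_rng(200 + r)
            rec = _simulate_records(rng, 1500, 2.0, np.log(0.02))
            fits = [fit_family(rec, fam, seed=r) for fam in ("weibull", "gompertz", "lognormal")]
            wins += d.compare_aic(fits).family == "weibull"
        assert wins >= int(0.8 * reps)


class TestStepwise:
    def test_empty_candidates_gives_baseline_fit(self):
        rng = np.random.default_rng(2)
        rec = _simulate_records(rng, 300, 1.0, -2.0)
        fit = d.stepwise_select(rec, [], 0.05)
        assert fit.covariate_names == ()
        assert fit.selection_trace == ()

    def test_null_covariate_usually_excluded(self):
        excluded = 0
        reps = 10
        for r in range(reps):
            rng = np.random.default_rng(300 + r)
            rec = _simulate_records(rng, 800, 1.2, -2.0, (0.0,))
            fit = d.stepwise_select(rec, ["x0"], 0.05)
            excluded += "x0" not in fit.covariate_names
        assert excluded >= reps - 2

    def test_strong_covariate_always_included(self):
        included = 0
        reps = 6
        for r in range(reps):
            rng = np.random.default_rng(400 + r)
            rec = _simulate_records(rng, 800, 1.2, -2.5, (1.0,), sd=0.7)
            fit = d.stepwise_select(rec, ["x0"], 0.05)
            included += "x0" in fit.covariate_names
        assert included == reps

    def test_collinear_second_entrant_rejected(self):
        rng = np.random.default_rng(6)
        rec = _simulate_records(rng, 600, 1.2, -2.5, (0.8,), sd=0.7)
        rec["x_dup"] = rec["x0"]
        fit = d.stepwise_select(rec, ["x0", "x_dup"], 0.05)
        assert fit.covariate_names == ("x0",)
        assert any("collinear" in line for line in fit.selection_trace)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            d.stepwise_select(_records([1.0], [2.0]), [], alpha=1.5)


class TestDerivedQuantities:
    def test_survival_at_zero_is_one(self):
        fit = _fit(1.7, -1.0, (0.3,), ("x",))
        assert d.survival_at(fit, {"x": 2.0}, 0.0) == 1.0

    def test_median_exponential_unit(self):
        fit = _fit(1.0, np.log(np.log(2.0)))
        assert d.median_time(fit, {}) == pytest.approx(1.0, abs=1e-12)

    def test_memoryless_cycle_probability(self):
        fit = _fit(1.0, np.log(0.2))
        expected = 1.0 - np.exp(-0.1)
        for t in (0.0, 1.0, 7.5, 40.0):
            assert d.cycle_transition_prob(fit, {}, t, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_increasing_hazard_gives_increasing_cycle_probability(self):
        fit = _fit(2.0, -3.0)
        probs = [d.cycle_transition_prob(fit, {}, t, 0.5) for t in np.arange(0, 20, 0.5)]
        assert np.all(np.diff(probs) > 0)

    def test_cycle_probabilities_telescope_to_cumulative_risk(self):
        """Product over consecutive cycles reconstructs 1 - S(T) exactly."""
        fit = _fit(1.6, -2.2, (0.25,), ("x",))
        x = {"x": 1.3}
        dt = 0.5
        surv = 1.0
        for k in range(60):
            surv *= 1.0 - d.cycle_transition_prob(fit, x, k * dt, dt)
        assert 1.0 - surv == pytest.approx(1.0 - d.survival_at(fit, x, 60 * dt), abs=1e-12)

    def test_hba1c_gradient_orders_median_times(self):
        """Higher HbA1c strictly shortens the median time to RDR, matching
        the published 20 y / 13 y / 8 y gradient direction for T1DM."""
        from drscreen.params import reference_fit

        fit = reference_fit("T1DM")
        medians = [
            d.median_time(fit, {"hba1c": h, "duration": 7.8}) for h in (6.5, 8.0, 9.0)
        ]
        assert medians[0] > medians[1] > medians[2]

    @given(
        p=hs.floats(0.5, 3.0),
        beta0=hs.floats(-4.0, 0.0),
        t=hs.floats(0.0, 30.0),
        dt=hs.floats(0.1, 2.0),
    )
    def test_survival_monotone_and_cycle_prob_in_unit_interval(self, p, beta0, t, dt):
        fit = _fit(p, beta0)
        s1, s2 = d.survival_at(fit, {}, t), d.survival_at(fit, {}, t + dt)
        assert s2 <= s1 <= 1.0
        q = d.cycle_transition_prob(fit, {}, t, dt)
        assert 0.0 <= q <= 1.0
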