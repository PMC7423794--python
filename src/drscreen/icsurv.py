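"""Interval-censored parametric survival modelling of progression to
referable diabetic retinopathy.

The primary model is a Weibull proportional-hazards regression fitted by
maximum likelihood directly on the interval-censored data:

    S(t | x) = exp(-lambda_x * t**p),   lambda_x = exp(beta0 + x' beta),
    h(t | x) = p * lambda_x * t**(p-1).

A screening record contributes ``S(left|x) - S(right|x)`` when the event
was bracketed between two screens and ``S(left|x)`` when right-censored
(``right = +inf``).  A Cox model is not applicable under interval
censoring, hence the fully parametric likelihood.  Gompertz and lognormal
alternatives are fitted for AIC-based family comparison, and covariates
are chosen by a forward/backward Wald stepwise procedure.

Time is measured in years from the first (disease-free) screening event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "WeibullPHFit",
    "FamilyFit",
    "interval_loglik",
    "fit_interval_weibull",
    "fit_family",
    "compare_aic",
    "stepwise_select",
    "survival_at",
    "median_time",
    "cycle_transition_prob",
]

_BIG = 1e10  # penalty for invalid parameter regions during optimisation


# ---------------------------------------------------------------------------
# containers


@dataclass
class WeibullPHFit:
    """A fitted interval-censored Weibull proportional-hazards model.

    ``vcov`` is the observed-information covariance of the parameter
    vector ``(p, beta0, *beta)`` on the reported (original covariate)
    scale.
    """

    p: float
    beta0: float
    beta: np.ndarray
    covariate_names: tuple[str, ...]
    vcov: np.ndarray | None = None
    loglik: float = np.nan
    n_params: int = 0
    converged: bool = True
    n_records: int = 0
    messages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.covariate_names = tuple(self.covariate_names)
        if self.p <= 0:
            raise ValueError(f"Weibull shape p must be > 0, got {self.p}")
        if not self.n_params:
            self.n_params = 2 + self.beta.size

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.p, self.beta0], self.beta])

    def se(self) -> np.ndarray:
        if self.vcov is None:
            raise ValueError("fit carries no covariance matrix")
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, np.inf))

    def wald_pvalues(self) -> dict[str, float]:
        """Two-sided normal Wald p-values for the covariate coefficients."""
        se = self.se()[2:]
        out = {}
        for i, name in enumerate(self.covariate_names):
            z = self.beta[i] / se[i] if se[i] > 0 else np.inf
            out[name] = float(2.0 * stats.norm.sf(abs(z)))
        return out

    def linear_predictor(self, x) -> float:
        xv = _as_covariate_vector(x, self.covariate_names)
        return float(self.beta0 + xv @ self.beta)


@dataclass
class FamilyFit:
    """A parametric survival fit of one distributional family."""

    family: str  # weibull | gompertz | lognormal
    params: dict[str, float]
    loglik: float
    n_params: int
    converged: bool = True

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


# ---------------------------------------------------------------------------
# record handling


def _extract_records(records, covariate_names: Sequence[str]):
    """Pull (left, right, X) arrays out of a records DataFrame.

    ``right`` uses ``np.inf`` for right-censored subjects.
    """
    if isinstance(records, pd.DataFrame):
        left = records["left"].to_numpy(dtype=float)
        right = records["right"].to_numpy(dtype=float)
        X = (
            records.loc[:, list(covariate_names)].to_numpy(dtype=float)
            if covariate_names
            else np.zeros((len(records), 0))
        )
    else:  # sequence of (left, right) tuples, covariate-free
        arr = np.asarray(records, dtype=float)
        left, right = arr[:, 0], arr[:, 1]
        X = np.zeros((len(left), 0))
    if np.any(left < 0):
        raise ValueError("censoring interval with left < 0")
    if np.any(left >= right):
        bad = int(np.argmax(left >= right))
        raise ValueError(f"record {bad} has left >= right ({left[bad]} >= {right[bad]})")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate value in records")
    return left, right, X


def _log_surv_weibull(t: np.ndarray, p: float, eta: np.ndarray) -> np.ndarray:
    """log S(t) = -exp(eta + p*log t), with S(0) = 1 exactly."""
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast(t, eta).shape)
    pos = t > 0
    logt = np.log(np.where(pos, t, 1.0))
    val = -np.exp(np.broadcast_to(eta, out.shape) + p * logt)
    return np.where(pos, val, 0.0)


def _interval_loglik_terms(logS_l, logS_r, is_interval):
    """Per-record log-likelihood contributions from log-survival values."""
    ll = np.array(logS_l, dtype=float, copy=True)
    if np.any(is_interval):
        diff = logS_r[is_interval] - logS_l[is_interval]  # <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            mass = -np.expm1(diff)  # S(l) - S(r) scaled by S(l)
            ll[is_interval] = logS_l[is_interval] + np.where(
                mass > 0, np.log(np.where(mass > 0, mass, 1.0)), -np.inf
            )
    return ll


def interval_loglik(fit: WeibullPHFit, records) -> float:
    """Interval-censored Weibull log-likelihood of ``records`` under ``fit``.

    Interval-censored rows contribute ``log(S(left|x) - S(right|x))``,
    right-censored rows ``log S(left|x)``.  Returns ``-inf`` (never raises)
    when some interval has zero probability under the parameters.
    """
    left, right, X = _extract_records(records, fit.covariate_names)
    eta = fit.beta0 + X @ fit.beta
    is_interval = np.isfinite(right)
    logS_l = _log_surv_weibull(left, fit.p, eta)
    logS_r = np.where(is_interval, _log_surv_weibull(np.where(is_interval, right, 1.0), fit.p, eta), -np.inf)
    return float(np.sum(_interval_loglik_terms(logS_l, logS_r, is_interval)))


# ---------------------------------------------------------------------------
# Weibull fitting


def _weibull_nll_factory(left, right, X):
    is_interval = np.isfinite(right)
    right_safe = np.where(is_interval, right, 1.0)

    def nll(theta):
        logp = theta[0]
        if abs(logp) > 10:
            return _BIG
        p = np.exp(logp)
        eta = theta[1] + X @ theta[2:]
        if np.any(np.abs(eta) > 500):
            return _BIG
        logS_l = _log_surv_weibull(left, p, eta)
        logS_r = np.where(is_interval, _log_surv_weibull(right_safe, p, eta), -np.inf)
        ll = _interval_loglik_terms(logS_l, logS_r, is_interval)
        total = ll.sum()
        if not np.isfinite(total):
            return _BIG
        return -total

    return nll


def _nll_original_scale(left, right, X):
    """Negative log-likelihood parameterised by (p, beta0, beta) directly."""
    base = _weibull_nll_factory(left, right, X)

    def nll(params):
        p = params[0]
        if p <= 0:
            return _BIG
        theta = np.concatenate([[np.log(p)], params[1:]])
        return base(theta)

    return nll


def fit_interval_weibull(
    records,
    covariate_names: Sequence[str] = (),
    *,
    n_restarts: int = 5,
    seed: int = 0,
    compute_vcov: bool = True,
) -> WeibullPHFit:
    """Maximum-likelihood Weibull PH fit on interval/right-censored records.

    Continuous covariates are standardised internally for optimisation and
    the coefficients are reported back on the original scale.  The shape is
    optimised through ``log p``.  ``n_restarts`` dispersed restarts guard
    against local optima; non-convergence is reported through the
    ``converged`` flag together with the best point found.
    """
    covariate_names = tuple(covariate_names)
    left, right, X = _extract_records(records, covariate_names)
    if not np.any(np.isfinite(right)):
        raise ValueError("no interval-censored (event) records: model is not identified")

    # standardise continuous columns; leave near-binary columns alone
    mu = X.mean(axis=0) if X.size else np.zeros(0)
    sd = X.std(axis=0) if X.size else np.zeros(0)
    is_binary = np.array(
        [set(np.unique(X[:, j])) <= {0.0, 1.0} for j in range(X.shape[1])], dtype=bool
    )
    scale = np.where(is_binary | (sd < 1e-12), 1.0, sd)
    shift = np.where(is_binary | (sd < 1e-12), 0.0, mu)
    if X.size and np.any(~is_binary & (sd < 1e-12)):
        raise ValueError("constant covariate column cannot enter the hazard")
    Xs = (X - shift) / scale

    # rank check (separation-like degeneracies surface as rank loss)
    if Xs.shape[1]:
        design = np.column_stack([np.ones(len(Xs)), Xs])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariate matrix is rank deficient (collinear covariates)")

    nll = _weibull_nll_factory(left, right, Xs)

    # crude initial rate from events per unit mid-interval exposure
    mid = np.where(np.isfinite(right), 0.5 * (left + right), left)
    exposure = max(mid.sum(), 1e-9)
    events = int(np.isfinite(right).sum())
    b0_init = np.log(max(events, 1) / exposure)
    theta0 = np.concatenate([[0.0, b0_init], np.zeros(Xs.shape[1])])

    rng = np.random.default_rng(seed)
    best = None
    messages: list[str] = []
    for attempt in range(max(1, n_restarts)):
        start = theta0 if attempt == 0 else theta0 + rng.normal(
            scale=[0.5, 1.0] + [0.3] * Xs.shape[1]
        )
        res = optimize.minimize(nll, start, method="L-BFGS-B")
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    assert best is not None
    converged = bool(best.success) and best.fun < _BIG / 2
    if not converged:
        messages.append(f"optimiser did not report convergence: {best.message}")

    theta = best.x
    p_hat = float(np.exp(theta[0]))
    beta_s = theta[2:]
    beta = beta_s / scale if beta_s.size else beta_s
    beta0 = float(theta[1] - (beta_s * shift / scale).sum()) if beta_s.size else float(theta[1])

    if np.any(np.abs(beta_s) > 10):
        messages.append("a coefficient diverged; possible separation-like degeneracy")
        converged = False

    vcov = None
    loglik = -float(best.fun)
    if compute_vcov:
        params = np.concatenate([[p_hat, beta0], beta])
        nll_orig = _nll_original_scale(left, right, X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            H = approx_hess(params, nll_orig)
        try:
            vcov = np.linalg.inv(H)
            vcov = 0.5 * (vcov + vcov.T)
            if np.any(np.diag(vcov) < 0):
                raise np.linalg.LinAlgError("negative variance")
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
            vcov = 0.5 * (vcov + vcov.T)
            messages.append("observed information not positive definite; pseudo-inverse used")

    return WeibullPHFit(
        p=p_hat,
        beta0=beta0,
        beta=beta,
        covariate_names=covariate_names,
        vcov=vcov,
        loglik=loglik,
        converged=converged,
        n_records=len(left),
        messages=tuple(messages),
    )


# ---------------------------------------------------------------------------
# alternative families for AIC comparison


def _gompertz_logS(t, log_a, b, eta):
    """Gompertz PH: h(t) = a e^{bt} lambda_x; H(t) = (a/b)(e^{bt}-1) lambda_x."""
    t = np.asarray(t, dtype=float)
    if abs(b) < 1e-8:
        cum = np.exp(log_a) * t * (1.0 + 0.5 * b * t)
    else:
        cum = np.exp(log_a) / b * np.expm1(b * t)
    return -cum * np.exp(eta)


def _lognormal_logS(t, mu, log_sigma, eta):
    """Lognormal AFT on log-time: log T ~ N(mu - x'gamma, sigma^2)."""
    t = np.asarray(t, dtype=float)
    sigma = np.exp(log_sigma)
    out = np.zeros(np.broadcast(t, eta).shape)
    pos = t > 0
    z = (np.log(np.where(pos, t, 1.0)) - (mu - np.broadcast_to(eta, out.shape))) / sigma
    return np.where(pos, stats.norm.logsf(z), 0.0)


def _generic_nll(logS_fn, n_base, left, right, X):
    is_interval = np.isfinite(right)
    right_safe = np.where(is_interval, right, 1.0)

    def nll(theta):
        base = theta[:n_base]
        eta = X @ theta[n_base:] if X.shape[1] else 0.0
        with np.errstate(over="ignore"):
            logS_l = logS_fn(left, *base, eta)
            logS_r = np.where(is_interval, logS_fn(right_safe, *base, eta), -np.inf)
        ll = _interval_loglik_terms(np.broadcast_to(logS_l, left.shape), logS_r, is_interval)
        total = ll.sum()
        return -total if np.isfinite(total) else _BIG

    return nll


def fit_family(records, family: str, covariate_names: Sequence[str] = (), *, seed: int = 0) -> FamilyFit:
    """Fit one parametric family to the same interval-censored records.

    Parameterisations (recorded here because conventions vary):
    Weibull ``S = exp(-lambda t^p)`` with ``lambda = exp(beta0 + x'beta)``;
    Gompertz hazard ``a exp(bt)`` with PH multiplier ``exp(x'beta)``;
    lognormal accelerated-failure on ``log t`` with location ``mu - x'beta``
    and scale ``sigma``.
    """
    family = family.lower()
    covariate_names = tuple(covariate_names)
    if family == "weibull":
        f = fit_interval_weibull(records, covariate_names, seed=seed, compute_vcov=False)
        params = {"p": f.p, "beta0": f.beta0}
        params.update({f"beta_{n}": float(b) for n, b in zip(f.covariate_names, f.beta)})
        return FamilyFit("weibull", params, f.loglik, f.n_params, f.converged)

    left, right, X = _extract_records(records, covariate_names)
    k = X.shape[1]
    mid = np.where(np.isfinite(right), 0.5 * (left + right), left)
    if family == "gompertz":
        nll = _generic_nll(_gompertz_logS, 2, left, right, X)
        rate = max(int(np.isfinite(right).sum()), 1) / max(mid.sum(), 1e-9)
        theta0 = np.concatenate([[np.log(rate), 0.01], np.zeros(k)])
        base_names = ["log_a", "b"]
    elif family == "lognormal":
        nll = _generic_nll(_lognormal_logS, 2, left, right, X)
        theta0 = np.concatenate([[np.log(np.median(mid[mid > 0]) + 1e-9), 0.0], np.zeros(k)])
        base_names = ["mu", "log_sigma"]
    else:
        raise ValueError(f"unknown survival family '{family}'")

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(3):
        start = theta0 if attempt == 0 else theta0 + rng.normal(scale=0.5, size=theta0.size)
        res = optimize.minimize(nll, start, method="Nelder-Mead", options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        res = optimize.minimize(nll, res.x, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    params = dict(zip(base_names, best.x[:2]))
    params.update({f"beta_{n}": float(b) for n, b in zip(covariate_names, best.x[2:])})
    return FamilyFit(family, params, -float(best.fun), 2 + k, bool(best.fun < _BIG / 2))


def compare_aic(fits: Sequence[FamilyFit]) -> FamilyFit:
    """Select the family with minimal AIC.

    Ties break toward fewer parameters, then toward the Weibull family.
    Non-converged candidates are excluded with a warning, never chosen
    silently.
    """
    usable = [f for f in fits if f.converged]
    for f in fits:
        if not f.converged:
            warnings.warn(f"{f.family} fit did not converge; excluded from AIC comparison")
    if not usable:
        raise ValueError("no converged candidate fits to compare")
    return min(usable, key=lambda f: (f.aic, f.n_params, 0 if f.family == "weibull" else 1))


# ---------------------------------------------------------------------------
# stepwise covariate selection


def stepwise_select(
    records,
    candidates: Sequence[str],
    alpha: float = 0.05,
    *,
    seed: int = 0,
    max_sweeps: int = 10,
) -> WeibullPHFit:
    """Forward-addition / backward-removal Wald stepwise Weibull selection.

    Forward step: among candidates whose Wald p-value would be below
    ``alpha``, add the one with the largest |z|.  Backward step: drop the
    included covariate with the largest Wald p >= ``alpha``.  A covariate
    removed twice is barred from re-entry, which guarantees termination.
    The inclusion/removal trace is attached to the returned fit as
    ``selection_trace``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    candidates = list(dict.fromkeys(candidates))
    included: list[str] = []
    removal_count: dict[str, int] = {c: 0 for c in candidates}
    trace: list[str] = []

    def fit_with(names):
        return fit_interval_weibull(records, names, seed=seed)

    if isinstance(records, pd.DataFrame) and candidates:
        corr = records[candidates].corr().abs()
    else:
        corr = None

    for _ in range(max_sweeps):
        changed = False
        # forward
        while True:
            best_name, best_z = None, 0.0
            for cand in candidates:
                if cand in included or removal_count[cand] >= 2:
                    continue
                if corr is not None and any(corr.loc[cand, inc] > 0.999 for inc in included):
                    trace.append(f"reject {cand}: collinear with an included covariate")
                    removal_count[cand] = 2
                    continue
                try:
                    trial = fit_with(included + [cand])
                except ValueError as exc:
                    trace.append(f"reject {cand}: {exc}")
                    removal_count[cand] = 2
                    continue
                pv = trial.wald_pvalues()[cand]
                se = trial.se()[2 + len(included)]
                z = abs(trial.beta[len(included)] / se) if se > 0 else 0.0
                if pv < alpha and z > best_z:
                    best_name, best_z = cand, z
            if best_name is None:
                break
            included.append(best_name)
            trace.append(f"add {best_name} (|z|={best_z:.2f})")
            changed = True
        # backward
        while included:
            fit = fit_with(included)
            pvals = fit.wald_pvalues()
            worst = max(included, key=lambda n: pvals[n])
            if pvals[worst] < alpha:
                break
            included.remove(worst)
            removal_count[worst] += 1
            trace.append(f"remove {worst} (p={pvals[worst]:.3f})")
            changed = True
        if not changed:
            break

    final = fit_with(included)
    final.selection_trace = tuple(trace)  # type: ignore[attr-defined]
    return final


# ---------------------------------------------------------------------------
# derived quantities


def _as_covariate_vector(x, names: tuple[str, ...]) -> np.ndarray:
    if isinstance(x, Mapping):
        try:
            return np.array([float(x[n]) for n in names])
        except KeyError as exc:
            raise KeyError(f"covariate {exc} missing from profile; fit needs {names}") from exc
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    if xv.size != len(names):
        raise ValueError(f"expected {len(names)} covariate values, got {xv.size}")
    return xv


def log_survival(fit: WeibullPHFit, x, t) -> np.ndarray:
    eta = fit.linear_predictor(x)
    return _log_surv_weibull(np.asarray(t, dtype=float), fit.p, np.array(eta))


def survival_at(fit: WeibullPHFit, x, t):
    """S(t | x) = exp(-lambda_x t^p)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival requested at negative time")
    out = np.exp(log_survival(fit, x, t))
    return float(out) if out.ndim == 0 else out


def median_time(fit: WeibullPHFit, x) -> float:
    """Median time to the event: (ln 2 / lambda_x)^(1/p)."""
    lam = np.exp(fit.linear_predictor(x))
    return float((np.log(2.0) / lam) ** (1.0 / fit.p))


def cycle_transition_prob(fit: WeibullPHFit, x, t: float, dt: float) -> float:
    """Conditional probability of the event within (t, t+dt] given event-free at t.

    Computed as ``1 - S(t+dt)/S(t)`` in log space so that survival
    underflow at long horizons cannot produce NaNs.  Constant in ``t``
    when ``p = 1`` (memoryless exponential special case).
    """
    if t < 0:
        raise ValueError("cycle start time must be >= 0")
    if dt <= 0:
        raise ValueError("cycle length dt must be > 0")
    eta = fit.linear_predictor(x)
    logS_t = _log_surv_weibull(np.array(t), fit.p, np.array(eta))
    logS_td = _log_surv_weibull(np.array(t + dt), fit.p, np.array(eta))
    return float(-np.expm1(logS_td - logS_t))
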