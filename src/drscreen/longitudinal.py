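"""Quadratic-in-time multilevel models for irregular GP measurements.

Primary-care measurements (HbA1c, blood pressure, lipids, ...) are taken
at GP appointments, not at screening visits.  To attach covariate values
to screening dates each analyte is modelled as

    y_ij = (beta + b_i)' (1, t_ij, t_ij^2) + eps_ij,
    b_i ~ N(0, Sigma),  eps_ij ~ N(0, sigma^2),

a quadratic function of time with subject-level random coefficients
constrained to a normal distribution across subjects.  Fitting is by
marginal maximum likelihood (statsmodels ``MixedLM``); per-subject
coefficients are the shrunken posterior means, and predictions at
screening dates are ``(beta + b_i)' (1, t, t^2)``.

Times are centred at the grand mean observation time before fitting to
reduce collinearity of the polynomial basis; predictions transform back.
Each analyte is fitted independently (no multivariate longitudinal
model), matching the two-stage design in which the survival model
consumes predicted values as fixed covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["QuadraticMixedFit", "fit_quadratic_mixed", "predict_at_times"]


@dataclass
class QuadraticMixedFit:
    fixed: np.ndarray                       # (intercept, slope, curvature)
    random_cov: np.ndarray                  # 3x3 PSD Sigma across subjects
    residual_var: float
    per_subject: dict[str, np.ndarray]      # shrunken (b0, b1, b2) + fixed
    time_center: float
    obs_range: dict[str, tuple[float, float]]
    converged: bool = True
    intercept_only: bool = False
    messages: tuple[str, ...] = ()

    def basis(self, times) -> np.ndarray:
        tc = np.asarray(times, dtype=float) - self.time_center
        return np.column_stack([np.ones(tc.shape), tc, tc**2])

    def blup(self, times, values) -> np.ndarray:
        """Posterior-mean subject coefficients from raw observations.

        Closed-form shrinkage: ``b = Sigma Z' V^{-1} (y - Z beta)`` with
        ``V = Z Sigma Z' + sigma^2 I``; returns ``beta + b``.  Used both
        for subjects outside the estimation sample and to verify the
        shrinkage behaviour of the fit.
        """
        Z = self.basis(times)
        y = np.asarray(values, dtype=float)
        V = Z @ self.random_cov @ Z.T + self.residual_var * np.eye(len(y))
        resid = y - Z @ self.fixed
        b = self.random_cov @ Z.T @ np.linalg.solve(V, resid)
        return self.fixed + b


def _series_frame(series) -> pd.DataFrame:
    """Accept a long DataFrame or a list of (subject_id, times, values)."""
    if isinstance(series, pd.DataFrame):
        df = series
        missing = {"subject_id", "time_years", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"measurement frame missing columns {sorted(missing)}")
        return df
    rows = []
    for sid, times, values in series:
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.size == 0:
            raise ValueError(f"subject {sid} has no observations")
        if np.any(np.diff(times) <= 0) and times.size > 1:
            raise ValueError(f"subject {sid}: observation times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"subject {sid}: non-finite measurement value")
        rows.append(pd.DataFrame({"subject_id": sid, "time_years": times, "value": values}))
    return pd.concat(rows, ignore_index=True)


def fit_quadratic_mixed(series, *, reml: bool = False) -> QuadraticMixedFit:
    """Fit the quadratic mixed model to one analyte's measurement series.

    Degenerate designs (fewer than three distinct observation times in
    the whole dataset) cannot identify a curvature: the fit falls back to
    a random-intercept-only model with a warning rather than returning a
    rank-deficient answer.
    """
    df = _series_frame(series)
    n_subjects = df["subject_id"].nunique()
    if n_subjects < 10:
        raise ValueError(f"need >= 10 subjects for the multilevel fit, got {n_subjects}")

    t0 = float(df["time_years"].mean())
    obs_range = {
        str(sid): (float(g["time_years"].min()), float(g["time_years"].max()))
        for sid, g in df.groupby("subject_id")
    }
    y = df["value"].to_numpy(dtype=float)
    tc = df["time_years"].to_numpy(dtype=float) - t0

    messages: list[str] = []

    # exactly constant response: nothing to estimate
    if np.ptp(y) == 0:
        c = float(y[0])
        fixed = np.array([c, 0.0, 0.0])
        return QuadraticMixedFit(
            fixed=fixed,
            random_cov=np.zeros((3, 3)),
            residual_var=0.0,
            per_subject={sid: fixed.copy() for sid in obs_range},
            time_center=t0,
            obs_range=obs_range,
            messages=("constant response; degenerate fit returned",),
        )

    n_unique_t = np.unique(np.round(tc, 12)).size
    if n_unique_t < 3:
        warnings.warn(
            "fewer than 3 distinct observation times: curvature not identified, "
            "falling back to an intercept-only multilevel model"
        )
        return _intercept_only_fit(df, t0, obs_range)

    # pooled OLS pre-check: a noiseless single global quadratic makes the
    # mixed-model likelihood degenerate (sigma^2 -> 0), so short-circuit.
    X = np.column_stack([np.ones_like(tc), tc, tc**2])
    ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ ols
    if np.max(np.abs(resid)) < 1e-10:
        fixed = ols
        return QuadraticMixedFit(
            fixed=fixed,
            random_cov=np.zeros((3, 3)),
            residual_var=0.0,
            per_subject={sid: fixed.copy() for sid in obs_range},
            time_center=t0,
            obs_range=obs_range,
            messages=("noiseless global quadratic; degenerate fit returned",),
        )

    groups = df["subject_id"].to_numpy()
    model = sm.MixedLM(y, X, groups=groups, exog_re=X)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            result = model.fit(reml=reml, method="lbfgs", maxiter=500)
        except Exception:
            result = model.fit(reml=reml, method="powell", maxiter=500)
        if not getattr(result, "converged", True):
            result = model.fit(reml=reml, method="cg", maxiter=1000)
        converged = bool(getattr(result, "converged", True))
        for w in caught:
            messages.append(str(w.message))

    fixed = np.asarray(result.fe_params, dtype=float)
    Sigma = np.asarray(result.cov_re, dtype=float)
    # project onto the PSD cone against round-off
    evals, evecs = np.linalg.eigh(0.5 * (Sigma + Sigma.T))
    Sigma = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
    sigma2 = float(result.scale)

    per_subject = {}
    for sid, re in result.random_effects.items():
        per_subject[str(sid)] = fixed + np.asarray(re, dtype=float)

    return QuadraticMixedFit(
        fixed=fixed,
        random_cov=Sigma,
        residual_var=sigma2,
        per_subject=per_subject,
        time_center=t0,
        obs_range=obs_range,
        converged=converged,
        messages=tuple(messages),
    )


def _intercept_only_fit(df: pd.DataFrame, t0: float, obs_range) -> QuadraticMixedFit:
    y = df["value"].to_numpy(dtype=float)
    groups = df["subject_id"].to_numpy()
    X = np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = sm.MixedLM(y, X, groups=groups, exog_re=X).fit(reml=False)
    mu = float(np.asarray(result.fe_params).ravel()[0])
    v = float(np.asarray(result.cov_re).ravel()[0])
    Sigma = np.zeros((3, 3))
    Sigma[0, 0] = max(v, 0.0)
    per_subject = {
        str(sid): np.array([mu + float(np.asarray(re).ravel()[0]), 0.0, 0.0])
        for sid, re in result.random_effects.items()
    }
    return QuadraticMixedFit(
        fixed=np.array([mu, 0.0, 0.0]),
        random_cov=Sigma,
        residual_var=float(result.scale),
        per_subject=per_subject,
        time_center=t0,
        obs_range=obs_range,
        intercept_only=True,
        messages=("intercept-only fallback",),
    )


def predict_at_times(fit: QuadraticMixedFit, subject_id, times):
    """Predicted analyte values for one subject at requested times.

    Unknown subjects receive the population fixed-effect curve.  Returns
    a DataFrame with the prediction and two flags: ``population`` (no
    subject-specific coefficients were available) and ``extrapolated``
    (the time lies outside the subject's observed range).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    sid = str(subject_id)
    coef = fit.per_subject.get(sid)
    population = coef is None
    if population:
        coef = fit.fixed
    values = fit.basis(times) @ coef
    if population or sid not in fit.obs_range:
        extrapolated = np.ones(times.size, dtype=bool)
    else:
        lo, hi = fit.obs_range[sid]
        extrapolated = (times < lo) | (times > hi)
    return pd.DataFrame(
        {
            "time_years": times,
            "predicted_value": values,
            "population": population,
            "extrapolated": extrapolated,
        }
    )
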