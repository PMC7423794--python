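"""Synthetic linked screening + primary-care cohorts.

Generates per-subject demographic and clinical profiles for a Type 1 /
Type 2 diabetes screening population, near-annual screening events with
jitter, irregular GP measurement series, and interval-censored /
right-censored times to referable retinopathy (RDR) drawn from a Weibull
proportional-hazards law.  The default parameters reproduce the
demographic structure of the Welsh screening population used to estimate
the progression model (covariate means/SDs, treatment and smoking
proportions, cohort sizes 1,232 T1DM / 26,812 T2DM) and a time-to-RDR law
calibrated so that median times at representative HbA1c levels follow the
published gradient (about 20 / 13 / 8 years at HbA1c 6.5 / 8.0 / 9.0 %
for T1DM, slower for T2DM).

Subjects enter at their first screening event (time origin t = 0) with no
retinopathy, mirroring the inclusion rule of the study population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .icsurv import WeibullPHFit

__all__ = [
    "TypeConfig",
    "GeneratorConfig",
    "SchedulePolicy",
    "CohortDataset",
    "generate_cohort",
    "simulate_progression_times",
    "apply_screening_schedule",
]

CONTINUOUS_COVARIATES = (
    "hba1c", "sbp", "dbp", "tchol", "hdl", "ldl", "trig", "egfr", "bmi",
)
FLAG_COVARIATES = (
    "metformin", "sulphonylurea", "insulin", "antihtn", "lipidlower", "smoker",
)

#: Hard physiological floors used when truncating the sampling normals.
_FLOORS = {
    "hba1c": 4.0, "sbp": 70.0, "dbp": 40.0, "tchol": 1.5, "hdl": 0.3,
    "ldl": 0.5, "trig": 0.2, "egfr": 5.0, "bmi": 13.0,
}


@dataclass
class TypeConfig:
    """Generating law for one diabetes type."""

    n: int
    age_mean: float
    age_sd: float
    duration_mean: float
    duration_sd: float
    covariate_means: dict[str, float]
    covariate_sds: dict[str, float]
    flag_probs: dict[str, float]
    male_prop: float
    weibull_p: float
    weibull_beta0: float
    weibull_betas: dict[str, float]

    def validate(self, label: str, errors: list[str]) -> None:
        if self.n < 0:
            errors.append(f"{label}.n must be >= 0, got {self.n}")
        for name, sd in self.covariate_sds.items():
            if sd <= 0:
                errors.append(f"{label}.covariate_sds[{name}] must be > 0, got {sd}")
        for nm, v in [("age_sd", self.age_sd), ("duration_sd", self.duration_sd)]:
            if v <= 0:
                errors.append(f"{label}.{nm} must be > 0, got {v}")
        for name, pr in self.flag_probs.items():
            if not 0.0 <= pr <= 1.0:
                errors.append(f"{label}.flag_probs[{name}] must lie in [0,1], got {pr}")
        if not 0.0 <= self.male_prop <= 1.0:
            errors.append(f"{label}.male_prop must lie in [0,1], got {self.male_prop}")
        if self.weibull_p <= 0:
            errors.append(f"{label}.weibull_p must be > 0, got {self.weibull_p}")


def _t1dm_default(n: int = 1232) -> TypeConfig:
    return TypeConfig(
        n=n,
        age_mean=22.7, age_sd=11.6,
        duration_mean=7.8, duration_sd=9.4,
        covariate_means={
            "hba1c": 8.7, "sbp": 121.7, "dbp": 71.8, "tchol": 4.5, "hdl": 1.5,
            "ldl": 2.5, "trig": 1.3, "egfr": 107.9, "bmi": 24.1,
        },
        covariate_sds={
            "hba1c": 1.6, "sbp": 9.5, "dbp": 5.6, "tchol": 0.7, "hdl": 0.4,
            "ldl": 0.6, "trig": 0.6, "egfr": 22.8, "bmi": 4.6,
        },
        flag_probs={
            "metformin": 0.016, "sulphonylurea": 0.098, "insulin": 1.0,
            # antihypertensive / lipid-lowering proportions are not published
            # for this cohort; plausible values for a young T1DM population.
            "antihtn": 0.10, "lipidlower": 0.15, "smoker": 0.038,
        },
        male_prop=0.538,
        weibull_p=1.4,
        weibull_beta0=-8.648,
        weibull_betas={"hba1c": 0.50, "duration": 0.10},
    )


def _t2dm_default(n: int = 26812) -> TypeConfig:
    return TypeConfig(
        n=n,
        age_mean=62.3, age_sd=12.1,
        duration_mean=4.2, duration_sd=4.1,
        covariate_means={
            "hba1c": 7.5, "sbp": 138.2, "dbp": 79.2, "tchol": 4.6, "hdl": 1.2,
            "ldl": 2.4, "trig": 2.1, "egfr": 79.5, "bmi": 32.3,
        },
        covariate_sds={
            "hba1c": 1.2, "sbp": 10.6, "dbp": 6.3, "tchol": 0.8, "hdl": 0.3,
            "ldl": 0.7, "trig": 1.0, "egfr": 18.7, "bmi": 6.3,
        },
        flag_probs={
            "metformin": 0.605, "sulphonylurea": 0.22, "insulin": 0.041,
            "antihtn": 0.55, "lipidlower": 0.55, "smoker": 0.387,
        },
        male_prop=0.561,
        weibull_p=1.3,
        weibull_beta0=-7.884,
        weibull_betas={"hba1c": 0.45, "duration": 0.075},
    )


@dataclass
class SchedulePolicy:
    """Screening recall policy: target interval with uniform jitter.

    Jitter is uniform on [-jitter, +jitter] years around each anniversary;
    observed Welsh recall intervals drift past the 12-month target, which
    the jitter emulates.  Draws producing non-increasing screen times are
    resampled, never emitted.
    """

    interval_years: float = 1.0
    jitter_years: float = 0.15
    followup_years: float = 10.0

    def validate(self, errors: list[str]) -> None:
        if self.interval_years <= 0:
            errors.append(f"schedule.interval_years must be > 0, got {self.interval_years}")
        if self.jitter_years < 0:
            errors.append(f"schedule.jitter_years must be >= 0, got {self.jitter_years}")
        if self.followup_years <= 0:
            errors.append(f"schedule.followup_years must be > 0, got {self.followup_years}")


@dataclass
class GeneratorConfig:
    t1dm: TypeConfig = field(default_factory=_t1dm_default)
    t2dm: TypeConfig = field(default_factory=_t2dm_default)
    schedule: SchedulePolicy = field(default_factory=SchedulePolicy)
    # GP measurement process for the longitudinal module
    gp_visit_interval: float = 0.6
    gp_visit_jitter: float = 0.25
    hba1c_noise_sd: float = 0.30
    hba1c_slope_sd: float = 0.08
    hba1c_curv_sd: float = 0.010
    sbp_noise_sd: float = 6.0

    @classmethod
    def default(cls, n_t1dm: int = 1232, n_t2dm: int = 26812, **kwargs) -> "GeneratorConfig":
        cfg = cls(t1dm=_t1dm_default(n_t1dm), t2dm=_t2dm_default(n_t2dm))
        for k, v in kwargs.items():
            setattr(cfg, k, v)
        return cfg

    def validate(self) -> None:
        errors: list[str] = []
        self.t1dm.validate("t1dm", errors)
        self.t2dm.validate("t2dm", errors)
        self.schedule.validate(errors)
        if errors:
            raise ValueError("invalid generator config: " + "; ".join(errors))


@dataclass
class CohortDataset:
    """A generated cohort: profiles, screening events, GP measurements,
    censoring records and (for validation only) the latent true event times."""

    profiles: pd.DataFrame
    events: pd.DataFrame
    measurements: pd.DataFrame
    records: pd.DataFrame
    true_times: pd.Series

    def write_csv(self, outdir, prefix: str = "") -> None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.profiles.to_csv(outdir / f"{prefix}profiles.csv", index=False)
        self.events.to_csv(outdir / f"{prefix}events.csv", index=False)
        self.measurements.to_csv(outdir / f"{prefix}measurements.csv", index=False)
        rec = self.records.copy()
        rec["right"] = rec["right"].map(lambda v: "inf" if np.isinf(v) else repr(float(v)))
        rec.to_csv(outdir / f"{prefix}records.csv", index=False)


def read_records_csv(path) -> pd.DataFrame:
    rec = pd.read_csv(path, comment="#")
    rec["right"] = rec["right"].replace("inf", np.inf).astype(float)
    return rec


# ---------------------------------------------------------------------------
# sampling primitives


def _truncated_normal(rng, mean, sd, n, lower=-np.inf, upper=np.inf):
    """Normal draws truncated to [max(lower, mean-4sd), min(upper, mean+4sd)]."""
    lo = max(lower, mean - 4.0 * sd)
    hi = min(upper, mean + 4.0 * sd)
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _draw_profiles(rng, cfg: TypeConfig, dtype: str) -> pd.DataFrame:
    n = cfg.n
    prefix = "T1" if dtype == "T1DM" else "T2"
    data = {
        "subject_id": [f"{prefix}-{i:06d}" for i in range(n)],
        "diabetes_type": [dtype] * n,
        "age_at_entry": _truncated_normal(rng, cfg.age_mean, cfg.age_sd, n, lower=12.0),
        "sex": np.where(rng.random(n) < cfg.male_prop, "M", "F"),
        "duration": _truncated_normal(rng, cfg.duration_mean, cfg.duration_sd, n, lower=0.0),
    }
    for name in CONTINUOUS_COVARIATES:
        data[name] = _truncated_normal(
            rng, cfg.covariate_means[name], cfg.covariate_sds[name], n,
            lower=_FLOORS.get(name, -np.inf),
        )
    for name in FLAG_COVARIATES:
        p = cfg.flag_probs.get(name, 0.0)
        data[name] = (rng.random(n) < p).astype(int)
    df = pd.DataFrame(data)
    if dtype == "T1DM":
        df["insulin"] = 1  # T1DM implies insulin treatment
    return df


def simulate_progression_times(fit, profiles: pd.DataFrame, seed: int) -> np.ndarray:
    """Exact RDR onset times by inverse-transform sampling of S(t).

    ``t = (-ln U / lambda_i)^(1/p)`` with ``lambda_i = exp(beta0 + x_i' beta)``.
    ``fit`` may be a :class:`~drscreen.icsurv.WeibullPHFit` or any object
    with ``p``, ``beta0``, and a ``weibull_betas`` mapping (a
    :class:`TypeConfig`).
    """
    if isinstance(fit, WeibullPHFit):
        p, beta0 = fit.p, fit.beta0
        betas = dict(zip(fit.covariate_names, fit.beta))
    else:
        p, beta0 = fit.weibull_p, fit.weibull_beta0
        betas = fit.weibull_betas
    if p <= 0:
        raise ValueError(f"Weibull shape p must be > 0, got {p}")
    eta = np.full(len(profiles), beta0, dtype=float)
    for name, b in betas.items():
        eta += b * profiles[name].to_numpy(dtype=float)
    lam = np.exp(eta)
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=len(profiles))
    return (-np.log(u) / lam) ** (1.0 / p)


def _screening_times(rng, n: int, policy: SchedulePolicy) -> np.ndarray:
    """Matrix of screen times (row per subject); NaN past follow-up.

    Screens sit at k * interval + jitter; rows with non-increasing times
    are resampled.
    """
    k_max = int(np.floor((policy.followup_years + policy.jitter_years) / policy.interval_years))
    if k_max < 1:
        return np.zeros((n, 1))
    anchors = np.arange(1, k_max + 1) * policy.interval_years
    times = anchors[None, :] + rng.uniform(-policy.jitter_years, policy.jitter_years, size=(n, k_max))
    full = np.column_stack([np.zeros(n), times])
    bad = np.any(np.diff(full, axis=1) <= 0, axis=1)
    for _ in range(100):
        if not np.any(bad):
            break
        nb = int(bad.sum())
        full[bad, 1:] = anchors[None, :] + rng.uniform(
            -policy.jitter_years, policy.jitter_years, size=(nb, k_max)
        )
        bad = np.any(np.diff(full, axis=1) <= 0, axis=1)
    else:
        raise RuntimeError("could not draw strictly increasing screening times")
    full[:, 1:] = np.where(full[:, 1:] <= policy.followup_years, full[:, 1:], np.nan)
    return full


def _grade_at(t: np.ndarray, event_time: np.ndarray) -> np.ndarray:
    """Stylised screening grade on the path to RDR.

    Grades step NoDR -> MinBDR -> ModBDR as the latent onset time
    approaches (at 50% and 85% of it), then RDR from the onset onwards.
    """
    frac = t / event_time
    grade = np.full(t.shape, "NoDR", dtype=object)
    grade[frac >= 0.5] = "MinBDR"
    grade[frac >= 0.85] = "ModBDR"
    grade[frac >= 1.0] = "RDR"
    return grade


def _hba1c_drift(rng, n: int, cfg: GeneratorConfig):
    b1 = rng.normal(0.0, cfg.hba1c_slope_sd, size=n)
    b2 = rng.normal(0.0, cfg.hba1c_curv_sd, size=n)
    return b1, b2


def apply_screening_schedule(
    cohort, policy: SchedulePolicy, seed: int
) -> pd.DataFrame:
    """Convert exact onset times to interval-censored screening records.

    ``cohort`` may be a :class:`CohortDataset` or a ``(profiles,
    true_times)`` pair.  Each subject's onset is bracketed by the last
    negative and first positive scheduled screen; onsets beyond follow-up
    (or beyond the last attended screen) are right-censored with
    ``right = +inf`` and ``left`` equal to the last attended screen.
    The covariate row carries the values used in the hazard.
    """
    if isinstance(cohort, CohortDataset):
        profiles, true_times = cohort.profiles, cohort.true_times.to_numpy()
    else:
        profiles, true_times = cohort
        true_times = np.asarray(true_times, dtype=float)
    errors: list[str] = []
    policy.validate(errors)
    if errors:
        raise ValueError("; ".join(errors))
    n = len(profiles)
    if n == 0:
        return pd.DataFrame(columns=["subject_id", "diabetes_type", "left", "right"])
    rng = np.random.default_rng(seed)
    screens = _screening_times(rng, n, policy)
    lefts = np.empty(n)
    rights = np.empty(n)
    for i in range(n):
        row = screens[i][~np.isnan(screens[i])]
        T = true_times[i]
        after = row[row >= T]
        if after.size:
            rights[i] = after[0]
            lefts[i] = row[row < T][-1] if np.any(row < T) else 0.0
        else:
            lefts[i] = row[-1]
            rights[i] = np.inf
    rec = pd.DataFrame(
        {
            "subject_id": profiles["subject_id"].to_numpy(),
            "diabetes_type": profiles["diabetes_type"].to_numpy(),
            "left": lefts,
            "right": rights,
        }
    )
    for name in ("duration",) + CONTINUOUS_COVARIATES + FLAG_COVARIATES:
        if name in profiles:
            rec[name] = profiles[name].to_numpy()
    return rec


def generate_cohort(config: GeneratorConfig, seed: int) -> CohortDataset:
    """Generate a full synthetic cohort.

    Deterministic in ``(config, seed)``: the same pair always produces an
    identical dataset.  Empirical covariate means match the configured
    means to Monte-Carlo accuracy.
    """
    config.validate()
    master = np.random.SeedSequence(seed)
    s_profiles, s_times, s_sched, s_meas = master.spawn(4)

    rng_p = np.random.default_rng(s_profiles)
    profiles = pd.concat(
        [
            _draw_profiles(rng_p, config.t1dm, "T1DM"),
            _draw_profiles(rng_p, config.t2dm, "T2DM"),
        ],
        ignore_index=True,
    )
    n = len(profiles)

    # latent onset times per type from the configured Weibull PH law
    times = np.empty(n)
    seeds_t = np.random.default_rng(s_times).integers(0, 2**31 - 1, size=2)
    for j, (dtype, cfg) in enumerate([("T1DM", config.t1dm), ("T2DM", config.t2dm)]):
        mask = (profiles["diabetes_type"] == dtype).to_numpy()
        if mask.any():
            times[mask] = simulate_progression_times(cfg, profiles[mask], int(seeds_t[j]))
    true_times = pd.Series(times, index=profiles.index, name="true_time")

    # screening events with jitter, stopping at first RDR screen
    rng_s = np.random.default_rng(s_sched)
    screens = _screening_times(rng_s, n, config.schedule)
    drift1, drift2 = _hba1c_drift(rng_s, n, config)
    sid = profiles["subject_id"].to_numpy()
    dty = profiles["diabetes_type"].to_numpy()
    base_hba = profiles["hba1c"].to_numpy()
    ev_sid, ev_dty, ev_t, ev_grade, ev_hba = [], [], [], [], []
    for i in range(n):
        row = screens[i][~np.isnan(screens[i])]
        grades = _grade_at(row, times[i])
        stop = np.argmax(grades == "RDR") + 1 if np.any(grades == "RDR") else len(row)
        t_i = row[:stop]
        ev_sid.append(np.repeat(sid[i], stop))
        ev_dty.append(np.repeat(dty[i], stop))
        ev_t.append(t_i)
        ev_grade.append(grades[:stop])
        ev_hba.append(base_hba[i] + drift1[i] * t_i + drift2[i] * t_i**2)
    events = pd.DataFrame(
        {
            "subject_id": np.concatenate(ev_sid) if ev_sid else [],
            "diabetes_type": np.concatenate(ev_dty) if ev_dty else [],
            "time_years": np.concatenate(ev_t) if ev_t else [],
            "grade": np.concatenate(ev_grade) if ev_grade else [],
            "hba1c": np.concatenate(ev_hba) if ev_hba else [],
        }
    )

    # irregular GP measurement series (HbA1c with quadratic drift, SBP flat)
    rng_m = np.random.default_rng(s_meas)
    horizon = config.schedule.followup_years
    k = max(int(np.floor(horizon / config.gp_visit_interval)), 1)
    t_m = np.arange(1, k + 1)[None, :] * config.gp_visit_interval + rng_m.uniform(
        -config.gp_visit_jitter, config.gp_visit_jitter, size=(n, k)
    )
    t_m = np.sort(np.clip(t_m, 0.01, horizon), axis=1)
    t_m = np.column_stack([np.zeros(n), t_m])  # baseline measurement at entry
    hba_vals = (
        base_hba[:, None]
        + drift1[:, None] * t_m
        + drift2[:, None] * t_m**2
        + rng_m.normal(0.0, config.hba1c_noise_sd, size=t_m.shape)
    )
    sbp_vals = profiles["sbp"].to_numpy()[:, None] + rng_m.normal(
        0.0, config.sbp_noise_sd, size=t_m.shape
    )
    m = t_m.shape[1]
    measurements = pd.DataFrame(
        {
            "subject_id": np.concatenate([np.repeat(sid, m), np.repeat(sid, m)]),
            "time_years": np.concatenate([t_m.ravel(), t_m.ravel()]),
            "analyte": np.concatenate([np.repeat("hba1c", n * m), np.repeat("sbp", n * m)]),
            "value": np.concatenate([hba_vals.ravel(), sbp_vals.ravel()]),
        }
    )

    # Records share the event-level screening grid, so `left` is always an
    # attended screen time of the same realisation.
    records = _records_from_grid(profiles, times, screens)
    return CohortDataset(profiles, events, measurements, records, true_times)


def _records_from_grid(profiles: pd.DataFrame, times: np.ndarray, screens: np.ndarray) -> pd.DataFrame:
    n = len(profiles)
    lefts = np.empty(n)
    rights = np.empty(n)
    for i in range(n):
        row = screens[i][~np.isnan(screens[i])]
        T = times[i]
        after = row[row >= T]
        if after.size:
            rights[i] = after[0]
            lefts[i] = row[row < T][-1] if np.any(row < T) else 0.0
        else:
            lefts[i] = row[-1]
            rights[i] = np.inf
    rec = pd.DataFrame(
        {
            "subject_id": profiles["subject_id"].to_numpy(),
            "diabetes_type": profiles["diabetes_type"].to_numpy(),
            "left": lefts,
            "right": rights,
        }
    )
    for name in ("duration",) + CONTINUOUS_COVARIATES + FLAG_COVARIATES:
        if name in profiles:
            rec[name] = profiles[name].to_numpy()
    return rec
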