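"""Multi-state Markov cohort model of retinopathy screening pathways.

The cohort enters disease-free at the first screening event and moves,
in 6-month cycles, through:

* three pre-referable screening grades (NoDR, MinBDR, ModBDR), all of
  which feed the referable-retinopathy (RDR) onset hazard supplied by
  the interval-censored survival model;
* a 10-state RDR severity pathway, tracked separately while *undetected*
  (between screens) and after referral to the hospital eye service
  (HES).  Undetected disease progresses untreated with the same
  severity transitions ("unidentified progression");
* detection, which can occur only at screening cycles implied by the
  strategy (every 2nd cycle under annual screening, every 4th under
  biennial), and applies the 50% one-step "knockback" adjustment that
  models false-positive referrals discharged after the first HES visit;
* per-cycle treatment assignment within HES, after which treated people
  are stationary apart from mortality;
* severe vision loss, split between living-at-home and care-home
  residence tiers; and
* death, from national life-table rates multiplied by a diabetes-type
  mortality factor.

All occupancy mass is carried in double precision; rows of every
composed per-cycle matrix sum to one within 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol

import numpy as np
import pandas as pd

from . import states as st
from .icsurv import WeibullPHFit, cycle_transition_prob

__all__ = [
    "LifeTable",
    "TransitionTables",
    "TransitionModel",
    "StrategySpec",
    "CohortStratum",
    "MarkovTrace",
    "WeibullOnset",
    "ConstantOnset",
    "adjust_mortality",
    "knockback_matrix",
    "knockback_adjust",
    "untreated_progression",
    "build_hes_entry_distribution",
    "build_transition_matrix",
    "run_cohort",
    "ANNUAL",
    "BIENNIAL",
]

RESOURCE_COLUMNS = (
    "screening_visits",
    "hes_visits",
    "oct",
    "laser",
    "anti_vegf",
    "vitrectomy",
    "svl_home_py",
    "svl_care_py",
)


# ---------------------------------------------------------------------------
# inputs


@dataclass
class LifeTable:
    """Single-year-of-age annual death probabilities (ONS layout: age, qx)."""

    age: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValueError("life table qx values must lie in [0, 1]")
        if np.any(np.diff(self.age) != 1):
            raise ValueError("life table must cover consecutive single-year ages")

    def annual_qx(self, age: float) -> float:
        """qx at the containing single-year age, clamped to the table range."""
        i = int(np.clip(np.floor(age), self.age[0], self.age[-1]) - self.age[0])
        return float(self.qx[i])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.age, "qx": self.qx}).to_csv(path, index=False)


def adjust_mortality(qx_annual: float, multiplier: float, cycle_length: float) -> float:
    """Per-cycle death probability from an adjusted annual rate.

    ``q = 1 - (1 - min(qx * multiplier, 1))**cycle_length``; capped so
    the adjusted annual probability never exceeds one, and exactly
    compounding back to it over ``1/cycle_length`` cycles.
    """
    if not 0.0 <= qx_annual <= 1.0:
        raise ValueError(f"annual qx must lie in [0,1], got {qx_annual}")
    if multiplier <= 0:
        raise ValueError(f"mortality multiplier must be > 0, got {multiplier}")
    adj = min(qx_annual * multiplier, 1.0)
    return 1.0 - (1.0 - adj) ** cycle_length


@dataclass
class TransitionTables:
    """Fixed transition structure of the RDR pathway and HES treatment.

    ``hes`` is the per-cycle 10x10 row-stochastic severity transition
    matrix while under (or awaiting) HES care; ``rdr_entry`` the severity
    mix at RDR onset; ``p_treat`` per-cycle treatment probabilities per
    severity; ``treat_resources`` expected procedure counts (OCT, laser,
    anti-VEGF, vitrectomy) charged once at treatment; ``svl_home_fraction``
    the share of severe-vision-loss mass residing at home rather than in
    care.  Shipped defaults are synthetic test fixtures, not study values.
    """

    hes: np.ndarray
    rdr_entry: np.ndarray
    pre_rdr_minbdr: float = 0.03
    pre_rdr_modbdr: float = 0.03
    p_treat: np.ndarray = field(default_factory=lambda: np.zeros(st.N_RDR))
    treat_resources: np.ndarray = field(default_factory=lambda: np.zeros((st.N_RDR, 4)))
    svl_home_fraction: float = 0.9

    def __post_init__(self) -> None:
        self.hes = np.asarray(self.hes, dtype=float)
        self.rdr_entry = np.asarray(self.rdr_entry, dtype=float)
        self.p_treat = np.asarray(self.p_treat, dtype=float)
        self.treat_resources = np.asarray(self.treat_resources, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.hes.shape != (st.N_RDR, st.N_RDR):
            raise ValueError(f"hes matrix must be {st.N_RDR}x{st.N_RDR}")
        if np.any((self.hes < 0) | (self.hes > 1)):
            raise ValueError("hes matrix entries must lie in [0, 1]")
        rs = self.hes.sum(axis=1)
        if np.any(np.abs(rs - 1.0) > 1e-10):
            bad = st.RDR_SEVERITY[int(np.argmax(np.abs(rs - 1.0)))]
            raise ValueError(f"hes matrix row for {bad} does not sum to 1")
        if abs(self.rdr_entry.sum() - 1.0) > 1e-10 or np.any(self.rdr_entry < 0):
            raise ValueError("rdr_entry must be a probability distribution")
        if np.any((self.p_treat < 0) | (self.p_treat > 1)):
            raise ValueError("p_treat entries must lie in [0, 1]")
        for nm, v in [("pre_rdr_minbdr", self.pre_rdr_minbdr), ("pre_rdr_modbdr", self.pre_rdr_modbdr)]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1], got {v}")
        if not 0.0 <= self.svl_home_fraction <= 1.0:
            raise ValueError("svl_home_fraction must lie in [0, 1]")
        if np.any(self.treat_resources < 0):
            raise ValueError("treat_resources counts must be >= 0")


class OnsetModel(Protocol):
    def prob(self, stratum: "CohortStratum", t: float, dt: float) -> float: ...


@dataclass
class WeibullOnset:
    """RDR onset hazard from a fitted interval-censored Weibull model."""

    fit: WeibullPHFit

    def prob(self, stratum, t, dt):
        return cycle_transition_prob(self.fit, stratum.covariates, t, dt)


@dataclass
class ConstantOnset:
    """Fixed per-cycle onset probability (loaded-table alternative)."""

    per_cycle: float

    def prob(self, stratum, t, dt):
        return self.per_cycle


@dataclass
class TransitionModel:
    """Everything needed to compose per-cycle transition matrices."""

    onset: Mapping[str, OnsetModel]  # keyed by diabetes type
    tables: TransitionTables
    life_table: LifeTable
    mortality_multipliers: dict[str, float] = field(
        default_factory=lambda: {"T1DM": 3.0, "T2DM": 1.5}
    )

    def onset_probability(self, stratum, t, dt) -> float:
        try:
            model = self.onset[stratum.diabetes_type]
        except KeyError as exc:
            raise KeyError(f"no onset model for diabetes type {exc}") from exc
        p = model.prob(stratum, t, dt)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"onset probability {p} outside [0,1] at t={t}")
        return p


@dataclass
class StrategySpec:
    """A screening recall strategy.

    ``interval_years`` must be a positive multiple of the 6-month cycle;
    the published comparison uses 1 (annual) and 2 (biennial).  With
    ``eligibility_rule`` set, the first recall after entry stays annual
    (the "two prior negative screens" gate before extending the
    interval).
    """

    name: str
    interval_years: float
    eligibility_rule: bool = False

    def __post_init__(self) -> None:
        cycles = self.interval_years / st.CYCLE_YEARS
        if self.interval_years <= 0 or abs(cycles - round(cycles)) > 1e-9:
            raise ValueError(
                f"screening interval must be a positive multiple of {st.CYCLE_YEARS} y, "
                f"got {self.interval_years}"
            )

    @property
    def cycles_per_screen(self) -> int:
        return int(round(self.interval_years / st.CYCLE_YEARS))

    def is_screen_boundary(self, cycle_index: int) -> bool:
        """Whether a screen happens at cycle boundary ``cycle_index`` (> 0)."""
        if cycle_index <= 0:
            return False
        if cycle_index % self.cycles_per_screen == 0:
            return True
        return self.eligibility_rule and cycle_index == int(round(1.0 / st.CYCLE_YEARS))


ANNUAL = StrategySpec("annual", 1.0)
BIENNIAL = StrategySpec("biennial", 2.0)


@dataclass
class CohortStratum:
    """One modelled stratum: diabetes type x covariate profile."""

    diabetes_type: str
    age_at_entry: float
    covariates: dict[str, float]
    weight: float = 1.0
    label: str = ""


# ---------------------------------------------------------------------------
# bespoke adjustment rules


def knockback_matrix() -> np.ndarray:
    """The 50% one-severity-step knockback operator over RDR states.

    Models false-positive referrals discharged after the first HES
    appointment: half of the mass of each non-minimal severity state
    moves one step down the severity order; the minimal state keeps its
    mass.  Mass-conserving by construction.
    """
    K = np.zeros((st.N_RDR, st.N_RDR))
    K[0, 0] = 1.0
    for k in range(1, st.N_RDR):
        K[k, k] = 0.5
        K[k, k - 1] = 0.5
    return K


def knockback_adjust(rdr_distribution) -> np.ndarray:
    d = np.asarray(rdr_distribution, dtype=float)
    if d.shape != (st.N_RDR,):
        raise ValueError(f"distribution must have length {st.N_RDR}")
    if np.any(d < 0):
        raise ValueError("distribution has negative mass")
    return d @ knockback_matrix()


def untreated_progression(rdr_distribution, hes_transitions) -> np.ndarray:
    """One year (two 6-month steps) of untreated severity progression.

    Applied to disease that entered RDR early in a biennial interval and
    progressed before anyone could refer it; no treatment exits, mass
    conserved.
    """
    d = np.asarray(rdr_distribution, dtype=float)
    H = np.asarray(hes_transitions, dtype=float)
    return d @ H @ H


def build_hes_entry_distribution(current_rdr_mix, hes_transitions) -> np.ndarray:
    """Severity mix at the first HES visit.

    The prevailing RDR mix is progressed one year through the severity
    transitions and renormalised.
    """
    d = np.asarray(current_rdr_mix, dtype=float)
    total = d.sum()
    if total <= 0:
        raise ValueError("RDR mix has zero mass; cannot form an entry distribution")
    out = untreated_progression(d / total, hes_transitions)
    return out / out.sum()


# ---------------------------------------------------------------------------
# per-cycle matrix composition


def _hes_route_matrix(tables: TransitionTables):
    """Routing applied after a within-HES severity step.

    State j exits to its treated state with probability ``p_treat[j]``
    (charging the per-severity procedure bundle), stays untreated in HES
    otherwise; severity SevereLossOfVision routes to the home/care
    residence split instead.  Returns the (10, N_STATES) routing matrix
    and the (10, 4) expected-resource matrix conditional on occupying
    severity j after the step.
    """
    route = np.zeros((st.N_RDR, st.N_STATES))
    res = np.zeros((st.N_RDR, 4))
    i_hes0 = st.I_HES.start
    i_home, i_care = st.I_SVL.start, st.I_SVL.start + 1
    for j, name in enumerate(st.RDR_SEVERITY):
        if j == st.SLV_RANK:
            route[j, i_home] = tables.svl_home_fraction
            route[j, i_care] = 1.0 - tables.svl_home_fraction
            continue
        pt = tables.p_treat[j]
        route[j, i_hes0 + j] = 1.0 - pt
        route[j, st.STATE_INDEX[st.TREATED_TARGET[name]]] = pt
        res[j] = pt * tables.treat_resources[j]
    return route, res


def _alive_dynamics(model: TransitionModel, strategy: StrategySpec, h: float, detect: bool):
    """The alive-conditional dynamics matrix D and treatment-resource rows."""
    S = st.N_STATES
    tab = model.tables
    H = tab.hes
    K = knockback_matrix()
    D = np.zeros((S, S))

    onset_vec = np.zeros(S)
    if detect:
        onset_vec[st.I_HES] = tab.rdr_entry @ K
    else:
        onset_vec[st.I_UND] = tab.rdr_entry

    g1, g2 = tab.pre_rdr_minbdr, tab.pre_rdr_modbdr
    for i in range(3):
        D[i] = h * onset_vec
    D[0, 0] += (1.0 - h) * (1.0 - g1)
    D[0, 1] += (1.0 - h) * g1
    D[1, 1] += (1.0 - h) * (1.0 - g2)
    D[1, 2] += (1.0 - h) * g2
    D[2, 2] += 1.0 - h

    # undetected RDR progresses untreated; at a screen it is referred
    # with the knockback applied at HES entry
    if detect:
        D[st.I_UND, st.I_HES] = H @ K
    else:
        D[st.I_UND, st.I_UND] = H

    route, res = _hes_route_matrix(model.tables)
    D[st.I_HES] = H @ route
    treat_res = np.zeros((S, 4))
    treat_res[st.I_HES] = H @ res

    for i in list(range(st.I_TREATED.start, st.I_TREATED.stop)) + list(
        range(st.I_SVL.start, st.I_SVL.stop)
    ):
        D[i, i] = 1.0
    return D, treat_res


def _cycle_inputs(model, strategy, stratum, cycle_index):
    t = st.CYCLE_YEARS * cycle_index
    q = adjust_mortality(
        model.life_table.annual_qx(stratum.age_at_entry + t),
        model.mortality_multipliers[stratum.diabetes_type],
        st.CYCLE_YEARS,
    )
    h = model.onset_probability(stratum, t, st.CYCLE_YEARS)
    detect = strategy.is_screen_boundary(cycle_index + 1)
    return q, h, detect


def build_transition_matrix(
    model: TransitionModel,
    strategy: StrategySpec,
    cohort_stratum: CohortStratum,
    cycle_index: int,
) -> np.ndarray:
    """Full per-cycle transition matrix for one cycle of one strategy.

    Composes the screening-state dynamics, HES severity dynamics,
    detection (only at screening boundaries implied by the strategy) and
    life-table mortality as independent competing risks: death occurs
    with the per-cycle probability ``q``; survivors follow the disease
    dynamics.  Rows sum to one within 1e-10 and any negative composed
    entry is a hard error naming the offending cells.
    """
    q, h, detect = _cycle_inputs(model, strategy, cohort_stratum, cycle_index)
    D, _ = _alive_dynamics(model, strategy, h, detect)
    P = (1.0 - q) * D
    P[:, st.I_DEAD] += q
    P[st.I_DEAD] = 0.0
    P[st.I_DEAD, st.I_DEAD] = 1.0
    _check_stochastic(P, cycle_index)
    return P


def _check_stochastic(P: np.ndarray, cycle_index: int) -> None:
    if np.any(P < -1e-12):
        rows, cols = np.where(P < -1e-12)
        cells = ", ".join(
            f"({st.ALL_STATES[r]} -> {st.ALL_STATES[c]}) = {P[r, c]:.3e}"
            for r, c in zip(rows[:5], cols[:5])
        )
        raise ValueError(f"negative transition probabilities at cycle {cycle_index}: {cells}")
    rowsum = P.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-10):
        bad = int(np.argmax(np.abs(rowsum - 1.0)))
        raise ValueError(
            f"non-stochastic transition matrix at cycle {cycle_index}: "
            f"row {st.ALL_STATES[bad]} sums to {rowsum[bad]!r}"
        )


# ---------------------------------------------------------------------------
# cohort iteration


@dataclass
class MarkovTrace:
    """Per-cycle state occupancy and resource-use streams for one strategy."""

    strategy: str
    occupancy: np.ndarray  # (n_cycles + 1, N_STATES)
    ages: np.ndarray       # (n_cycles + 1,)
    resources: pd.DataFrame  # n_cycles rows, RESOURCE_COLUMNS

    @property
    def n_cycles(self) -> int:
        return len(self.resources)

    def state_series(self, name: str) -> np.ndarray:
        return self.occupancy[:, st.STATE_INDEX[name]]

    def alive_mass(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, st.I_DEAD]

    def life_expectancy(self) -> float:
        """Undiscounted person-years lived, counting start-of-cycle occupancy."""
        return float(st.CYCLE_YEARS * self.alive_mass()[: self.n_cycles].sum())

    def to_frame(self) -> pd.DataFrame:
        occ = pd.DataFrame(self.occupancy[:-1], columns=list(st.ALL_STATES))
        occ.insert(0, "cycle", np.arange(self.n_cycles))
        occ.insert(1, "age", self.ages[:-1])
        return pd.concat([occ, self.resources.reset_index(drop=True)], axis=1)


def run_cohort(
    model: TransitionModel,
    strategy: StrategySpec,
    stratum: CohortStratum,
    horizon_age: float = 100.0,
    *,
    max_cycles: int | None = None,
) -> MarkovTrace:
    """Iterate the cohort to the horizon (age 100 or cohort extinction).

    The trace records state occupancy at every cycle boundary plus the
    per-cycle resource streams that the economics layer prices:
    screening visits (community states attending at screen boundaries),
    HES visits (monitoring while untreated in HES, plus the referral
    visit), expected treatment procedures, and person-years of severe
    vision loss by residence tier.
    """
    S = st.N_STATES
    occ = np.zeros(S)
    occ[st.STATE_INDEX["NoDR"]] = 1.0

    n_cycles = int(np.ceil((horizon_age - stratum.age_at_entry) / st.CYCLE_YEARS))
    if max_cycles is not None:
        n_cycles = min(n_cycles, max_cycles)
    if n_cycles < 1:
        raise ValueError("horizon does not cover a single cycle")

    occ_hist = [occ.copy()]
    res_hist = []
    community = np.arange(st.COMMUNITY.start, st.COMMUNITY.stop)
    hes_idx = np.arange(st.I_HES.start, st.I_HES.stop)
    i_home, i_care = st.I_SVL.start, st.I_SVL.start + 1

    for k in range(n_cycles):
        q, h, detect = _cycle_inputs(model, strategy, stratum, k)
        D, treat_res = _alive_dynamics(model, strategy, h, detect)
        P = (1.0 - q) * D
        P[:, st.I_DEAD] += q
        P[st.I_DEAD] = 0.0
        P[st.I_DEAD, st.I_DEAD] = 1.0
        _check_stochastic(P, k)

        occ_next = occ @ P
        if abs(occ_next.sum() - 1.0) > 1e-9:
            raise RuntimeError(f"occupancy mass not conserved at cycle {k}")

        surv = 1.0 - q
        screen_visits = float(occ[community].sum() * surv) if detect else 0.0
        # referral inflow: community mass that survives the cycle and lands in HES
        detected = float((occ[community] * surv) @ D[community][:, hes_idx].sum(axis=1))
        hes_visits = float(occ[hes_idx].sum() * surv + detected)
        treat = (occ * surv) @ treat_res  # (4,) expected procedure counts
        res_hist.append(
            {
                "screening_visits": screen_visits,
                "hes_visits": hes_visits,
                "oct": treat[0],
                "laser": treat[1],
                "anti_vegf": treat[2],
                "vitrectomy": treat[3],
                "svl_home_py": float(occ[i_home] * st.CYCLE_YEARS),
                "svl_care_py": float(occ[i_care] * st.CYCLE_YEARS),
            }
        )
        if occ_next[st.I_DEAD] < occ[st.I_DEAD] - 1e-12:
            raise RuntimeError(f"dead mass decreased at cycle {k}")
        occ = occ_next
        occ_hist.append(occ.copy())
        if occ[st.I_DEAD] > 1.0 - 1e-6:
            break

    occupancy = np.vstack(occ_hist)
    ages = stratum.age_at_entry + st.CYCLE_YEARS * np.arange(len(occ_hist))
    return MarkovTrace(
        strategy=strategy.name,
        occupancy=occupancy,
        ages=ages,
        resources=pd.DataFrame(res_hist, columns=list(RESOURCE_COLUMNS)),
    )


# ---------------------------------------------------------------------------
# fixture construction (synthetic, clearly non-study values)


def default_transition_tables() -> TransitionTables:
    """Synthetic RDR-pathway fixture tables.

    Severity progression accelerates with rank; the onset severity mix
    concentrates in pre-proliferative and maculopathy disease; treatment
    probabilities and procedure bundles are plausible fixtures labelled
    non-study values throughout.
    """
    H = np.eye(st.N_RDR)
    step1 = [0.08, 0.09, 0.10, 0.11, 0.12, 0.13, 0.14, 0.15, 0.16]
    for i in range(st.N_RDR - 1):
        skip = 0.02 if i < st.N_RDR - 2 else 0.0
        H[i, i] = 1.0 - step1[i] - skip
        H[i, i + 1] = step1[i]
        if skip:
            H[i, i + 2] = skip
    entry = np.zeros(st.N_RDR)
    entry[:4] = [0.55, 0.25, 0.15, 0.05]
    # Pre-proliferative disease is monitored, not treated; treatment rates
    # rise with severity.
    p_treat = np.array([0.0, 0.35, 0.35, 0.55, 0.55, 0.65, 0.65, 0.70, 0.70, 0.0])
    # columns: oct, laser, anti_vegf, vitrectomy
    res = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [2.0, 0.0, 3.0, 0.0],
            [2.0, 0.5, 3.0, 0.0],
            [0.0, 1.5, 0.0, 0.0],
            [2.0, 1.5, 3.0, 0.0],
            [0.0, 2.0, 0.0, 0.0],
            [2.0, 2.0, 3.0, 0.0],
            [0.0, 2.0, 0.0, 0.3],
            [2.0, 2.0, 2.0, 0.5],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    return TransitionTables(
        hes=H,
        rdr_entry=entry,
        p_treat=p_treat,
        treat_resources=res,
        svl_home_fraction=0.9,
    )


def synthetic_life_table(age_min: int = 12, age_max: int = 100) -> LifeTable:
    """A Gompertz-Makeham national-style life table (synthetic stand-in
    for the ONS table, same layout)."""
    ages = np.arange(age_min, age_max + 1)
    qx = np.minimum(2e-4 + 3.5e-5 * np.exp(0.09 * ages), 1.0)
    return LifeTable(ages, qx)
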