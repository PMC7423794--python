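"""Costing, utilities, discounting and the decremental cost-effectiveness
ratio (DCER) decision rule.

Costs are 2018 GBP from an NHS + personal-social-services perspective.
Extending screening from annual to biennial typically *saves* money and
*loses* a little health, so the comparison produces a DCER (GBP saved
per QALY forgone); the decision rule is the reverse of the ICER rule:
a DCER at or above the willingness-to-pay threshold (20,000 GBP/QALY)
means the savings justify the loss and biennial screening is deemed
cost-effective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import states as st
from .markov import MarkovTrace

__all__ = [
    "CostTable",
    "UtilityTable",
    "DiscountSpec",
    "CEResult",
    "discount_factor",
    "accumulate",
    "compute_dcer",
]

#: Published EQ-5D weights for the referable-retinopathy severity states.
RDR_UTILITIES = {
    "PreProlif": 0.7915,
    "Mac": 0.7365,
    "PreProlifMac": 0.7365,
    "EasyToTreatProlif": 0.7047,
    "EasyToTreatProlifMac": 0.693,
    "HighRiskProlif": 0.7047,
    "HighRiskProlifMacVI": 0.693,
    "SevereProlif": 0.7047,
    "SevereProlifMacVL": 0.693,
    "SevereLossOfVision": 0.6218,
}

#: Which proliferative/maculopathy complication track a state sits on, for
#: the within-track monotonicity check of utility weights.
_TRACKS = (
    ("PreProlif", "EasyToTreatProlif", "HighRiskProlif", "SevereProlif", "SevereLossOfVision"),
    ("Mac", "PreProlifMac", "EasyToTreatProlifMac", "HighRiskProlifMacVI", "SevereProlifMacVL", "SevereLossOfVision"),
)


@dataclass
class CostTable:
    """Unit costs, 2018 GBP (screening/treatment resource table)."""

    screening_visit: float = 33.0
    hes_visit: float = 106.0
    oct_scan: float = 117.0
    laser: float = 131.0
    anti_vegf: float = 822.0
    vitrectomy: float = 989.0
    sight_loss_home_pa: float = 1483.0
    sight_loss_care_pa: float = 6972.0
    price_year: int = 2018

    def validate(self) -> None:
        for name, v in self.__dict__.items():
            if name != "price_year" and v < 0:
                raise ValueError(f"cost {name} must be >= 0, got {v}")


@dataclass
class UtilityTable:
    """EQ-5D utility weights per health state.

    RDR-state weights are published values; the pre-referable weight
    (healthy with diabetes) is a configurable non-study default of 0.80.
    Treated states carry the weight of a stabilised case of the treated
    disease; severe-vision-loss residence states carry the severe
    loss-of-vision weight.
    """

    rdr: dict[str, float] = field(default_factory=lambda: dict(RDR_UTILITIES))
    pre_rdr: float = 0.80
    treated: dict[str, float] = field(
        default_factory=lambda: {
            "Treated_STDR": 0.7047,
            "Treated_Mac": 0.7365,
            "Treated_Both": 0.693,
        }
    )
    svl: float = 0.6218

    def validate(self, *, strict: bool = True) -> None:
        values = list(self.rdr.values()) + list(self.treated.values()) + [self.pre_rdr, self.svl]
        for v in values:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"utility weight {v} outside [0, 1]")
        if strict:
            for track in _TRACKS:
                present = [s for s in track if s in self.rdr]
                w = [self.rdr[s] for s in present]
                if any(b > a + 1e-12 for a, b in zip(w, w[1:])):
                    raise ValueError(
                        f"utility weights must be non-increasing along severity track {present}"
                    )

    def weight_vector(self) -> np.ndarray:
        """Weights aligned to the full model state space.

        A severity state missing from the table is a hard error naming
        the state.
        """
        w = np.zeros(st.N_STATES)
        w[st.I_PRE] = self.pre_rdr
        for j, name in enumerate(st.RDR_SEVERITY):
            if name not in self.rdr:
                raise KeyError(f"utility table has no weight for state '{name}'")
            w[st.I_UND.start + j] = self.rdr[name]
            w[st.I_HES.start + j] = self.rdr[name]
        for j, name in enumerate(st.TREATED):
            if name not in self.treated:
                raise KeyError(f"utility table has no weight for state '{name}'")
            w[st.I_TREATED.start + j] = self.treated[name]
        w[st.I_SVL] = self.svl
        w[st.I_DEAD] = 0.0
        return w


@dataclass
class DiscountSpec:
    """Annual discount rate with discrete per-cycle factors.

    Base rate 3.5% per annum (1.5% in sensitivity analysis).  With
    ``midpoint`` set (the default) flows in cycle k are discounted to
    the cycle midpoint t = (k + 0.5) * 0.5 years.
    """

    rate: float = 0.035
    midpoint: bool = True

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"discount rate must be >= 0, got {self.rate}")


def discount_factor(spec: DiscountSpec, time_years: float):
    """(1 + rate)^(-t); equal to one at t = 0."""
    t = np.asarray(time_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("discounting requested at negative time")
    out = (1.0 + spec.rate) ** (-t)
    return float(out) if out.ndim == 0 else out


def accumulate(
    trace: MarkovTrace, costs: CostTable, utilities: UtilityTable, spec: DiscountSpec
) -> tuple[float, float]:
    """Discounted (cost, QALYs) for one strategy's trace.

    Per cycle: cost = priced resource streams of the cycle; utility =
    start-of-cycle occupancy x state weight x 0.5 years.  Both are
    multiplied by the cycle's discount factor and summed.
    """
    costs.validate()
    utilities.validate(strict=False)
    w = utilities.weight_vector()
    K = trace.n_cycles
    k = np.arange(K)
    t = (k + 0.5) * st.CYCLE_YEARS if spec.midpoint else k * st.CYCLE_YEARS
    d = discount_factor(spec, t)

    r = trace.resources
    cost_per_cycle = (
        r["screening_visits"].to_numpy() * costs.screening_visit
        + r["hes_visits"].to_numpy() * costs.hes_visit
        + r["oct"].to_numpy() * costs.oct_scan
        + r["laser"].to_numpy() * costs.laser
        + r["anti_vegf"].to_numpy() * costs.anti_vegf
        + r["vitrectomy"].to_numpy() * costs.vitrectomy
        + r["svl_home_py"].to_numpy() * costs.sight_loss_home_pa
        + r["svl_care_py"].to_numpy() * costs.sight_loss_care_pa
    )
    qaly_per_cycle = trace.occupancy[:K] @ w * st.CYCLE_YEARS
    return float(cost_per_cycle @ d), float(qaly_per_cycle @ d)


# ---------------------------------------------------------------------------
# decision rule


@dataclass
class CEResult:
    """Incremental comparison of biennial against annual screening.

    ``delta_cost``/``delta_qalys`` are biennial minus annual.  ``kind``
    records which quadrant of the cost-effectiveness plane the increment
    falls in: ``dcer`` (saves money, loses QALYs), ``icer`` (costs
    money, gains QALYs), ``dominant`` (saves money, no QALY loss),
    ``dominated`` (costs money, no gain), or ``equivalent``.  The ratio
    is defined only for the dcer/icer kinds; a DCER at or above the
    threshold counts as cost-effective (boundary inclusive), an ICER at
    or below it.
    """

    cost_annual: float
    qalys_annual: float
    cost_biennial: float
    qalys_biennial: float
    delta_cost: float
    delta_qalys: float
    ratio: float | None
    kind: str
    threshold: float
    cost_effective: bool

    def as_dict(self) -> dict:
        return {
            "cost_annual": self.cost_annual,
            "qalys_annual": self.qalys_annual,
            "cost_biennial": self.cost_biennial,
            "qalys_biennial": self.qalys_biennial,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "dcer": self.ratio if self.ratio is not None else float("nan"),
            "kind": self.kind,
            "cost_effective": self.cost_effective,
        }


def compute_dcer(
    annual: tuple[float, float], biennial: tuple[float, float], threshold: float = 20000.0
) -> CEResult:
    """Apply the DCER decision rule to two (cost, QALY) pairs.

    Both strategies must have been evaluated on identical strata and
    horizon; increments are biennial minus annual.
    """
    ca, ea = float(annual[0]), float(annual[1])
    cb, eb = float(biennial[0]), float(biennial[1])
    for v in (ca, ea, cb, eb):
        if not math.isfinite(v):
            raise ValueError("non-finite cost/QALY input to compute_dcer")
    dc, de = cb - ca, eb - ea

    ratio: float | None = None
    if dc < 0 and de < 0:
        kind = "dcer"
        ratio = dc / de  # positive: GBP saved per QALY forgone
        ce = ratio >= threshold
    elif dc > 0 and de > 0:
        kind = "icer"
        ratio = dc / de
        ce = ratio <= threshold
    elif dc <= 0 and de >= 0:
        kind = "equivalent" if (dc == 0 and de == 0) else "dominant"
        ce = True
    else:  # dc > 0 and de <= 0, or dc >= 0 and de < 0
        kind = "dominated"
        ce = False
    return CEResult(
        cost_annual=ca,
        qalys_annual=ea,
        cost_biennial=cb,
        qalys_biennial=eb,
        delta_cost=dc,
        delta_qalys=de,
        ratio=ratio,
        kind=kind,
        threshold=threshold,
        cost_effective=ce,
    )
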