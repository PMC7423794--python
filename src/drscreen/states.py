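"""Health-state space of the retinopathy screening model.

The model tracks a cohort through three pre-referable screening grades,
ten referable-retinopathy (RDR) severity states — duplicated into an
*undetected* zone (disease present, subject still attending community
screening) and a *hospital eye service* (HES) zone (disease detected and
under specialist monitoring) — three absorbing treated states, two severe
vision-loss residence states and death.
"""

from __future__ import annotations

import numpy as np

#: Screening grades below the referable threshold, in increasing severity.
PRE_RDR = ("NoDR", "MinBDR", "ModBDR")

#: Referable-retinopathy severity states in strictly increasing total order.
#: The index in this tuple is the severity rank used by the knockback rule.
RDR_SEVERITY = (
    "PreProlif",
    "Mac",
    "PreProlifMac",
    "EasyToTreatProlif",
    "EasyToTreatProlifMac",
    "HighRiskProlif",
    "HighRiskProlifMacVI",
    "SevereProlif",
    "SevereProlifMacVL",
    "SevereLossOfVision",
)

TREATED = ("Treated_STDR", "Treated_Mac", "Treated_Both")
SVL = ("SVL_Home", "SVL_Care")
DEAD = "Dead"

UNDETECTED_RDR = tuple(f"RDR:{s}" for s in RDR_SEVERITY)
HES_RDR = tuple(f"HES:{s}" for s in RDR_SEVERITY)

ALL_STATES = PRE_RDR + UNDETECTED_RDR + HES_RDR + TREATED + SVL + (DEAD,)

N_RDR = len(RDR_SEVERITY)
N_STATES = len(ALL_STATES)

# index ranges into ALL_STATES
I_PRE = slice(0, 3)
I_UND = slice(3, 3 + N_RDR)
I_HES = slice(3 + N_RDR, 3 + 2 * N_RDR)
I_TREATED = slice(3 + 2 * N_RDR, 3 + 2 * N_RDR + 3)
I_SVL = slice(3 + 2 * N_RDR + 3, 3 + 2 * N_RDR + 5)
I_DEAD = N_STATES - 1

#: States whose occupants attend community screening appointments.
COMMUNITY = slice(0, 3 + N_RDR)

STATE_INDEX = {name: i for i, name in enumerate(ALL_STATES)}

#: Severity rank (index into RDR_SEVERITY) of the vision-loss terminal state.
SLV_RANK = N_RDR - 1

# Treated-state routing: which absorbing treated state each RDR severity
# maps to once treatment is received.  Maculopathy disease without
# treatable proliferative change routes to Treated_Mac (for
# PreProlifMac only the maculopathy is treated; the pre-proliferative
# component is monitored), combined proliferative + maculopathy disease
# to Treated_Both, proliferative-only disease to Treated_STDR.
# SevereLossOfVision never routes to treatment (handled by the
# vision-loss split instead).
TREATED_TARGET = {
    "PreProlif": "Treated_STDR",
    "Mac": "Treated_Mac",
    "PreProlifMac": "Treated_Mac",
    "EasyToTreatProlif": "Treated_STDR",
    "EasyToTreatProlifMac": "Treated_Both",
    "HighRiskProlif": "Treated_STDR",
    "HighRiskProlifMacVI": "Treated_Both",
    "SevereProlif": "Treated_STDR",
    "SevereProlifMacVL": "Treated_Both",
}

#: Model cycle length in years ("a 6-month cycle").
CYCLE_YEARS = 0.5


def severity_rank(state: str) -> int:
    """Severity rank of an RDR severity name (0 = least severe)."""
    return RDR_SEVERITY.index(state)


def state_vector() -> np.ndarray:
    """A zero occupancy vector over the full state space."""
    return np.zeros(N_STATES)
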