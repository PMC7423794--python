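"""Individual-level microsimulation oracle for the cohort Markov model.

Deliberately independent of the cohort-iteration code path: it consumes
only the per-cycle transition matrices and pushes sampled individuals
through them, so agreement with the deterministic trace validates the
matrix composition and the occupancy bookkeeping.
"""

import numpy as np

from drscreen import states as st
from drscreen.markov import build_transition_matrix


def microsimulate(model, strategy, stratum, n_simulants, seed, n_cycles):
    """Occupancy proportions (n_cycles + 1, N_STATES) from n simulants."""
    rng = np.random.default_rng(seed)
    counts = np.zeros(st.N_STATES, dtype=np.int64)
    counts[st.STATE_INDEX["NoDR"]] = n_simulants
    history = [counts / n_simulants]
    for k in range(n_cycles):
        P = build_transition_matrix(model, strategy, stratum, k)
        new = np.zeros(st.N_STATES, dtype=np.int64)
        for s in np.nonzero(counts)[0]:
            row = np.clip(P[s], 0.0, None)
            new += rng.multinomial(counts[s], row / row.sum())
        counts = new
        history.append(counts / n_simulants)
    return np.vstack(history)
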