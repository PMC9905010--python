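"""Brute-force enumeration oracle for the event-impact distribution.

For short horizons the exact distribution of the total-impact trajectory is
enumerable: each single-occurrence event either first fires in year t (with
probability p_t * prod_{s<t}(1 - p_s)) or never fires. Independent events
combine by convolution. Used to validate the Monte-Carlo engine; shares no
code with it.
"""

from itertools import product

import numpy as np


def event_outcomes(p, impact):
    """All (probability, trajectory) outcomes for one single-occurrence event.

    Onset-year impact persists to the horizon end.
    """
    p = np.asarray(p, dtype=float)
    impact = np.asarray(impact, dtype=float)
    T = len(p)
    outcomes = []
    none_prob = 1.0
    for t in range(T):
        prob = p[t] * np.prod(1.0 - p[:t])
        traj = np.zeros(T)
        traj[t:] = impact[t]
        if prob > 0:
            outcomes.append((prob, traj))
        none_prob *= 1.0 - p[t]
    if none_prob > 0:
        outcomes.append((none_prob, np.zeros(T)))
    return outcomes


def total_impact_distribution(events):
    """Exact distribution of the summed trajectory over independent events.

    ``events`` is a sequence of (p_array, impact_array) pairs. Returns a list
    of (probability, total_trajectory) pairs summing to 1.
    """
    combos = []
    per_event = [event_outcomes(p, i) for p, i in events]
    for combo in product(*per_event):
        prob = float(np.prod([c[0] for c in combo]))
        traj = np.sum([c[1] for c in combo], axis=0)
        combos.append((prob, traj))
    return combos


def exact_cdf(distribution, year_index, x):
    """P(total impact in the given year <= x) from an enumerated distribution."""
    return float(
        sum(prob for prob, traj in distribution if traj[year_index] <= x + 1e-12)
    )


def exact_mean(distribution):
    """Expected total-impact trajectory."""
    return np.sum([prob * traj for prob, traj in distribution], axis=0)
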