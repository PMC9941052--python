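"""Independent brute-force oracles used by the test suite.

These deliberately use naive explicit loops so they share no code path with
the library implementations they check.
"""

from __future__ import annotations

import numpy as np


def concordance_bruteforce(scores, times, events, weights=None) -> float:
    """Explicit pair-enumeration Harrell's C: for every ordered pair where i's
    death is observed strictly before j's time, count 1 if score_i > score_j,
    1/2 on a tie, weighted by w_i * w_j."""
    n = len(scores)
    w = [1.0] * n if weights is None else list(weights)
    num = 0.0
    den = 0.0
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if times[i] < times[j]:
                pw = w[i] * w[j]
                den += pw
                if scores[i] > scores[j]:
                    num += pw
                elif scores[i] == scores[j]:
                    num += 0.5 * pw
    return float("nan") if den == 0 else num / den


def km_survival_bruteforce(times, events, horizon) -> float:
    """Hand product-limit estimator: walk distinct event times in order,
    multiplying (1 - d_t / n_t) with n_t = number still at risk at t-."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    for t in sorted(set(times[events == 1])):
        if t > horizon:
            break
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
    return s
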