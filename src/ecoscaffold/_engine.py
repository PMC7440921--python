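"""Numba kernel for the exact direct-method SSA on one collective.

The kernel keeps incremental aggregates (per-colour competition pressure and
per-colour total birth rate) that are updated in O(1) per event; they are
recomputed from scratch every 2**20 events to eliminate floating-point
drift, so the maintained rates are contractually equal to a full
recomputation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_RESYNC = 1 << 20


@njit(cache=True)
def ssa_growth(counts, colour, r, a_intra, a_inter, T, seed):  # pragma: no cover
    """Advance ``counts`` (int64 array, modified in place) to time ``T``.

    ``colour`` holds 0 (red) / 1 (blue) per population. Returns the number
    of events executed. Exact stochastic simulation (direct method): one
    exponential waiting time and one categorical event choice per step.
    """
    np.random.seed(seed)
    n = counts.shape[0]

    # aggregates: s[c] = competition pressure felt by colour c,
    # bt[c] = total birth rate of colour c populations
    s0 = 0.0
    s1 = 0.0
    bt0 = 0.0
    bt1 = 0.0
    for j in range(n):
        nj = counts[j]
        if nj > 0:
            if colour[j] == 0:
                s0 += a_intra[j] * nj
                s1 += a_inter[j] * nj
                bt0 += r[j] * nj
            else:
                s1 += a_intra[j] * nj
                s0 += a_inter[j] * nj
                bt1 += r[j] * nj

    t = 0.0
    events = 0
    while True:
        total = bt0 * (1.0 + s0) + bt1 * (1.0 + s1)
        if total <= 0.0:
            break
        t += np.random.exponential(1.0 / total)
        if t >= T:
            break
        # categorical choice over the 2n (birth, death) rates
        u = np.random.random() * total
        chosen = -1
        is_death = False
        for i in range(n):
            ni = counts[i]
            if ni == 0:
                continue
            b = r[i] * ni
            if u < b:
                chosen = i
                is_death = False
                break
            u -= b
            d = b * (s0 if colour[i] == 0 else s1)
            if u < d:
                chosen = i
                is_death = True
                break
            u -= d
        if chosen < 0:
            # float round-off pushed u past the last rate: take the last
            # population with a positive rate (death branch is always the
            # final summand when pressure > 0, birth otherwise)
            for i in range(n - 1, -1, -1):
                if counts[i] > 0:
                    chosen = i
                    sc = s0 if colour[i] == 0 else s1
                    is_death = sc > 0.0
                    break
            if chosen < 0:
                break

        delta = -1 if is_death else 1
        counts[chosen] += delta
        cj = colour[chosen]
        if cj == 0:
            s0 += delta * a_intra[chosen]
            s1 += delta * a_inter[chosen]
            bt0 += delta * r[chosen]
        else:
            s1 += delta * a_intra[chosen]
            s0 += delta * a_inter[chosen]
            bt1 += delta * r[chosen]

        events += 1
        if events % _RESYNC == 0:
            s0 = 0.0
            s1 = 0.0
            bt0 = 0.0
            bt1 = 0.0
            for j in range(n):
                nj = counts[j]
                if nj > 0:
                    if colour[j] == 0:
                        s0 += a_intra[j] * nj
                        s1 += a_inter[j] * nj
                        bt0 += r[j] * nj
                    else:
                        s1 += a_intra[j] * nj
                        s0 += a_inter[j] * nj
                        bt1 += r[j] * nj
    return events
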