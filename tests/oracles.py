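"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: exposure is recomputed
minute by minute, ANOVA from explicit sum-of-squares formulas, and the
Fisher 2x2 p-value from the hypergeometric pmf.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def minute_level_exposure(diary, grid):
    """Exposure recomputed at 1-min resolution: every minute contributes its
    slot/microenvironment cell mean if the cell is available; the average is
    over contributing minutes."""
    total, minutes = 0.0, 0
    for minute in range(1440):
        t = minute // 10           # 0-based slot
        me = int(diary.slots[t])
        if grid.available[t, me]:
            total += grid.means[t, me]
            minutes += 1
    return total / minutes, minutes


def anova_f(groups):
    """One-way ANOVA F from explicit SSB/SSW sums of squares."""
    all_vals = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    grand = all_vals.mean()
    k = len(groups)
    n = len(all_vals)
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


def fisher_2x2_p(table):
    """Two-sided Fisher p for a 2x2 table by direct hypergeometric
    enumeration over the free cell (probability-ordering convention)."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def lognormal_mean(mu, sigma):
    return math.exp(mu + sigma * sigma / 2.0)
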