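"""Spearman rank correlation with an exact small-sample option.

rs is the Pearson correlation of average ranks (scipy's implementation);
the p-value comes from the usual t-approximation, except for n <= 10 where
the exact permutation distribution over all n! rank orders is enumerated.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np
from scipy import stats


def spearman(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rank correlation and two-sided p-value.

    Ranks use midranks for ties.  For n <= ``exact_max_n`` the p-value is the
    exact permutation tail probability P(|rs*| >= |rs|); above that, the
    t-approximation with n - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rs = float(stats.spearmanr(x, y).statistic)
    if n <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(rs)
        count = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= obs - 1e-12:
                count += 1
        p = count / factorial(n)
    else:
        if abs(rs) >= 1.0:
            p = 0.0
        else:
            t = rs * np.sqrt((n - 2) / (1.0 - rs**2))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rs, float(p)
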