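"""Independent oracles used by the test suite.

These deliberately re-derive expected values from first principles
(enumeration, step-by-step recursion with fresh quantile calls) rather
than calling back into the package's implementations.
"""

from __future__ import annotations

import math
import statistics

from scipy.stats import t as t_dist


def esd_oracle(values, r_max, alpha=0.05):
    """Step-by-step recomputation of the generalized ESD recursion.

    Returns (n_outliers, statistics, critical_values, removed_indices),
    computed with plain Python statistics and a fresh t-quantile per step.
    """
    data = list(enumerate(float(v) for v in values))
    n = len(data)
    r = min(r_max, n // 2, n - 2)
    stats_out, crits, removed = [], [], []
    for i in range(1, r + 1):
        xs = [v for _, v in data]
        mean = statistics.fmean(xs)
        sd = statistics.stdev(xs)
        if sd == 0.0:
            break
        best = max(range(len(xs)), key=lambda k: (abs(xs[k] - mean), -k))
        R = abs(xs[best] - mean) / sd
        p = 1.0 - alpha / (2.0 * (n - i + 1))
        df = n - i - 1
        tq = float(t_dist.ppf(p, df))
        lam = (n - i) * tq / math.sqrt((df + tq * tq) * (n - i + 1))
        stats_out.append(R)
        crits.append(lam)
        removed.append(data[best][0])
        del data[best]
    n_out = 0
    for i, (R, lam) in enumerate(zip(stats_out, crits)):
        if R > lam:
            n_out = i + 1
    return n_out, stats_out, crits, removed


def hypergeom_tail_enum(k, K, n, N):
    """P(X >= k) by exact enumeration of the hypergeometric pmf."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def bh_stepup(p_values):
    """Reference Benjamini-Hochberg step-up: q_(k) = min_{j>=k} min(1, p_(j) m/j)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, p_values[i] * m / rank))
        adjusted[i] = running
    return adjusted
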