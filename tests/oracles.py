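"""Independent brute-force reference implementations used only by tests.

Each function here is written from the textbook definition with explicit
loops, deliberately sharing no code path with the package, so agreement is
evidence rather than tautology.
"""

from __future__ import annotations

import math


def pearson_bruteforce(x, y) -> float:
    """Sample Pearson correlation straight from the covariance formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def corr_matrix_bruteforce(rows) -> list[list[float]]:
    p = len(rows)
    return [[1.0 if i == j else pearson_bruteforce(rows[i], rows[j])
             for j in range(p)] for i in range(p)]


def sum_r_bruteforce(R, exclude_idx=()) -> list[float]:
    """Per-feature sum of correlations over partners (j != i, j not excluded)."""
    p = len(R)
    out = []
    for i in range(p):
        s = 0.0
        for j in range(p):
            if j != i and j not in exclude_idx:
                s += R[i][j]
        out.append(s)
    return out


def paired_t_bruteforce(a, b):
    """Two-tailed paired t-test: t = mean(d) / (sd(d)/sqrt(n))."""
    from scipy.stats import t as tdist  # distribution function only

    n = len(a)
    d = [y - x for x, y in zip(a, b)]
    md = sum(d) / n
    sd = math.sqrt(sum((v - md) ** 2 for v in d) / (n - 1))
    t = md / (sd / math.sqrt(n))
    p = 2.0 * tdist.sf(abs(t), n - 1)
    return t, p


def bh_bruteforce(pvals) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values by the definition:
    q_(i) = min over j >= i of min(1, m * p_(j) / j)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, m * pvals[i] / rank))
        q[i] = running
    return q
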