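"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity from first principles (exact integer
arithmetic, exhaustive enumeration, naive agglomeration) and never calls
the code path it checks.
"""

from itertools import combinations
from math import comb, sqrt

import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with exact integers.

    p = sum of hypergeometric probabilities over all tables with the
    observed margins whose probability is <= that of the observed table.
    Probabilities are compared as exact integer products, so ties are
    resolved exactly.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    # P(x) proportional to comb(r1, x) * comb(r2, c1 - x)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    obs = weights[a]
    total = sum(weights.values())  # == comb(n, c1)
    assert total == comb(n, c1)
    tail = sum(w for w in weights.values() if w <= obs)
    return tail / total


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all label assignments.

    U counts pairs (xi, yj) with xi > yj plus half the ties; the null
    distribution comes from all C(n1+n2, n1) ways of assigning the pooled
    values to group x.
    """
    x = list(x)
    y = list(y)
    pooled = x + y
    n1 = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    obs = u_of(tuple(range(n1)))
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2.0
    dev = abs(obs - mean_u)
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(u_of(idx) - mean_u) >= dev - 1e-12:
            count += 1
    return obs, count / total


def _cluster_distance(xa, xb, method: str) -> float:
    """Inter-cluster distance recomputed from member coordinates."""
    if method == "average":
        return float(np.mean([np.linalg.norm(p - q) for p in xa for q in xb]))
    if method == "complete":
        return float(np.max([np.linalg.norm(p - q) for p in xa for q in xb]))
    if method == "ward":
        na, nb = len(xa), len(xb)
        ca = np.mean(xa, axis=0)
        cb = np.mean(xb, axis=0)
        return float(sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ca - cb))
    raise ValueError(method)


def agglomerate_two_groups(x: np.ndarray, method: str) -> list[set[int]]:
    """Naive agglomeration down to two clusters.

    At each step the pair of clusters at minimal distance (recomputed
    from scratch from member coordinates; ties broken by smallest member
    indices) is merged.  Returns the two final clusters as index sets.
    """
    clusters: list[list[int]] = [[i] for i in range(len(x))]
    while len(clusters) > 2:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = _cluster_distance(x[clusters[i]], x[clusters[j]], method)
                key = (d, min(clusters[i]), min(clusters[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        merged = sorted(clusters[i] + clusters[j])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return [set(c) for c in clusters]


def pooled_t(x, y) -> tuple[float, float]:
    """Textbook pooled-variance two-sample t and two-sided p."""
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (n1 + n2 - 2)
    se = sqrt(sp2 * (1 / n1 + 1 / n2))
    t = (x.mean() - y.mean()) / se
    return t, 2 * tdist.sf(abs(t), n1 + n2 - 2)


def schoenfeld_logrank_power(n1, n2, hazard1, hazard2, horizon, alpha=0.05):
    """Approximate two-sided log-rank power for exponential survival with
    administrative censoring (Schoenfeld's formula)."""
    from scipy.stats import norm

    n = n1 + n2
    p1 = n1 / n
    d = (n1 * (1 - np.exp(-hazard1 * horizon))
         + n2 * (1 - np.exp(-hazard2 * horizon)))
    theta = np.log(hazard1 / hazard2)
    za = norm.ppf(1 - alpha / 2)
    return float(norm.cdf(sqrt(d * p1 * (1 - p1)) * abs(theta) - za))
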