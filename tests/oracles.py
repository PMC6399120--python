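"""Independent brute-force oracles used to pin down the analytical routines.

Each oracle recomputes a quantity by enumeration, grid search or direct
counting, without sharing any code path with the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb, factorial

import numpy as np


def hwe_exact_enumeration(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p by full enumeration in exact rational arithmetic."""
    n = n_aa + n_ab + n_bb
    nb = 2 * n_bb + n_ab
    n_min = min(nb, 2 * n - nb)
    if n_min == 0:
        return 1.0
    weights = {}
    for het in range(n_min % 2, n_min + 1, 2):
        hom_min = (n_min - het) // 2
        hom_maj = n - het - hom_min
        if hom_maj < 0:
            continue
        weights[het] = (
            2**het * factorial(n)
            // (factorial(het) * factorial(hom_min) * factorial(hom_maj))
        )
    total = sum(weights.values())
    probs = {k: Fraction(v, total) for k, v in weights.items()}
    obs = probs[n_ab]
    return float(sum(v for v in probs.values() if v <= obs))


def fisher_2x2_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration (rationals)."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(x: int) -> Fraction:
        return Fraction(comb(col1, x) * comb(n - col1, row1 - x), comb(n, row1))

    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    obs = pmf(a)
    return float(sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= obs))


def auc_pair_counting(scores, labels) -> float:
    """AUC by exhaustive case/control pair comparison with the half-tie rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = 0.0
    for x in cases:
        for y in controls:
            wins += 1.0 if x > y else (0.5 if x == y else 0.0)
    return wins / (len(cases) * len(controls))


def logistic_grid_search(y, x, span=10.0, refinements=6):
    """Maximise the 2-parameter logistic likelihood by coarse-to-fine grid."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)

    def ll(b0, b1):
        eta = b0 + b1 * x
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))

    center, width, step = (0.0, 0.0), span, span / 50
    best = None
    for _ in range(refinements):
        b0s = np.arange(center[0] - width, center[0] + width + step / 2, step)
        b1s = np.arange(center[1] - width, center[1] + width + step / 2, step)
        vals = [(ll(b0, b1), b0, b1) for b0 in b0s for b1 in b1s]
        best = max(vals)
        # the next pass fully covers the winning cell at 10x resolution
        center, width, step = (best[1], best[2]), 2 * step, step / 10
    return best[1], best[2], best[0]


def em_haplotype_grid_search(table, coarse=0.02):
    """Maximise the two-locus multinomial likelihood over the 3-simplex."""

    def ll(h):
        p11, p10, p01, p00 = h
        g = np.array(
            [
                [p00**2, 2 * p00 * p01, p01**2],
                [2 * p00 * p10, 2 * p11 * p00 + 2 * p10 * p01, 2 * p01 * p11],
                [p10**2, 2 * p10 * p11, p11**2],
            ]
        )
        with np.errstate(divide="ignore"):
            return float(
                np.where(table > 0, table * np.log(np.clip(g, 1e-300, None)), 0.0).sum()
            )

    def scan(grid_pts):
        best = (-np.inf, None)
        for p11 in grid_pts:
            for p10 in grid_pts:
                if p11 + p10 > 1:
                    continue
                for p01 in grid_pts:
                    p00 = 1.0 - p11 - p10 - p01
                    if p01 + p11 + p10 > 1 or p00 < 0:
                        continue
                    h = (p11, p10, p01, p00)
                    v = ll(h)
                    if v > best[0]:
                        best = (v, h)
        return best

    _, h = scan(np.arange(0.0, 1.0 + coarse / 2, coarse))
    for step in (coarse / 5, coarse / 25):
        c = h
        grids = [
            np.clip(np.arange(ci - 5 * step, ci + 5 * step + step / 2, step), 0, 1)
            for ci in c[:3]
        ]
        best = (-np.inf, h)
        for p11 in grids[0]:
            for p10 in grids[1]:
                for p01 in grids[2]:
                    p00 = 1.0 - p11 - p10 - p01
                    if p00 < 0:
                        continue
                    v = ll((p11, p10, p01, p00))
                    if v > best[0]:
                        best = (v, (p11, p10, p01, p00))
        h = best[1]
    return np.array(h)


def optimal_threshold_scan(scores, labels):
    """Best Youden threshold by scanning every candidate cut point."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    m = (labels == 1).sum()
    n = (labels == 0).sum()
    best = (-np.inf, None, None, None)
    for t in np.unique(scores):
        sens = float((scores[labels == 1] >= t).sum() / m)
        spec = float((scores[labels == 0] < t).sum() / n)
        j = sens + spec - 1.0
        if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and spec > (best[3] or -1)):
            best = (j, t, sens, spec)
    return best[1], best[2], best[3]


def mann_whitney_enumeration(x, y, alternative="two-sided"):
    """Mann-Whitney p by enumerating all group assignments of the pooled data."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    nx = len(x)
    ranks = rankdata(pooled)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    us = []
    for idx in combinations(range(len(pooled)), nx):
        us.append(float(ranks[list(idx)].sum() - nx * (nx + 1) / 2))
    us = np.asarray(us)
    if alternative == "less":
        return float((us <= u_obs + 1e-12).mean())
    if alternative == "greater":
        return float((us >= u_obs - 1e-12).mean())
    return min(
        1.0,
        2 * min(float((us <= u_obs + 1e-12).mean()), float((us >= u_obs - 1e-12).mean())),
    )
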