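"""Independent brute-force oracles used to verify pipeline computations.

Each oracle is written from the definition of the quantity, not from the
implementation path it checks.
"""

from collections import Counter
from itertools import combinations

import numpy as np


def ibs_allele_sharing(d1: int, d2: int, ploidy: int = 3) -> float:
    """IBS at one locus as maximal shared alleles between unordered allele multisets.

    A dosage d corresponds to the multiset {alt x d, ref x (ploidy - d)}; the
    similarity is the size of the multiset intersection divided by ploidy.
    """
    m1 = Counter({"alt": d1, "ref": ploidy - d1})
    m2 = Counter({"alt": d2, "ref": ploidy - d2})
    shared = sum((m1 & m2).values())
    return shared / ploidy


def average_linkage_heights(dissim: np.ndarray) -> list[float]:
    """Exhaustive UPGMA agglomeration: merge heights in order.

    Average linkage between clusters A and B is the mean of all pairwise
    dissimilarities between their members, computed from the original matrix
    at every step.
    """
    n = dissim.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = float(
                np.mean([dissim[i, j] for i in clusters[a] for j in clusters[b]])
            )
            if best is None or d < best[0] - 1e-15:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights


def _ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, RSS by the closed-form normal equations."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    rss = float(((y - slope * x - intercept) ** 2).sum())
    return slope, intercept, rss


def broken_stick_exhaustive(
    o2: np.ndarray, rate: np.ndarray, min_segment: int = 3
) -> tuple[int, float, float]:
    """Evaluate every admissible breakpoint; return (index, total RSS, pcrit).

    P_crit is the intersection O2 of the two closed-form OLS lines, falling
    back to the breakpoint observation's O2 when the lines are parallel or the
    intersection leaves the observed O2 range.
    """
    order = np.argsort(-np.asarray(o2, dtype=float))
    o2 = np.asarray(o2, dtype=float)[order]
    rate = np.asarray(rate, dtype=float)[order]
    n = len(o2)
    best = None
    for b in range(min_segment, n - min_segment + 1):
        ml, cl, rss_l = _ols_normal_equations(o2[:b], rate[:b])
        mr, cr, rss_r = _ols_normal_equations(o2[b:], rate[b:])
        total = rss_l + rss_r
        if best is None or total < best[0] - 1e-15:
            best = (total, b, (ml, cl), (mr, cr))
    total, b, (ml, cl), (mr, cr) = best
    if abs(ml - mr) > 1e-12:
        x = (cr - cl) / (ml - mr)
        pcrit = x if o2.min() - 1e-9 <= x <= o2.max() + 1e-9 else o2[b]
    else:
        pcrit = o2[b]
    return b, total, float(pcrit)
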