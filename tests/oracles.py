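"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (loops, enumeration) and shares no
code with the package's computational paths.
"""
from __future__ import annotations

from itertools import combinations
from math import comb


def overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def brute_force_hits(variants, genes, mode, promoter_length=5000):
    """All-pairs interval check. Returns {lncRNA id: n distinct overlapping variants}."""
    support = {}
    for g in genes:
        if not g.is_lncRNA:
            continue
        regions = []
        if mode == "gene":
            regions = [(g.start, g.end)]
        elif mode == "exon":
            regions = list(g.exons)
        elif mode == "gene_plus_promoter":
            regions = [(g.start, g.end)]
            if g.strand == "+":
                regions.append((max(0, g.start - promoter_length), g.start))
            else:
                regions.append((g.end, g.end + promoter_length))
        n = 0
        for v in variants:
            if v.chrom != g.chrom:
                continue
            if any(overlaps(v.start, v.end, s, e) for s, e in regions):
                n += 1
        if n:
            support[g.gene_id] = n
    return support


def hypergeom_tail_enum(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    population = list(range(N))
    successes = set(range(K))
    hits = sum(1 for draw in combinations(population, n) if len(successes & set(draw)) >= k)
    return hits / comb(N, n)


def bh_stepup_hand(pvalues):
    """Hand BH step-up: sort, adjusted_(i) = min_{j>=i} m p_(j)/j, map back."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adjusted_sorted = [None] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        adjusted_sorted[rank - 1] = min(running, 1.0)
    out = [None] * m
    for rank, i in enumerate(indexed):
        out[i] = adjusted_sorted[rank]
    return out


def ranksum_exact_enum(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating group assignments (no ties)."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n1, n2 = len(a), len(b)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in a) - n1 * (n1 + 1) / 2
    us = []
    for idx in combinations(range(n1 + n2), n1):
        r = sum(i + 1 for i in idx)
        us.append(r - n1 * (n1 + 1) / 2)
    total = len(us)
    lo = sum(1 for u in us if u <= u_obs) / total
    hi = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2 * min(lo, hi))


def pearson_naive(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / (vx * vy) ** 0.5
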