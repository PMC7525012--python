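"""Over-representation analysis (ORA) of gene lists against GMT collections.

Plain upper-tail hypergeometric per term with Benjamini-Hochberg FDR
across the collection. The universe is explicit (by default all
protein-coding genes in the annotation) and genes outside it are
dropped before testing.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .expression_metrics import compare_groups

logger = logging.getLogger(__name__)

#: terms with fewer in-universe members than this are skipped
MIN_TERM_SIZE = 3


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be in [0, 1] and non-NaN")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(population N, successes K, draws n)."""
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def ora(
    gene_list,
    collection: dict[str, tuple[str, set[str]]],
    universe,
    min_term_size: int = MIN_TERM_SIZE,
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation, sorted by p.

    Columns: term, description, k (list hits), K (term size in
    universe), n (effective list size), N (universe size), fold, p, fdr.
    """
    universe = set(universe)
    raw = list(dict.fromkeys(gene_list))
    eff = [g for g in raw if g in universe]
    dropped = len(raw) - len(eff)
    if dropped:
        logger.info("ora: dropped %d genes outside the universe", dropped)
    if not eff:
        raise ValueError("gene list is empty after intersecting with the universe")
    N, n = len(universe), len(eff)
    eff_set = set(eff)
    rows = []
    skipped = []
    for term, (desc, members) in collection.items():
        K_set = members & universe
        K = len(K_set)
        if K < min_term_size:
            skipped.append(term)
            continue
        k = len(K_set & eff_set)
        p = hypergeom_upper_tail(k, N, K, n)
        fold = (k / n) / (K / N)
        rows.append(
            {"term": term, "description": desc, "k": k, "K": K, "n": n, "N": N, "fold": fold, "p": p}
        )
    if skipped:
        logger.info("ora: skipped %d terms with < %d in-universe members", len(skipped), min_term_size)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    return table.sort_values(["p", "term"]).reset_index(drop=True)


def region_comparison(
    neighbors_by_region: dict[str, set[str]],
    collection: dict[str, tuple[str, set[str]]],
    universe,
    top_k: int = 15,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """-log10(p) matrix of each region's top enriched terms.

    Rows = union over regions of the top_k terms with p < alpha; columns
    = regions; NA where a term was not tested or did not pass in that
    region.
    """
    if len(neighbors_by_region) < 2:
        raise ValueError("region_comparison needs >= 2 regions")
    per_region: dict[str, pd.Series] = {}
    selected: list[str] = []
    for region, genes in neighbors_by_region.items():
        table = ora(sorted(genes), collection, universe)
        passing = table[table["p"] < alpha]
        if passing.empty:
            warnings.warn(f"region {region!r}: no terms with p < {alpha}")
        top = passing.head(top_k)
        per_region[region] = pd.Series(
            -np.log10(top["p"].to_numpy()), index=top["term"].to_numpy()
        )
        for t in top["term"]:
            if t not in selected:
                selected.append(t)
    mat = pd.DataFrame(index=selected, columns=list(neighbors_by_region), dtype=float)
    for region, scores in per_region.items():
        mat.loc[scores.index, region] = scores
    return mat


def known_gene_proportion(
    hit_neighbors: dict[str, set[str]],
    background_neighbors: dict[str, set[str]],
    known_genes,
) -> tuple[pd.Series, pd.Series, float]:
    """Per-lncRNA fraction of neighbors that are known disease genes.

    Returns (hit proportions, background proportions, two-sided rank-sum
    p-value between the two groups). lncRNAs without neighbors get NA.
    """
    known = set(known_genes)
    if not known:
        raise ValueError("known gene list is empty")

    def props(nbrs: dict[str, set[str]]) -> pd.Series:
        return pd.Series(
            {
                lnc: (len(s & known) / len(s)) if s else np.nan
                for lnc, s in nbrs.items()
            },
            dtype=float,
        )

    hp, bp = props(hit_neighbors), props(background_neighbors)
    for name, v in (("hit", hp), ("background", bp)):
        if v.dropna().empty:
            raise ValueError(f"{name} group has no lncRNA with neighbors")
    p = compare_groups(hp, bp).p_value
    return hp, bp, p
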