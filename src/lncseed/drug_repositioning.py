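"""Rank drugs by over-representation of their pathway sets in the altered list.

Each drug contributes a 2x2 table over the background pathway universe
(in drug set x in altered list); significance is one-sided Fisher's
exact (greater), with BH FDR across drugs.
"""
from __future__ import annotations

import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

DEFAULT_FDR_MAX = 0.5


def altered_pathways(enrichment_tables, fdr_max: float = DEFAULT_FDR_MAX) -> list[str]:
    """Pathways with fdr <= fdr_max, deduplicated across input ORA tables.

    ``enrichment_tables`` is one ORA result frame or an iterable of them
    (one per neighbor category).
    """
    if isinstance(enrichment_tables, pd.DataFrame):
        enrichment_tables = [enrichment_tables]
    seen: dict[str, None] = {}
    for table in enrichment_tables:
        if "fdr" not in table.columns:
            raise ValueError("enrichment table lacks an fdr column")
        for term in table.loc[table["fdr"] <= fdr_max, "term"]:
            seen.setdefault(term, None)
    if not seen:
        raise ValueError(
            f"no pathway passed fdr <= {fdr_max}; consider raising the threshold"
        )
    return list(seen)


def drug_enrichment(
    altered,
    drug_sets: dict[str, set[str]],
    background,
) -> pd.DataFrame:
    """Per-drug one-sided Fisher enrichment of its pathway set in the altered list.

    Columns: drug, overlap, set_size, a, b, c, d, p, fdr — sorted by
    ascending p then drug id. Drug sets are intersected with the
    background first; a drug emptied by that intersection gets p = 1 and
    is flagged.
    """
    background = set(background)
    altered = set(altered)
    if not altered <= background:
        raise ValueError("altered pathways must be a subset of the background")
    if not drug_sets:
        raise ValueError("need >= 1 drug set")
    N = len(background)
    rows = []
    for drug, pathways in drug_sets.items():
        pset = set(pathways) & background
        dropped = len(set(pathways)) - len(pset)
        a = len(pset & altered)
        b = len(pset) - a
        c = len(altered) - a
        d = N - a - b - c
        if not pset:
            p = 1.0
        else:
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater").pvalue)
        rows.append(
            {
                "drug": drug,
                "overlap": a,
                "set_size": len(pset),
                "dropped_out_of_background": dropped,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p": p,
                "empty_after_intersection": not pset,
            }
        )
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    return table.sort_values(["p", "drug"]).reset_index(drop=True)
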