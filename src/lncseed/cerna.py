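"""Competing-endogenous-RNA neighbors via shared-miRNA over-representation.

A protein-coding gene is a ceRNA partner of a lncRNA when the two share
at least ``min_shared`` regulating miRNAs and the sharing is significant
by an upper-tail hypergeometric test (BH FDR across all tested pairs).
The miRNA universe is the set of distinct miRNAs in the interaction
table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr
from .models import Annotation

DEFAULT_MIN_SHARED = 2
DEFAULT_ALPHA = 0.01


@dataclass
class InteractionTable:
    """Deduplicated miRNA -> target edges."""

    edges: pd.DataFrame  # columns miRNA_id, gene_id

    def __post_init__(self) -> None:
        self.edges = self.edges[["miRNA_id", "gene_id"]].drop_duplicates().reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "InteractionTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @property
    def miRNA_universe(self) -> set[str]:
        return set(self.edges["miRNA_id"])

    def regulators_of(self, gene_id: str) -> set[str]:
        return set(self.edges.loc[self.edges["gene_id"] == gene_id, "miRNA_id"])

    def incidence(self, gene_ids: list[str]) -> pd.DataFrame:
        """miRNA x gene 0/1 incidence for the given genes."""
        mirnas = sorted(self.miRNA_universe)
        mat = pd.DataFrame(0, index=mirnas, columns=gene_ids, dtype=np.int8)
        sub = self.edges[self.edges["gene_id"].isin(gene_ids)]
        for mir, gene in zip(sub["miRNA_id"], sub["gene_id"]):
            mat.loc[mir, gene] = 1
        return mat


def shared_mirna_test(
    lnc_regulators: set[str], gene_regulators: set[str], universe_size: int
) -> tuple[int, float]:
    """Shared-regulator count and upper-tail hypergeometric p.

    Population = universe_size miRNAs, successes = |lnc_regulators|,
    draws = |gene_regulators|, observed = |intersection|. Empty set on
    either side gives (0, 1.0).
    """
    if universe_size < max(len(lnc_regulators), len(gene_regulators)):
        raise ValueError("universe smaller than a regulator set")
    if not lnc_regulators or not gene_regulators:
        return 0, 1.0
    shared = len(lnc_regulators & gene_regulators)
    p = float(
        stats.hypergeom.sf(shared - 1, universe_size, len(lnc_regulators), len(gene_regulators))
    )
    return shared, min(p, 1.0)


def score_all_pairs(
    interactions: InteractionTable,
    lncRNA_ids: list[str],
    coding_ids: list[str],
) -> pd.DataFrame:
    """Shared counts and hypergeometric p for every lncRNA x coding pair.

    Vectorized through the miRNA incidence matrix; pairs where either
    side has no regulators get p = 1.
    """
    M = len(interactions.miRNA_universe)
    inc = interactions.incidence(list(dict.fromkeys(list(lncRNA_ids) + list(coding_ids))))
    L = inc[list(lncRNA_ids)].to_numpy()
    G = inc[list(coding_ids)].to_numpy()
    shared = L.T @ G  # n_lnc x n_coding
    deg_l = L.sum(axis=0)
    deg_g = G.sum(axis=0)
    rows = []
    for i, lnc in enumerate(lncRNA_ids):
        if deg_l[i] == 0:
            p_row = np.ones(len(coding_ids))
        else:
            p_row = stats.hypergeom.sf(shared[i] - 1, M, int(deg_l[i]), deg_g)
            p_row = np.where(deg_g == 0, 1.0, p_row)
        for j, gene in enumerate(coding_ids):
            rows.append((lnc, gene, int(shared[i, j]), float(min(p_row[j], 1.0))))
    return pd.DataFrame(rows, columns=["lncRNA_id", "gene_id", "shared", "p"])


def cerna_neighbors(
    interactions: InteractionTable,
    lncRNA_ids,
    annotation: Annotation,
    min_shared: int = DEFAULT_MIN_SHARED,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Significant (lncRNA, protein-coding) ceRNA pairs.

    All pairs are scored; BH FDR is computed jointly across tested
    pairs; a pair is retained iff shared >= min_shared, p <= alpha and
    fdr <= alpha.
    """
    if interactions.edges.empty:
        raise ValueError("interaction table is empty")
    genes_in_table = set(interactions.edges["gene_id"])
    present = [g for g in lncRNA_ids if g in genes_in_table]
    absent = [g for g in lncRNA_ids if g not in genes_in_table]
    if absent:
        warnings.warn(f"lncRNAs absent from interaction table, skipped: {absent[:10]}")
    coding = [g.gene_id for g in annotation.protein_coding]
    if not present or not coding:
        return pd.DataFrame(columns=["lncRNA_id", "gene_id", "shared", "p", "fdr"])
    table = score_all_pairs(interactions, present, coding)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    keep = (table["shared"] >= min_shared) & (table["p"] <= alpha) & (table["fdr"] <= alpha)
    return table[keep].sort_values(["p", "lncRNA_id", "gene_id"]).reset_index(drop=True)


def permuted_null_pvalues(
    interactions: InteractionTable,
    lncRNA_id: str,
    coding_ids: list[str],
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pair p-values under random relabeling of the edge gene column.

    Used for null calibration: permuting targets breaks any real sharing
    structure, so the returned p-values should be (super-)uniform.
    """
    pvals = []
    for _ in range(n_permutations):
        perm = interactions.edges.copy()
        perm["gene_id"] = rng.permutation(perm["gene_id"].to_numpy())
        t = InteractionTable(perm)
        if lncRNA_id not in set(t.edges["gene_id"]):
            continue
        pvals.append(score_all_pairs(t, [lncRNA_id], coding_ids)["p"].to_numpy())
    return np.concatenate(pvals) if pvals else np.array([])
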