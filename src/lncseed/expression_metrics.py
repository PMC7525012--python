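"""Tissue-specificity and group-comparison statistics for hit vs background genes.

Per-tissue values are medians across that tissue's samples (mirroring
consortium-style per-tissue median TPM tables) before computing the
specificity index tau or the brain expression ratio.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import Annotation, ExpressionMatrix

#: pseudocount added to group means before fold change
FC_EPS = 0.1

#: largest per-group size for which the exact rank-sum distribution is used
EXACT_MAX_N = 25


def tau_index(tissue_values: np.ndarray | pd.Series) -> float:
    """Tissue-specificity index tau in [0, 1].

    tau = sum_i (1 - x_i / max(x)) / (N - 1). 0 for uniform expression,
    1 for single-tissue expression; NaN for an all-zero gene.
    """
    x = np.asarray(tissue_values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau_index needs a 1-d vector over >= 2 tissues")
    if np.any(x < 0):
        raise ValueError("expression must be non-negative")
    mx = x.max()
    if mx == 0:
        return float("nan")
    return float(np.sum(1.0 - x / mx) / (x.size - 1))


def brain_index(tissue_values: pd.Series, brain_tissues: set[str] | frozenset[str]) -> float:
    """Median expression over brain tissues divided by median over all tissues."""
    brain = [t for t in tissue_values.index if t in brain_tissues]
    if not brain:
        raise ValueError("brain_tissues must be a non-empty subset of the tissue index")
    overall = float(tissue_values.median())
    if overall == 0:
        return float("nan")
    return float(tissue_values[brain].median()) / overall


def gene_metrics(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene tau and brain index from per-tissue medians."""
    med = expr.tissue_medians()
    tau = med.apply(lambda row: tau_index(row.to_numpy()), axis=1)
    if expr.brain_tissues:
        bidx = med.apply(lambda row: brain_index(row, expr.brain_tissues), axis=1)
    else:
        bidx = pd.Series(np.nan, index=med.index)
    return pd.DataFrame({"tau": tau, "brain_index": bidx})


@dataclass(frozen=True)
class GroupComparison:
    median_a: float
    median_b: float
    p_value: float
    n_a: int
    n_b: int
    method: str


def compare_groups(values_a, values_b) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test between two value groups.

    NAs are dropped first. The exact null distribution is used when both
    groups have <= 25 values and no cross-group ties; otherwise the
    normal approximation with midranks, tie correction and continuity
    correction.
    """
    a = np.asarray(pd.Series(values_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(values_b).dropna(), dtype=float)
    for name, v in (("first", a), ("second", b)):
        if v.size < 2:
            raise ValueError(f"{name} group has < 2 values after NA removal")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if max(a.size, b.size) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        p_value=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
        method=method,
    )


def de_test(
    case: pd.DataFrame,
    control: pd.DataFrame,
    fc_min: float = 1.5,
    p_max: float = 0.05,
    eps: float = FC_EPS,
) -> pd.DataFrame:
    """Per-gene fold change (on group means, pseudocount ``eps``) and rank-sum p.

    A gene is called when FC > fc_min or FC < 1/fc_min (strict) and
    p < p_max. Rows are genes shared by both frames.
    """
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    genes = case.index.intersection(control.index)
    case = case.loc[genes]
    control = control.loc[genes]
    fc = (case.mean(axis=1) + eps) / (control.mean(axis=1) + eps)
    pvals = np.ones(len(genes))
    for i, g in enumerate(genes):
        pvals[i] = compare_groups(case.loc[g], control.loc[g]).p_value
    fc_pass = (fc > fc_min) | (fc < 1.0 / fc_min)
    out = pd.DataFrame({"fold_change": fc, "p_value": pvals}, index=genes)
    out["called"] = fc_pass & (out["p_value"] < p_max)
    return out


def call_de_lncRNAs(
    case: pd.DataFrame,
    control: pd.DataFrame,
    annotation: Annotation,
    fc_min: float = 1.5,
    p_max: float = 0.05,
) -> set[str]:
    """Differentially expressed genes, restricted to annotated lncRNAs."""
    table = de_test(case, control, fc_min=fc_min, p_max=p_max)
    lnc_ids = {g.gene_id for g in annotation.lncRNAs}
    return {g for g in table.index[table["called"]] if g in lnc_ids}
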