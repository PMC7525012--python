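"""Per-tissue unsigned weighted co-expression networks.

Adjacency is |Pearson r|^beta with beta chosen so the network
approximates scale-free topology. Neighbor extraction thresholds the
adjacency row of each lncRNA directly; module detection is deliberately
out of scope.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .models import Annotation, ExpressionMatrix

DEFAULT_POWERS = tuple(range(1, 21))
DEFAULT_TARGET_R2 = 0.85
DEFAULT_ADJ_MIN = 0.1
DEFAULT_STRINGENT_MIN = 0.3

#: hard cap on the fraction of samples outlier removal may drop
MAX_OUTLIER_FRACTION = 0.10


@dataclass
class CoexprNetwork:
    tissue: str
    gene_ids: list[str]
    beta: int
    adjacency: pd.DataFrame  # symmetric, diagonal 1, entries in [0, 1]
    fit_r2: float

    def __post_init__(self) -> None:
        a = self.adjacency.to_numpy()
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if ((a < 0) | (a > 1)).any():
            raise ValueError("adjacency entries must be in [0, 1]")


def mad_filter(values: pd.DataFrame, keep_fraction: float = 0.75) -> pd.DataFrame:
    """Keep the ceil(keep_fraction * G) genes with largest MAD across samples."""
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    med = values.median(axis=1)
    mad = (values.sub(med, axis=0)).abs().median(axis=1)
    n_keep = int(np.ceil(keep_fraction * len(values)))
    if n_keep < 3:
        raise ValueError(f"MAD filter would leave {n_keep} genes (< 3)")
    keep = mad.sort_values(ascending=False, kind="stable").index[:n_keep]
    keep = [g for g in values.index if g in set(keep)]  # preserve input order
    return values.loc[keep]


def remove_outlier_samples(
    values: pd.DataFrame,
    cut_height_quantile: float = 0.99,
    outlier_margin: float = 1.3,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples isolated by average-linkage clustering on Euclidean distance.

    The dendrogram is cut at ``outlier_margin`` times the given quantile
    of its merge heights; samples outside the largest resulting cluster
    are removal candidates, but only clusters of size 1 are treated as
    outliers and at most 10% of samples are ever removed. The margin
    keeps i.i.d. data intact (the top merge sits just above the 0.99
    height quantile even without outliers) while an obvious outlier
    joins the tree far higher.
    """
    n = values.shape[1]
    if n < 4:
        raise ValueError("need >= 4 samples for outlier detection")
    X = values.to_numpy().T
    dists = pdist(X)
    Z = linkage(dists, method="average")
    heights = Z[:, 2]
    if heights.max() == 0:  # all samples identical
        return values, []
    # reference height distribution excludes the top merges that potential
    # outliers themselves create, so the cut is stable in n
    n_exclude = max(1, int(np.floor(MAX_OUTLIER_FRACTION * n)))
    reference = np.sort(heights)[:-n_exclude]
    if reference.size == 0 or reference.max() == 0:
        return values, []
    cut = float(np.quantile(reference, cut_height_quantile)) * outlier_margin
    labels = fcluster(Z, t=cut, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    main = sizes.idxmax()
    candidates = [
        s for s, lab in zip(values.columns, labels) if lab != main and sizes[lab] == 1
    ]
    max_remove = int(np.floor(MAX_OUTLIER_FRACTION * n))
    if len(candidates) > max_remove:
        # keep the most extreme ones only, by mean distance to all samples
        sq = np.zeros((n, n))
        sq[np.triu_indices(n, 1)] = dists
        sq += sq.T
        mean_d = pd.Series(sq.mean(axis=0), index=values.columns)
        candidates = list(mean_d[candidates].sort_values(ascending=False).index[:max_remove])
    kept = [s for s in values.columns if s not in set(candidates)]
    return values[kept], candidates


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) vs log10 mean(k) over connectivity bins.

    Signed negative when the slope is positive (topology is the opposite
    of scale-free).
    """
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        kb = k[idx == b]
        if kb.size == 0:
            continue
        xs.append(np.log10(kb.mean()))
        ys.append(np.log10(kb.size / k.size))
    if len(xs) < 3:
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = np.sum((np.asarray(ys) - pred) ** 2)
    ss_tot = np.sum((np.asarray(ys) - np.mean(ys)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-r2 if slope > 0 else r2)


def _correlation(values: pd.DataFrame) -> np.ndarray:
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(values.index, sd) if s == 0]
        raise ValueError(f"constant gene(s) make correlation undefined: {bad[:5]}")
    r = np.corrcoef(arr)
    return np.clip(r, -1.0, 1.0)


def pick_soft_threshold(
    values: pd.DataFrame,
    candidate_powers: tuple[int, ...] = DEFAULT_POWERS,
    target_r2: float = DEFAULT_TARGET_R2,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power approximating scale-free topology.

    Returns the smallest candidate with fit R^2 >= target_r2, or the
    maximizer (with a warning) when none reaches the target.
    """
    if values.shape[1] < 8:
        raise ValueError("need >= 8 samples to pick a soft threshold")
    absr = np.abs(_correlation(values))
    rows = []
    for beta in candidate_powers:
        a = absr**beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rows.append(
            {"power": beta, "fit_r2": _scale_free_fit(k), "mean_k": float(k.mean())}
        )
    table = pd.DataFrame(rows)
    ok = table[table["fit_r2"] >= target_r2]
    if len(ok):
        beta = int(ok.iloc[0]["power"])
    else:
        beta = int(table.loc[table["fit_r2"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reached fit R^2 {target_r2}; using beta={beta} "
            f"(best R^2 {table['fit_r2'].max():.3f})"
        )
    return beta, table


def build_adjacency(values: pd.DataFrame, beta: int, tissue: str = "") -> CoexprNetwork:
    """Unsigned adjacency a_ij = |pearson(x_i, x_j)|^beta, diagonal 1."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    absr = np.abs(_correlation(values))
    a = absr ** float(beta)
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0  # exact symmetry despite float noise
    adj = pd.DataFrame(a, index=values.index, columns=values.index)
    k = a.copy()
    np.fill_diagonal(k, 0.0)
    return CoexprNetwork(
        tissue=tissue,
        gene_ids=list(values.index),
        beta=int(beta),
        adjacency=adj,
        fit_r2=_scale_free_fit(k.sum(axis=1)),
    )


def coexpr_neighbors(
    net: CoexprNetwork,
    lncRNA_ids,
    annotation: Annotation,
    adjacency_min: float = DEFAULT_ADJ_MIN,
) -> dict[str, set[str]]:
    """Protein-coding genes with adjacency >= adjacency_min to each lncRNA.

    lncRNAs absent from the network are skipped with a warning.
    """
    coding = {g.gene_id for g in annotation.protein_coding}
    out: dict[str, set[str]] = {}
    in_net = set(net.gene_ids)
    missing = [g for g in lncRNA_ids if g not in in_net]
    if missing:
        warnings.warn(f"lncRNAs absent from network, skipped: {missing[:10]}")
    for gid in lncRNA_ids:
        if gid not in in_net:
            continue
        row = net.adjacency.loc[gid]
        out[gid] = {
            j for j in net.gene_ids if j != gid and j in coding and row[j] >= adjacency_min
        }
    return out


def tissue_network(
    expr: ExpressionMatrix,
    tissue: str,
    keep_fraction: float = 0.75,
    cut_height_quantile: float = 0.99,
    candidate_powers: tuple[int, ...] = DEFAULT_POWERS,
    target_r2: float = DEFAULT_TARGET_R2,
) -> tuple[CoexprNetwork, dict]:
    """Full per-tissue flow: MAD filter, outlier removal, power pick, adjacency."""
    values = expr.subset_tissue(tissue)
    values = mad_filter(values, keep_fraction)
    values, removed = remove_outlier_samples(values, cut_height_quantile)
    beta, fit_table = pick_soft_threshold(values, candidate_powers, target_r2)
    net = build_adjacency(values, beta, tissue=tissue)
    summary = {
        "tissue": tissue,
        "beta": beta,
        "fit_r2": float(fit_table.set_index("power").loc[beta, "fit_r2"]),
        "n_genes": values.shape[0],
        "n_samples": values.shape[1],
        "removed_samples": removed,
    }
    return net, summary
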