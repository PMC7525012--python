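"""Combine neighbor categories into high-reliability sets and the final report."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as lio
from .cerna import InteractionTable, cerna_neighbors
from .coexpression import (
    DEFAULT_ADJ_MIN,
    DEFAULT_STRINGENT_MIN,
    coexpr_neighbors,
    tissue_network,
)
from .drug_repositioning import altered_pathways, drug_enrichment
from .enrichment import known_gene_proportion, ora, region_comparison
from .expression_metrics import gene_metrics
from .models import Annotation
from .variant_mapping import (
    DEFAULT_FLANK,
    HitList,
    genomic_neighbors,
    identify_lncRNAs,
    subclass_distribution,
)

CATEGORIES = ("genomic", "cerna", "coexpr")


@dataclass
class NeighborSets:
    """Per-lncRNA neighbor gene sets, one dict per category."""

    genomic: dict[str, set[str]] = field(default_factory=dict)
    cerna: dict[str, set[str]] = field(default_factory=dict)
    coexpr: dict[str, set[str]] = field(default_factory=dict)

    def lncRNA_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in (self.genomic, self.cerna, self.coexpr):
            for k in d:
                seen.setdefault(k, None)
        return list(seen)

    def for_lncRNA(self, gid: str) -> dict[str, set[str]]:
        return {
            "genomic": self.genomic.get(gid, set()),
            "cerna": self.cerna.get(gid, set()),
            "coexpr": self.coexpr.get(gid, set()),
        }


def high_reliability(
    neighbors: NeighborSets, mode: str = "pooled"
) -> tuple[set[str], pd.DataFrame]:
    """Genes supported by >= 2 of the three neighbor categories.

    ``pooled`` (default) unions each category across lncRNAs before the
    >=2-of-3 rule; ``per_lncrna`` applies the rule within each lncRNA
    and unions the results. Also returns the per-gene category
    membership table used for Venn-style export.
    """
    if mode not in ("pooled", "per_lncrna"):
        raise ValueError("mode must be 'pooled' or 'per_lncrna'")
    if mode == "pooled":
        cat_sets = {
            "genomic": set().union(*neighbors.genomic.values()) if neighbors.genomic else set(),
            "cerna": set().union(*neighbors.cerna.values()) if neighbors.cerna else set(),
            "coexpr": set().union(*neighbors.coexpr.values()) if neighbors.coexpr else set(),
        }
    else:
        cat_sets = {c: set() for c in CATEGORIES}
        hr: set[str] = set()
        for gid in neighbors.lncRNA_ids():
            per = neighbors.for_lncRNA(gid)
            for c in CATEGORIES:
                cat_sets[c] |= per[c]
            genes = set().union(*per.values())
            hr |= {g for g in genes if sum(g in per[c] for c in CATEGORIES) >= 2}
        membership = _membership_frame(cat_sets)
        return hr, membership
    membership = _membership_frame(cat_sets)
    hr = set(membership.index[membership["n_categories"] >= 2])
    return hr, membership


def _membership_frame(cat_sets: dict[str, set[str]]) -> pd.DataFrame:
    genes = sorted(set().union(*cat_sets.values())) if any(cat_sets.values()) else []
    df = pd.DataFrame(
        {c: [g in cat_sets[c] for g in genes] for c in CATEGORIES}, index=genes
    )
    df["n_categories"] = df[list(CATEGORIES)].sum(axis=1) if genes else pd.Series(dtype=int)
    return df


@dataclass
class PipelineResult:
    hits: HitList
    subclass_table: pd.DataFrame
    metrics: pd.DataFrame
    neighbors: NeighborSets
    stringent_coexpr: dict[str, set[str]]
    high_reliability_genes: set[str]
    membership: pd.DataFrame
    enrichment_tables: dict[str, pd.DataFrame]
    altered: list[str]
    drug_table: pd.DataFrame
    report: pd.DataFrame
    manifest: dict


def assemble_report(
    hits: HitList,
    annotation: Annotation,
    metrics: pd.DataFrame,
    neighbors: NeighborSets,
    hr_genes: set[str],
    manifest: dict,
) -> pd.DataFrame:
    """One row per hit lncRNA with subclass, support, metrics and neighbor counts."""
    for name, obj in (("hits", hits), ("metrics", metrics), ("neighbors", neighbors)):
        if obj is None:
            raise ValueError(f"missing stage output: {name}")
    rows = []
    for gid in hits.lncRNA_ids:
        per = neighbors.for_lncRNA(gid)
        all_nbrs = set().union(*per.values())
        rows.append(
            {
                "lncRNA_id": gid,
                "subclass": annotation[gid].gene_type,
                "n_variants": hits.per_id_support[gid],
                "tau": metrics.loc[gid, "tau"] if gid in metrics.index else float("nan"),
                "brain_index": metrics.loc[gid, "brain_index"] if gid in metrics.index else float("nan"),
                "n_genomic": len(per["genomic"]),
                "n_cerna": len(per["cerna"]),
                "n_coexpr": len(per["coexpr"]),
                "n_high_reliability": len(all_nbrs & hr_genes),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    annotation_path: str | Path,
    variants_path: str | Path,
    expression_path: str | Path,
    samples_path: str | Path,
    interactions_path: str | Path,
    pathways_path: str | Path,
    drugs_path: str | Path,
    mode: str = "gene",
    flank: int = DEFAULT_FLANK,
    coexpr_tissue: str = "cortex",
    adjacency_min: float = DEFAULT_ADJ_MIN,
    stringent_min: float = DEFAULT_STRINGENT_MIN,
    cerna_min_shared: int = 2,
    cerna_alpha: float = 0.01,
    altered_fdr_max: float = 0.5,
    hr_mode: str = "pooled",
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full variant-to-drug pipeline from input files."""
    annotation = lio.read_gtf(annotation_path)
    variants = lio.read_variants_bed(variants_path)
    expr = lio.read_expression(expression_path, samples_path)
    interactions = InteractionTable.from_tsv(interactions_path)
    pathways = lio.read_gmt(pathways_path)
    drug_gmt = lio.read_gmt(drugs_path)

    hits = identify_lncRNAs(variants, annotation, mode=mode)
    subclass_table = subclass_distribution(hits, annotation)
    metrics = gene_metrics(expr)

    nbrs = NeighborSets()
    nbrs.genomic = genomic_neighbors(hits, annotation, flank=flank)
    cerna_table = cerna_neighbors(
        interactions, hits.lncRNA_ids, annotation, min_shared=cerna_min_shared, alpha=cerna_alpha
    )
    nbrs.cerna = {gid: set() for gid in hits.lncRNA_ids}
    for lnc, gene in zip(cerna_table["lncRNA_id"], cerna_table["gene_id"]):
        nbrs.cerna.setdefault(lnc, set()).add(gene)

    net, net_summary = tissue_network(expr, coexpr_tissue)
    nbrs.coexpr = coexpr_neighbors(net, hits.lncRNA_ids, annotation, adjacency_min=adjacency_min)
    stringent = coexpr_neighbors(net, hits.lncRNA_ids, annotation, adjacency_min=stringent_min)

    hr_input = NeighborSets(genomic=nbrs.genomic, cerna=nbrs.cerna, coexpr=stringent)
    hr_genes, membership = high_reliability(hr_input, mode=hr_mode)

    universe = [g.gene_id for g in annotation.protein_coding]
    enrichment_tables: dict[str, pd.DataFrame] = {}
    for cat in CATEGORIES:
        genes = set().union(*getattr(nbrs, cat).values()) if getattr(nbrs, cat) else set()
        if genes:
            enrichment_tables[cat] = ora(sorted(genes), pathways, universe)
    altered = altered_pathways(list(enrichment_tables.values()), fdr_max=altered_fdr_max)
    drug_table = drug_enrichment(
        altered, {d: s for d, (_, s) in drug_gmt.items()}, background=list(pathways)
    )

    manifest = {
        "lncseed_version": __version__,
        "mode": mode,
        "flank": flank,
        "coexpr_tissue": coexpr_tissue,
        "adjacency_min": adjacency_min,
        "stringent_min": stringent_min,
        "cerna_min_shared": cerna_min_shared,
        "cerna_alpha": cerna_alpha,
        "altered_fdr_max": altered_fdr_max,
        "hr_mode": hr_mode,
        "network": net_summary,
        "n_hits": len(hits),
        "inputs": {
            "annotation": str(annotation_path),
            "variants": str(variants_path),
            "expression": str(expression_path),
        },
    }
    report = assemble_report(hits, annotation, metrics, nbrs, hr_genes, manifest)

    result = PipelineResult(
        hits=hits,
        subclass_table=subclass_table,
        metrics=metrics,
        neighbors=nbrs,
        stringent_coexpr=stringent,
        high_reliability_genes=hr_genes,
        membership=membership,
        enrichment_tables=enrichment_tables,
        altered=altered,
        drug_table=drug_table,
        report=report,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.hits.to_frame().to_csv(outdir / "hits.tsv", sep="\t", index=False)
    result.report.to_csv(outdir / "report.tsv", sep="\t", index=False, float_format="%.6g")
    result.membership.to_csv(outdir / "venn_membership.tsv", sep="\t", index_label="gene_id")
    result.drug_table.to_csv(outdir / "drug_ranking.tsv", sep="\t", index=False, float_format="%.6g")
    for cat, table in result.enrichment_tables.items():
        table.to_csv(outdir / f"enrichment_{cat}.tsv", sep="\t", index=False, float_format="%.6g")
    (outdir / "altered_pathways.txt").write_text("\n".join(result.altered) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, default=str) + "\n")
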