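"""Identify disease-related lncRNAs by variant/annotation interval intersection.

Three target-region modes are supported: the gene body, the exon union,
and the gene body plus a strand-aware promoter (5 kb upstream of the TSS
by default). Overlap means >= 1 shared base on 0-based half-open
intervals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pyranges as pr

from .models import Annotation, GeneModel, VariantRecord, DEFAULT_PROMOTER_LENGTH

MODES = ("gene", "exon", "gene_plus_promoter")

DEFAULT_FLANK = 50_000


@dataclass
class HitList:
    """lncRNAs overlapped by >=1 variant under one intersection mode."""

    mode: str
    lncRNA_ids: list[str]
    per_id_support: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        for gid in self.lncRNA_ids:
            if self.per_id_support.get(gid, 0) < 1:
                raise ValueError(f"hit {gid} must have support >= 1")

    def __len__(self) -> int:
        return len(self.lncRNA_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.per_id_support

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.lncRNA_ids,
                "mode": self.mode,
                "n_variants": [self.per_id_support[g] for g in self.lncRNA_ids],
            }
        )


def _target_regions(
    lncRNAs: Sequence[GeneModel], mode: str, promoter_length: int
) -> pd.DataFrame:
    rows = []
    for g in lncRNAs:
        if mode == "gene":
            rows.append((g.chrom, g.start, g.end, g.gene_id))
        elif mode == "exon":
            for s, e in g.exons:
                rows.append((g.chrom, s, e, g.gene_id))
        else:  # gene_plus_promoter
            rows.append((g.chrom, g.start, g.end, g.gene_id))
            ps, pe = g.promoter(promoter_length)
            if ps < pe:
                rows.append((g.chrom, ps, pe, g.gene_id))
    return pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "gene_id"])


def _variants_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Chromosome": [v.chrom for v in variants],
            "Start": [v.start for v in variants],
            "End": [v.end for v in variants],
            "variant_idx": range(len(variants)),
        }
    )


def _check_chromosomes(variants: Sequence[VariantRecord], annotation: Annotation) -> None:
    vchroms = {v.chrom for v in variants}
    achroms = annotation.chroms
    unmatched = sorted(vchroms - achroms) + sorted(achroms - vchroms)
    if vchroms and achroms and (vchroms - achroms or achroms - vchroms):
        warnings.warn(
            f"chromosome names not shared between variants and annotation: {unmatched}",
            stacklevel=3,
        )


def identify_lncRNAs(
    variants: Sequence[VariantRecord],
    annotation: Annotation,
    mode: str = "gene",
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
) -> HitList:
    """Return lncRNAs whose mode-specific target region overlaps >=1 variant.

    Support counts are distinct variants per lncRNA (a variant spanning
    both the promoter and the gene body counts once).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    lncs = annotation.lncRNAs
    if not variants or not lncs:
        return HitList(mode=mode, lncRNA_ids=[], per_id_support={})
    _check_chromosomes(variants, annotation)

    targets = pr.PyRanges(_target_regions(lncs, mode, promoter_length))
    vdf = pr.PyRanges(_variants_frame(variants))
    joined = targets.join(vdf).df
    if joined.empty:
        return HitList(mode=mode, lncRNA_ids=[], per_id_support={})
    support = (
        joined.drop_duplicates(["gene_id", "variant_idx"]).groupby("gene_id").size().to_dict()
    )
    order = [g.gene_id for g in lncs if g.gene_id in support]
    return HitList(mode=mode, lncRNA_ids=order, per_id_support={g: int(support[g]) for g in order})


def containment_report(hits_by_mode: Mapping[str, HitList]) -> pd.DataFrame:
    """Pairwise containment |A n B| / |B| (as %) for every ordered mode pair.

    NA where the reference list B is empty.
    """
    if len(hits_by_mode) < 2:
        raise ValueError("containment_report needs >= 2 modes")
    rows = []
    for ma, ha in hits_by_mode.items():
        sa = set(ha.lncRNA_ids)
        for mb, hb in hits_by_mode.items():
            if ma == mb:
                continue
            sb = set(hb.lncRNA_ids)
            pct = float("nan") if not sb else 100.0 * len(sa & sb) / len(sb)
            rows.append({"mode_a": ma, "mode_b": mb, "containment_pct": pct})
    return pd.DataFrame(rows)


def _gene_overlaps_any(gene: GeneModel, records: Iterable[VariantRecord]) -> bool:
    return any(
        r.chrom == gene.chrom and r.start < gene.end and gene.start < r.end for r in records
    )


def cnv_validation(
    hits: HitList,
    cnv_set: Sequence[VariantRecord],
    annotation: Annotation,
    variants: Sequence[VariantRecord] | None = None,
    exclude: Sequence[VariantRecord] | None = None,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
) -> float:
    """Fraction of hit lncRNAs whose gene body overlaps >= 1 CNV record.

    When ``exclude`` is given, hits are first re-derived from
    ``variants`` minus the excluded records (same mode), so validation is
    not driven by records shared between the two sets.
    """
    if not cnv_set:
        raise ValueError("cnv_set must be non-empty")
    if exclude is not None:
        if variants is None:
            raise ValueError("exclude requires the original variants")
        excluded = {(v.chrom, v.start, v.end, v.variant_class) for v in exclude}
        kept = [v for v in variants if (v.chrom, v.start, v.end, v.variant_class) not in excluded]
        hits = identify_lncRNAs(kept, annotation, hits.mode, promoter_length)
    if not hits.lncRNA_ids:
        return float("nan")
    n_ok = sum(
        _gene_overlaps_any(annotation[gid], cnv_set) for gid in hits.lncRNA_ids
    )
    return n_ok / len(hits.lncRNA_ids)


def genomic_neighbors(
    hits: HitList | Sequence[str],
    annotation: Annotation,
    flank: int = DEFAULT_FLANK,
) -> dict[str, set[str]]:
    """Protein-coding genes overlapping the +/- ``flank`` window of each lncRNA."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    ids = hits.lncRNA_ids if isinstance(hits, HitList) else list(hits)
    coding = annotation.protein_coding
    out: dict[str, set[str]] = {}
    for gid in ids:
        lnc = annotation[gid]
        lo, hi = max(0, lnc.start - flank), lnc.end + flank
        out[gid] = {
            c.gene_id
            for c in coding
            if c.chrom == lnc.chrom and c.start < hi and lo < c.end
        }
    return out


def subclass_distribution(hits: HitList, annotation: Annotation) -> pd.DataFrame:
    """Count and proportion of hit lncRNAs per subclass (proportions sum to 1)."""
    counts: dict[str, int] = {}
    for gid in hits.lncRNA_ids:
        counts[annotation[gid].gene_type] = counts.get(annotation[gid].gene_type, 0) + 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "subclass": list(counts),
            "count": list(counts.values()),
            "proportion": [c / total for c in counts.values()],
        }
    )
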