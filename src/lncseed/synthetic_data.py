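"""Synthetic input generator with planted ground truth.

Every input the pipeline consumes can be generated here: a GTF
annotation with the five lncRNA subclasses plus protein-coding genes,
BED variants with planted lncRNA hits, a tissue-labeled expression
matrix with planted co-expression modules, a miRNA-target table with
planted ceRNA pairs, GMT pathway/drug collections with planted enriched
pathways and effective drugs, and a known disease-gene list.

Each generator draws from its own RNG stream keyed by (seed, generator
name), so adding a generator never shifts another's output and the same
config always produces byte-identical files.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .models import (
    Annotation,
    ExpressionMatrix,
    GeneModel,
    LNCRNA_SUBCLASSES,
    VariantRecord,
)

BRAIN_TISSUES = (
    "cortex",
    "cerebellum",
    "frontal_cortex_ba9",
    "anterior_cingulate_ba24",
    "hippocampus",
    "hypothalamus",
    "amygdala",
)
NON_BRAIN_TISSUES = ("liver", "lung", "heart", "kidney", "muscle", "spleen", "skin")

#: shared miRNAs injected per planted ceRNA pair (>= 3 by contract; set high
#: enough that planted pairs survive joint BH FDR at alpha = 0.01)
PLANTED_SHARED_MIRNAS = 12


class SizingError(ValueError):
    """Requested synthetic structure does not fit the configured sizes."""


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_lncRNA: int = 60
    n_protein_coding: int = 140
    n_variants: int = 250
    planted_hit_fraction: float = 0.5
    n_tissues: int = 6
    samples_per_tissue: int = 20
    n_modules: int = 5
    module_size: int = 10
    within_module_cor: float = 0.93
    n_mirnas: int = 150
    targets_per_mirna: int = 8
    n_planted_cerna_pairs: int = 15
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 25)
    n_drugs: int = 10
    pathways_per_drug: int = 6
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "n_lncRNA": self.n_lncRNA,
            "n_protein_coding": self.n_protein_coding,
            "n_variants": self.n_variants,
            "n_tissues": self.n_tissues,
            "samples_per_tissue": self.samples_per_tissue,
            "n_modules": self.n_modules,
            "module_size": self.module_size,
            "n_mirnas": self.n_mirnas,
            "targets_per_mirna": self.targets_per_mirna,
            "n_pathways": self.n_pathways,
            "n_drugs": self.n_drugs,
            "pathways_per_drug": self.pathways_per_drug,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0 <= self.planted_hit_fraction <= 1:
            raise ValueError("planted_hit_fraction must be in [0, 1]")
        if not 0 < self.within_module_cor < 1:
            raise ValueError("within_module_cor must be in (0, 1)")
        if self.n_planted_cerna_pairs < 0:
            raise ValueError("n_planted_cerna_pairs must be >= 0")
        lo, hi = self.pathway_size_range
        if not (2 <= lo <= hi):
            raise ValueError(f"pathway_size_range must satisfy 2 <= min <= max, got {self.pathway_size_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    planted_lncRNA_hits: set[str] = field(default_factory=set)
    planted_modules: dict[str, set[str]] = field(default_factory=dict)
    planted_cerna_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_enriched_pathways: set[str] = field(default_factory=set)
    planted_effective_drugs: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_lncRNA_hits": sorted(self.planted_lncRNA_hits),
            "planted_modules": {m: sorted(g) for m, g in sorted(self.planted_modules.items())},
            "planted_cerna_pairs": sorted(map(list, self.planted_cerna_pairs)),
            "planted_enriched_pathways": sorted(self.planted_enriched_pathways),
            "planted_effective_drugs": sorted(self.planted_effective_drugs),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_lncRNA_hits=set(d["planted_lncRNA_hits"]),
            planted_modules={m: set(g) for m, g in d["planted_modules"].items()},
            planted_cerna_pairs={tuple(p) for p in d["planted_cerna_pairs"]},
            planted_enriched_pathways=set(d["planted_enriched_pathways"]),
            planted_effective_drugs=set(d["planted_effective_drugs"]),
        )


def _rng(cfg: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), zlib.crc32(stream.encode())])
    )


# ---------------------------------------------------------------------------
# annotation


def _make_exons(
    rng: np.random.Generator, start: int, end: int, n_exons: int
) -> tuple[tuple[int, int], ...]:
    """n_exons disjoint exons strictly inside (start, end)."""
    margin = max(1, (end - start) // 50)
    lo, hi = start + margin, end - margin
    if hi - lo < 2 * n_exons + 2:
        mid_lo = start + (end - start) // 4
        mid_hi = end - (end - start) // 4
        return ((mid_lo, max(mid_hi, mid_lo + 1)),)
    cuts = np.sort(rng.choice(np.arange(lo, hi), size=2 * n_exons, replace=False))
    return tuple((int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_exons) if cuts[2 * i] < cuts[2 * i + 1])


def generate_annotation(cfg: SyntheticConfig) -> Annotation:
    """Place protein-coding genes and the five lncRNA subclasses on synthetic chromosomes.

    Intergenic genes (coding, lincRNA, non_coding) are laid out without
    overlap; antisense lncRNAs overlap a coding host on the opposite
    strand, bidirectional-promoter lncRNAs sit head-to-head upstream of
    a coding TSS, and sense-intronic lncRNAs lie inside a coding intron
    on the same strand.
    """
    rng = _rng(cfg, "annotation")
    subclasses = [LNCRNA_SUBCLASSES[i % len(LNCRNA_SUBCLASSES)] for i in range(cfg.n_lncRNA)]
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(cfg.n_lncRNA)]
    pcg_ids = [f"PCG{i + 1:04d}" for i in range(cfg.n_protein_coding)]

    intergenic: list[tuple[str, str]] = [(gid, "protein_coding") for gid in pcg_ids]
    attached: list[tuple[str, str]] = []
    for gid, sub in zip(lnc_ids, subclasses):
        if sub in ("lincRNA", "non_coding"):
            intergenic.append((gid, sub))
        else:
            attached.append((gid, sub))
    order = rng.permutation(len(intergenic))
    intergenic = [intergenic[i] for i in order]

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    placed: dict[str, GeneModel] = {}
    chrom_idx, cursor = 0, 0
    for gid, gtype in intergenic:
        if gtype == "protein_coding":
            length = int(rng.integers(20_000, 80_001))
            n_exons = int(rng.integers(3, 6))
        else:
            length = int(rng.integers(5_000, 30_001))
            n_exons = int(rng.integers(1, 4))
        gap = int(rng.integers(1_000, 30_001))
        while chrom_idx < len(chroms) and cursor + gap + length > cfg.chrom_length:
            chrom_idx += 1
            cursor = 0
        if chrom_idx >= len(chroms):
            raise SizingError(
                f"cannot place {len(intergenic)} intergenic genes of ~5-80 kb on "
                f"{cfg.n_chromosomes} chromosome(s) of {cfg.chrom_length} bp"
            )
        start = cursor + gap
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        placed[gid] = GeneModel(
            gene_id=gid,
            gene_type=gtype,
            chrom=chroms[chrom_idx],
            start=start,
            end=end,
            strand=strand,
            exons=_make_exons(rng, start, end, n_exons),
        )
        cursor = end

    coding = [placed[g] for g in pcg_ids]
    flip = {"+": "-", "-": "+"}
    for gid, sub in attached:
        host = coding[int(rng.integers(len(coding)))]
        if sub == "antisense":
            length = int(rng.integers(3_000, max(4_000, (host.end - host.start) // 2)))
            length = min(length, host.end - host.start - 200)
            start = host.start + int(rng.integers(0, host.end - host.start - length))
            end, strand = start + length, flip[host.strand]
        elif sub == "bidirectional_promoter_lncRNA":
            length = int(rng.integers(2_000, 10_001))
            gap = int(rng.integers(50, 501))
            if host.strand == "+":
                end = max(length + 1, host.start - gap)
                start = max(0, end - length)
            else:
                start = host.end + gap
                end = start + length
            strand = flip[host.strand]
            if end > cfg.chrom_length:
                start, end = max(0, cfg.chrom_length - length), cfg.chrom_length
        else:  # sense_intronic: inside a host intron, same strand
            introns = [
                (e0[1], e1[0])
                for e0, e1 in zip(host.exons, host.exons[1:])
                if e1[0] - e0[1] >= 600
            ]
            if not introns:
                intron = (host.start + 100, host.end - 100)
            else:
                intron = introns[int(rng.integers(len(introns)))]
            length = int(rng.integers(200, max(201, min(5_000, intron[1] - intron[0] - 100))))
            start = intron[0] + int(rng.integers(0, max(1, intron[1] - intron[0] - length)))
            end, strand = start + length, host.strand
        placed[gid] = GeneModel(
            gene_id=gid,
            gene_type=sub,
            chrom=host.chrom,
            start=start,
            end=end,
            strand=strand,
            exons=_make_exons(rng, start, end, int(rng.integers(1, 4))),
        )

    return Annotation(placed[g] for g in pcg_ids + lnc_ids)


# ---------------------------------------------------------------------------
# variants


def _variant_at(
    rng: np.random.Generator, chrom: str, pos: int, vclass: str, chrom_length: int
) -> VariantRecord:
    if vclass == "SNV":
        length = 1
    elif vclass == "Indel":
        length = int(rng.integers(2, 51))
    else:
        length = int(rng.integers(10_000, 100_001))
    start = min(pos, chrom_length - length)
    start = max(0, start)
    return VariantRecord(chrom, start, start + length, vclass)


def generate_variants(
    cfg: SyntheticConfig, annotation: Annotation
) -> tuple[list[VariantRecord], set[str]]:
    """Variants with a planted fraction of lncRNAs guaranteed >= 1 gene-body hit."""
    rng = _rng(cfg, "variants")
    lncs = annotation.lncRNAs
    n_planted = int(round(cfg.planted_hit_fraction * len(lncs)))
    planted_idx = rng.choice(len(lncs), size=n_planted, replace=False)
    planted = {lncs[i].gene_id for i in planted_idx}
    classes = np.array(["SNV", "Indel", "CNV"])

    variants: list[VariantRecord] = []
    for i in sorted(planted_idx):
        g = lncs[i]
        vclass = str(classes[int(rng.integers(3))])
        pos = int(rng.integers(g.start, g.end))
        v = _variant_at(rng, g.chrom, pos, vclass, cfg.chrom_length)
        # guarantee overlap even after end-of-chromosome clipping
        if not (v.start < g.end and g.start < v.end):
            v = VariantRecord(g.chrom, g.start, min(g.end, g.start + (v.end - v.start)), vclass)
        variants.append(v)

    chroms = sorted(annotation.chroms)
    for _ in range(max(0, cfg.n_variants - len(variants))):
        chrom = chroms[int(rng.integers(len(chroms)))]
        vclass = str(classes[int(rng.integers(3))])
        pos = int(rng.integers(0, cfg.chrom_length))
        variants.append(_variant_at(rng, chrom, pos, vclass, cfg.chrom_length))
    return variants, planted


# ---------------------------------------------------------------------------
# expression


def _tissue_labels(cfg: SyntheticConfig) -> tuple[list[str], set[str]]:
    n_brain = max(1, min(len(BRAIN_TISSUES), cfg.n_tissues - 2)) if cfg.n_tissues > 2 else 1
    tissues = list(BRAIN_TISSUES[:n_brain])
    i = 0
    while len(tissues) < cfg.n_tissues:
        tissues.append(
            NON_BRAIN_TISSUES[i % len(NON_BRAIN_TISSUES)]
            + ("" if i < len(NON_BRAIN_TISSUES) else f"_{i}")
        )
        i += 1
    return tissues, set(tissues) & set(BRAIN_TISSUES)


def generate_expression(
    cfg: SyntheticConfig, annotation: Annotation, planted_hits: set[str]
) -> tuple[ExpressionMatrix, dict[str, set[str]]]:
    """TPM-like matrix with planted correlated modules in every tissue.

    Each module holds one planted-hit lncRNA (when available) plus
    protein-coding genes; within each tissue all module members load on a
    shared latent factor so that coding-coding pairwise correlation
    approximates ``within_module_cor``. The module lncRNA carries much
    less private noise, making it a near-pure readout of the factor (its
    correlation with module coding genes is ~sqrt(within_module_cor)).
    Other genes are independent noise. Values are shifted to a positive
    baseline and truncated at 0.
    """
    rng = _rng(cfg, "expression")
    gene_ids = annotation.gene_ids
    coding_ids = [g.gene_id for g in annotation.protein_coding]
    lnc_ids = [g.gene_id for g in annotation.lncRNAs]
    if cfg.n_modules * cfg.module_size > len(gene_ids):
        raise SizingError(
            f"{cfg.n_modules} modules x {cfg.module_size} genes exceed {len(gene_ids)} genes"
        )
    if cfg.n_modules * (cfg.module_size - 1) > len(coding_ids):
        raise SizingError("not enough protein-coding genes to fill the planted modules")

    hit_pool = sorted(planted_hits) or list(lnc_ids)
    module_lncs = [hit_pool[i % len(hit_pool)] for i in range(cfg.n_modules)]
    # distinct lncRNA per module when possible
    if len(set(module_lncs)) < cfg.n_modules and len(hit_pool) >= cfg.n_modules:
        module_lncs = hit_pool[: cfg.n_modules]
    coding_pick = rng.choice(len(coding_ids), size=cfg.n_modules * (cfg.module_size - 1), replace=False)
    modules: dict[str, set[str]] = {}
    gene_module: dict[str, int] = {}
    for m in range(cfg.n_modules):
        members = {module_lncs[m]}
        for j in coding_pick[m * (cfg.module_size - 1) : (m + 1) * (cfg.module_size - 1)]:
            members.add(coding_ids[int(j)])
        modules[f"M{m + 1}"] = members
        for g in members:
            gene_module[g] = m

    tissues, brain = _tissue_labels(cfg)
    lnc_set = set(lnc_ids)
    r = cfg.within_module_cor
    sd = cfg.noise_sd
    loading = sd * np.sqrt(r / (1.0 - r)) if sd > 0 else 1.0
    base = pd.Series(rng.uniform(5.0, 15.0, size=len(gene_ids)), index=gene_ids)
    # planted hit lncRNAs get a mild cortex boost (tissue-specific signal)
    scale = pd.Series(
        np.where(
            [g in gene_module for g in gene_ids],
            sd,
            sd * rng.uniform(0.2, 0.9, size=len(gene_ids)),
        ),
        index=gene_ids,
    )

    cols: dict[str, np.ndarray] = {}
    sample_tissue: dict[str, str] = {}
    for t in tissues:
        factors = rng.standard_normal((cfg.n_modules, cfg.samples_per_tissue))
        noise = rng.standard_normal((len(gene_ids), cfg.samples_per_tissue))
        block = np.empty((len(gene_ids), cfg.samples_per_tissue))
        for i, g in enumerate(gene_ids):
            if g in gene_module:
                if sd > 0:
                    # module lncRNAs get 1/5 of the private noise so their
                    # adjacency to module coding genes survives high soft powers
                    g_sd = sd * (0.2 if g in lnc_set else 1.0)
                    block[i] = base[g] + loading * factors[gene_module[g]] + g_sd * noise[i]
                else:
                    block[i] = base[g] + factors[gene_module[g]]
            else:
                block[i] = base[g] + scale[g] * noise[i]
        if t == "cortex":
            boost = np.array([1.0 + (g in planted_hits) for g in gene_ids])
            block = block * boost[:, None]
        block = np.maximum(block, 0.0)
        for j in range(cfg.samples_per_tissue):
            sid = f"{t}_s{j + 1:02d}"
            cols[sid] = block[:, j]
            sample_tissue[sid] = t

    values = pd.DataFrame(cols, index=gene_ids)
    expr = ExpressionMatrix(
        values=values,
        sample_tissue=pd.Series(sample_tissue),
        brain_tissues=frozenset(brain),
    )
    return expr, modules


# ---------------------------------------------------------------------------
# miRNA interactions


def generate_interactions(
    cfg: SyntheticConfig, annotation: Annotation, planted_hits: set[str]
) -> tuple[pd.DataFrame, set[tuple[str, str]]]:
    """miRNA->target edges with planted shared-regulator ceRNA pairs.

    Each planted pair receives ``PLANTED_SHARED_MIRNAS`` common
    regulators on top of the random background edges.
    """
    rng = _rng(cfg, "interactions")
    gene_ids = annotation.gene_ids
    coding_ids = [g.gene_id for g in annotation.protein_coding]
    mirna_ids = [f"mir{i + 1:04d}" for i in range(cfg.n_mirnas)]
    if cfg.targets_per_mirna > len(gene_ids):
        raise SizingError("targets_per_mirna exceeds the number of genes")

    edges: list[tuple[str, str]] = []
    for mir in mirna_ids:
        for j in rng.choice(len(gene_ids), size=cfg.targets_per_mirna, replace=False):
            edges.append((mir, gene_ids[int(j)]))

    planted_pairs: set[tuple[str, str]] = set()
    if cfg.n_planted_cerna_pairs > 0:
        lnc_pool = sorted(planted_hits) or [g.gene_id for g in annotation.lncRNAs]
        if cfg.n_planted_cerna_pairs > len(coding_ids):
            raise SizingError("more planted ceRNA pairs than protein-coding genes")
        partners = rng.choice(len(coding_ids), size=cfg.n_planted_cerna_pairs, replace=False)
        for i, j in enumerate(partners):
            lnc = lnc_pool[i % len(lnc_pool)]
            gene = coding_ids[int(j)]
            planted_pairs.add((lnc, gene))
            for m in rng.choice(cfg.n_mirnas, size=PLANTED_SHARED_MIRNAS, replace=False):
                edges.append((mirna_ids[int(m)], lnc))
                edges.append((mirna_ids[int(m)], gene))

    table = (
        pd.DataFrame(edges, columns=["miRNA_id", "gene_id"])
        .drop_duplicates()
        .sort_values(["miRNA_id", "gene_id"])
        .reset_index(drop=True)
    )
    return table, planted_pairs


# ---------------------------------------------------------------------------
# gene sets, drugs, known genes


def _neighbor_pool(
    cfg: SyntheticConfig, annotation: Annotation, truth: GroundTruth
) -> set[str]:
    """Protein-coding genes expected as co-expression/ceRNA neighbors of planted hits.

    Genomic-flank genes are deliberately excluded: with densely packed
    synthetic chromosomes they would cover most of the coding universe
    and wash out the planted enrichment signal.
    """
    pool: set[str] = set()
    coding = {g.gene_id for g in annotation.protein_coding}
    for members in truth.planted_modules.values():
        pool |= members & coding
    for _lnc, gene in truth.planted_cerna_pairs:
        pool.add(gene)
    return pool & coding


def generate_genesets_and_drugs(
    cfg: SyntheticConfig, annotation: Annotation, truth: GroundTruth
) -> tuple[
    dict[str, tuple[str, set[str]]],
    dict[str, tuple[str, set[str]]],
    list[str],
    set[str],
    set[str],
]:
    """Pathway GMT, drug GMT and known-gene list with planted enrichment.

    Planted pathways draw most members from the planted-hit neighbor
    pool; planted drugs draw most of their pathway set from the planted
    pathways. Returns (pathways, drug_sets, known_genes,
    planted_pathways, planted_drugs).
    """
    rng = _rng(cfg, "genesets")
    coding_ids = [g.gene_id for g in annotation.protein_coding]
    lo, hi = cfg.pathway_size_range
    if hi > len(coding_ids):
        raise SizingError(
            f"pathway_size_range max {hi} exceeds {len(coding_ids)} protein-coding genes"
        )
    pool = sorted(_neighbor_pool(cfg, annotation, truth))
    others = sorted(set(coding_ids) - set(pool))

    n_planted_pw = min(cfg.n_pathways, max(3, cfg.n_pathways // 10))
    pathway_ids = [f"PW{i + 1:04d}" for i in range(cfg.n_pathways)]
    planted_pw = set(pathway_ids[:n_planted_pw])
    pathways: dict[str, tuple[str, set[str]]] = {}
    for pid in pathway_ids:
        size = int(rng.integers(lo, hi + 1))
        if pid in planted_pw and pool:
            n_from_pool = min(len(pool), int(np.ceil(0.9 * size)))
            members = {pool[int(i)] for i in rng.choice(len(pool), size=n_from_pool, replace=False)}
            rest_pool = [g for g in coding_ids if g not in members]
            extra = rng.choice(len(rest_pool), size=size - len(members), replace=False)
            members |= {rest_pool[int(i)] for i in extra}
            desc = "planted pathway"
        else:
            members = {coding_ids[int(i)] for i in rng.choice(len(coding_ids), size=size, replace=False)}
            desc = "background pathway"
        pathways[pid] = (desc, members)

    n_planted_drugs = max(1, cfg.n_drugs // 5)
    drug_ids = [f"DRUG{i + 1:03d}" for i in range(cfg.n_drugs)]
    planted_drugs = set(drug_ids[:n_planted_drugs])
    non_planted_pw = [p for p in pathway_ids if p not in planted_pw]
    drug_sets: dict[str, tuple[str, set[str]]] = {}
    for did in drug_ids:
        if did in planted_drugs:
            n_from_planted = min(
                len(planted_pw), max(cfg.pathways_per_drug // 2 + 1, cfg.pathways_per_drug - 2)
            )
            pw = {
                sorted(planted_pw)[int(i)]
                for i in rng.choice(len(planted_pw), size=n_from_planted, replace=False)
            }
            n_rest = cfg.pathways_per_drug - len(pw)
            if n_rest > 0 and non_planted_pw:
                pw |= {
                    non_planted_pw[int(i)]
                    for i in rng.choice(len(non_planted_pw), size=min(n_rest, len(non_planted_pw)), replace=False)
                }
            desc = "planted drug"
        else:
            pw = {
                pathway_ids[int(i)]
                for i in rng.choice(len(pathway_ids), size=min(cfg.pathways_per_drug, len(pathway_ids)), replace=False)
            }
            desc = "background drug"
        drug_sets[did] = (desc, pw)

    known: set[str] = set()
    if pool:
        n_known_pool = max(1, len(pool) // 2)
        known |= {pool[int(i)] for i in rng.choice(len(pool), size=n_known_pool, replace=False)}
    if others:
        n_known_bg = max(1, len(others) // 20)
        known |= {others[int(i)] for i in rng.choice(len(others), size=n_known_bg, replace=False)}

    return pathways, drug_sets, sorted(known), planted_pw, planted_drugs


# ---------------------------------------------------------------------------
# orchestration


def generate_all(cfg: SyntheticConfig, outdir: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Generate and write every pipeline input; returns file paths and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth()

    annotation = generate_annotation(cfg)
    variants, planted_hits = generate_variants(cfg, annotation)
    truth.planted_lncRNA_hits = planted_hits
    expr, modules = generate_expression(cfg, annotation, planted_hits)
    truth.planted_modules = modules
    interactions, pairs = generate_interactions(cfg, annotation, planted_hits)
    truth.planted_cerna_pairs = pairs
    pathways, drugs, known, planted_pw, planted_dr = generate_genesets_and_drugs(
        cfg, annotation, truth
    )
    truth.planted_enriched_pathways = planted_pw
    truth.planted_effective_drugs = planted_dr

    paths = {
        "annotation": outdir / "annotation.gtf",
        "variants": outdir / "variants.bed",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "interactions": outdir / "interactions.tsv",
        "pathways": outdir / "pathways.gmt",
        "drugs": outdir / "drugs.gmt",
        "known_genes": outdir / "known_genes.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "config": outdir / "config.json",
    }
    lio.write_gtf(annotation, paths["annotation"])
    lio.write_variants_bed(variants, paths["variants"])
    lio.write_expression(expr, paths["expression"], paths["samples"])
    interactions.to_csv(paths["interactions"], sep="\t", index=False)
    lio.write_gmt(pathways, paths["pathways"])
    lio.write_gmt(drugs, paths["drugs"])
    lio.write_gene_list(known, paths["known_genes"])
    truth.to_json(paths["ground_truth"])
    paths["config"].write_text(json.dumps(dataclasses.asdict(cfg), indent=1) + "\n")
    return paths, truth
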