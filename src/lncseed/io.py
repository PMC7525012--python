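"""Readers and writers for the plain-text formats the pipeline consumes.

GTF is written/read in the Ensembl dialect (attributes ``gene_id`` and
``gene_biotype``); variants are BED6 with the variant class in the name
column; gene sets use standard GMT (id, description, members).
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .models import Annotation, ExpressionMatrix, GeneModel, VariantRecord

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')

GTF_SOURCE = "lncseed"


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path) -> Annotation:
    """Parse a GTF into an :class:`Annotation`.

    Uses ``gene`` features for spans and ``exon`` features for exon
    structure; coordinates are converted from GTF's 1-based closed to
    0-based half-open. Duplicate gene ids raise.
    """
    gene_rows: dict[str, dict] = {}
    exon_rows: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GTF line: {line!r}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = f[:9]
            a = _parse_attributes(attrs)
            gid = a.get("gene_id")
            if gid is None:
                raise ValueError(f"GTF line without gene_id: {line!r}")
            s, e = int(start) - 1, int(end)
            if feature == "gene":
                if gid in gene_rows:
                    raise ValueError(f"duplicate gene id in annotation: {gid}")
                gene_rows[gid] = dict(
                    chrom=chrom,
                    start=s,
                    end=e,
                    strand=strand,
                    gene_type=a.get("gene_biotype", "other"),
                )
                order.append(gid)
            elif feature == "exon":
                exon_rows.setdefault(gid, []).append((s, e))
    genes = []
    for gid in order:
        row = gene_rows[gid]
        exons = tuple(sorted(exon_rows.get(gid, [(row["start"], row["end"])])))
        genes.append(GeneModel(gene_id=gid, exons=exons, **row))
    return Annotation(genes)


def write_gtf(annotation: Annotation | Iterable[GeneModel], path: str | Path) -> None:
    lines = []
    for g in annotation:
        attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.gene_type}";'
        lines.append(
            f"{g.chrom}\t{GTF_SOURCE}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for s, e in g.exons:
            lines.append(
                f"{g.chrom}\t{GTF_SOURCE}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_variants_bed(path: str | Path) -> list[VariantRecord]:
    """Read BED6 variants; the name column carries the variant class."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ValueError(f"BED line needs >=4 columns: {line!r}")
            out.append(VariantRecord(f[0], int(f[1]), int(f[2]), f[3]))
    return out


def write_variants_bed(variants: Iterable[VariantRecord], path: str | Path) -> None:
    lines = [f"{v.chrom}\t{v.start}\t{v.end}\t{v.variant_class}\t0\t." for v in variants]
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression(
    expr_path: str | Path,
    sample_map_path: str | Path,
) -> ExpressionMatrix:
    """Read a gene x sample TSV plus a sample->tissue map.

    The sample map has columns ``sample_id``, ``tissue`` and optionally
    ``is_brain`` (0/1) marking brain tissues.
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    smap = pd.read_csv(sample_map_path, sep="\t", dtype={"sample_id": str})
    smap = smap.set_index("sample_id")
    brain: frozenset[str] = frozenset()
    if "is_brain" in smap.columns:
        brain = frozenset(smap.loc[smap["is_brain"].astype(int) == 1, "tissue"])
    return ExpressionMatrix(values=values, sample_tissue=smap["tissue"], brain_tissues=brain)


def write_expression(expr: ExpressionMatrix, expr_path: str | Path, sample_map_path: str | Path) -> None:
    expr.values.to_csv(expr_path, sep="\t", float_format="%.6g", index_label="gene_id")
    rows = [
        {
            "sample_id": s,
            "tissue": expr.sample_tissue[s],
            "is_brain": int(expr.sample_tissue[s] in expr.brain_tissues),
        }
        for s in expr.values.columns
    ]
    pd.DataFrame(rows).to_csv(sample_map_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file: term id -> (description, member set)."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"GMT line needs >=3 columns: {line!r}")
            sets[f[0]] = (f[1], set(f[2:]))
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    lines = [
        "\t".join([term, desc, *sorted(members)]) for term, (desc, members) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line (first tab-separated column; '#' comments skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split("\t")[0])
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")
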