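"""Core domain types shared across pipeline stages.

Coordinates are 0-based half-open throughout (BED convention); GTF's
1-based closed coordinates are converted at parse/write time in :mod:`lncseed.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

#: The five annotation biotypes treated as lncRNA subclasses.
LNCRNA_SUBCLASSES = (
    "antisense",
    "bidirectional_promoter_lncRNA",
    "lincRNA",
    "non_coding",
    "sense_intronic",
)

VARIANT_CLASSES = ("SNV", "Indel", "CNV")

DEFAULT_PROMOTER_LENGTH = 5_000


@dataclass(frozen=True)
class GeneModel:
    """A gene with biotype, strand and exon structure."""

    gene_id: str
    gene_type: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end ({self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s}, {e}) outside gene span")

    @property
    def is_lncRNA(self) -> bool:
        return self.gene_type in LNCRNA_SUBCLASSES

    @property
    def is_protein_coding(self) -> bool:
        return self.gene_type == "protein_coding"

    def promoter(self, length: int = DEFAULT_PROMOTER_LENGTH) -> tuple[int, int]:
        """Strand-aware promoter interval upstream of the TSS, clipped at 0."""
        if self.strand == "+":
            return (max(0, self.start - length), self.start)
        return (self.end, self.end + length)


@dataclass(frozen=True)
class VariantRecord:
    """A genomic interval carrying a variant class (SNV, Indel or CNV)."""

    chrom: str
    start: int
    end: int
    variant_class: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"variant start must be < end ({self.start}, {self.end})")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")


class Annotation:
    """Ordered collection of :class:`GeneModel`, unique by gene_id."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene id in annotation: {g.gene_id}")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    @property
    def lncRNAs(self) -> list[GeneModel]:
        return [g for g in self if g.is_lncRNA]

    @property
    def protein_coding(self) -> list[GeneModel]:
        return [g for g in self if g.is_protein_coding]

    @property
    def chroms(self) -> set[str]:
        return {g.chrom for g in self}


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative expression (TPM-like) with tissue labels."""

    values: pd.DataFrame  # genes x samples
    sample_tissue: pd.Series  # sample id -> tissue label
    brain_tissues: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.sample_tissue.index)
        if missing:
            raise ValueError(f"samples without tissue label: {sorted(missing)[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_tissue[s], None)
        return list(seen)

    def samples_for(self, tissue: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_tissue[s] == tissue]

    def subset_tissue(self, tissue: str) -> pd.DataFrame:
        """Expression of all genes restricted to one tissue's samples."""
        cols = self.samples_for(tissue)
        if not cols:
            raise KeyError(f"no samples for tissue {tissue!r}")
        return self.values[cols]

    def tissue_medians(self) -> pd.DataFrame:
        """Per-gene median expression per tissue (genes x tissues)."""
        med = {t: self.subset_tissue(t).median(axis=1) for t in self.tissues}
        return pd.DataFrame(med, index=self.values.index)
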