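import numpy as np
import pytest

from lncseed import io as lio
from lncseed.models import Annotation, GeneModel, VariantRecord
from lncseed.variant_mapping import (
    HitList,
    cnv_validation,
    containment_report,
    genomic_neighbors,
    identify_lncRNAs,
    subclass_distribution,
)

from oracles import brute_force_hits


def gene(gid, start, end, gtype="lincRNA", strand="+", chrom="chr1", exons=None):
    return GeneModel(
        gene_id=gid, gene_type=gtype, chrom=chrom, start=start, end=end,
        strand=strand, exons=tuple(exons or [(start, end)]),
    )


def var(start, end, chrom="chr1", vclass="SNV"):
    return VariantRecord(chrom, start, end, vclass)


class TestIdentify:
    def test_contained_variant_hits(self):
        ann = Annotation([gene("L1", 50, 200)])
        hits = identify_lncRNAs([var(100, 101)], ann, "gene")
        assert hits.lncRNA_ids == ["L1"]
        assert hits.per_id_support == {"L1": 1}

    def test_half_open_boundary_no_hit(self):
        ann = Annotation([gene("L1", 50, 200)])
        hits = identify_lncRNAs([var(200, 201)], ann, "gene")
        assert len(hits) == 0

    def test_minus_strand_promoter(self):
        g = gene("L1", 1000, 2000, strand="-", exons=[(1100, 1900)])
        ann = Annotation([g])
        v = [var(6999, 7000)]
        assert g.promoter() == (2000, 7000)
        assert "L1" not in identify_lncRNAs(v, ann, "gene")
        assert "L1" not in identify_lncRNAs(v, ann, "exon")
        assert "L1" in identify_lncRNAs(v, ann, "gene_plus_promoter")

    def test_coding_genes_never_hit(self):
        ann = Annotation([gene("P1", 0, 500, gtype="protein_coding"), gene("L1", 1000, 2000)])
        hits = identify_lncRNAs([var(100, 101), var(1500, 1501)], ann, "gene")
        assert hits.lncRNA_ids == ["L1"]

    def test_empty_variants_empty_hitlist(self):
        ann = Annotation([gene("L1", 50, 200)])
        hits = identify_lncRNAs([], ann, "gene")
        assert len(hits) == 0

    def test_chromosome_mismatch_warns(self):
        ann = Annotation([gene("L1", 50, 200, chrom="chr1")])
        with pytest.warns(UserWarning, match="chr2"):
            identify_lncRNAs([var(100, 101, chrom="chr2")], ann, "gene")

    def test_invalid_mode_rejected(self):
        ann = Annotation([gene("L1", 50, 200)])
        with pytest.raises(ValueError):
            identify_lncRNAs([var(100, 101)], ann, "body")

    def test_support_counts_distinct_variants(self):
        # one variant spanning body and promoter counts once
        g = gene("L1", 1000, 2000, strand="+")
        hits = identify_lncRNAs([var(900, 1100)], Annotation([g]), "gene_plus_promoter")
        assert hits.per_id_support["L1"] == 1

    @pytest.mark.parametrize("mode", ["gene", "exon", "gene_plus_promoter"])
    def test_agrees_with_brute_force(self, variants, annotation, mode):
        hits = identify_lncRNAs(variants, annotation, mode)
        oracle = brute_force_hits(variants, list(annotation), mode)
        assert hits.per_id_support == oracle

    def test_agrees_with_brute_force_random_instance(self):
        rng = np.random.default_rng(42)
        genes = []
        for i in range(300):
            s = int(rng.integers(0, 500_000))
            e = s + int(rng.integers(100, 20_000))
            es = s + int(rng.integers(1, (e - s) // 2))
            ee = es + int(rng.integers(1, e - es))
            genes.append(
                gene(f"L{i}", s, e, strand="+" if rng.random() < 0.5 else "-",
                     chrom=f"chr{int(rng.integers(1, 3))}", exons=[(es, ee)])
            )
        vs = []
        for _ in range(500):
            s = int(rng.integers(0, 520_000))
            vs.append(var(s, s + int(rng.integers(1, 5_000)), chrom=f"chr{int(rng.integers(1, 3))}"))
        for mode in ("gene", "exon", "gene_plus_promoter"):
            hits = identify_lncRNAs(vs, Annotation(genes), mode)
            assert hits.per_id_support == brute_force_hits(vs, genes, mode)

    def test_mode_monotonicity(self, variants, annotation):
        exon = set(identify_lncRNAs(variants, annotation, "exon").lncRNA_ids)
        body = set(identify_lncRNAs(variants, annotation, "gene").lncRNA_ids)
        prom = set(identify_lncRNAs(variants, annotation, "gene_plus_promoter").lncRNA_ids)
        assert exon <= body <= prom

    def test_planted_recall_is_one(self, dataset, variants, annotation):
        _, truth = dataset
        hits = identify_lncRNAs(variants, annotation, "gene")
        assert truth.planted_lncRNA_hits <= set(hits.lncRNA_ids)


class TestHitListContract:
    def test_support_must_be_positive(self):
        with pytest.raises(ValueError):
            HitList(mode="gene", lncRNA_ids=["L1"], per_id_support={"L1": 0})

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            HitList(mode="nope", lncRNA_ids=[], per_id_support={})


class TestContainment:
    def _hl(self, mode, ids):
        return HitList(mode=mode, lncRNA_ids=ids, per_id_support={i: 1 for i in ids})

    def test_identity_is_100(self):
        hits = {"gene": self._hl("gene", ["a", "b"]), "exon": self._hl("exon", ["a", "b"])}
        rep = containment_report(hits)
        assert (rep["containment_pct"] == 100.0).all()

    def test_disjoint_is_0(self):
        hits = {"gene": self._hl("gene", ["a", "b"]),
                "exon": self._hl("exon", ["c", "d", "e", "f"])}
        rep = containment_report(hits).set_index(["mode_a", "mode_b"])
        assert rep.loc[("gene", "exon"), "containment_pct"] == 0.0

    def test_empty_reference_is_na(self):
        hits = {"gene": self._hl("gene", ["a"]), "exon": self._hl("exon", [])}
        rep = containment_report(hits).set_index(["mode_a", "mode_b"])
        assert np.isnan(rep.loc[("gene", "exon"), "containment_pct"])

    def test_needs_two_modes(self):
        with pytest.raises(ValueError):
            containment_report({"gene": self._hl("gene", ["a"])})

    def test_exon_hits_contained_in_gene_hits(self, variants, annotation):
        hits = {
            m: identify_lncRNAs(variants, annotation, m) for m in ("gene", "exon")
        }
        rep = containment_report(hits).set_index(["mode_a", "mode_b"])
        assert rep.loc[("gene", "exon"), "containment_pct"] == 100.0


class TestCnvValidation:
    def _setup(self):
        genes = [gene(f"L{i}", i * 10_000, i * 10_000 + 5_000) for i in range(10)]
        ann = Annotation(genes)
        hits = HitList("gene", [g.gene_id for g in genes],
                       {g.gene_id: 1 for g in genes})
        return ann, hits, genes

    def test_saturation(self):
        ann, hits, genes = self._setup()
        cnvs = [var(g.start, g.end, vclass="CNV") for g in genes]
        assert cnv_validation(hits, cnvs, ann) == 1.0

    def test_no_overlap(self):
        ann, hits, _ = self._setup()
        cnvs = [var(900_000, 950_000, vclass="CNV")]
        assert cnv_validation(hits, cnvs, ann) == 0.0

    def test_seven_of_ten(self):
        ann, hits, genes = self._setup()
        cnvs = [var(g.start + 10, g.start + 20, vclass="CNV") for g in genes[:7]]
        assert cnv_validation(hits, cnvs, ann) == pytest.approx(0.7)

    def test_exclude_rederives_hits(self):
        ann, _, genes = self._setup()
        shared_cnv = var(genes[0].start, genes[0].end, vclass="CNV")
        snv = var(genes[1].start + 5, genes[1].start + 6)
        variants = [shared_cnv, snv]
        hits = identify_lncRNAs(variants, ann, "gene")
        assert len(hits) == 2
        # after excluding the CNV from the variant set, only L1 remains a hit
        frac = cnv_validation(hits, [shared_cnv], ann, variants=variants, exclude=[shared_cnv])
        assert frac == 0.0  # L1's gene body is not overlapped by the CNV

    def test_empty_cnv_set_rejected(self):
        ann, hits, _ = self._setup()
        with pytest.raises(ValueError):
            cnv_validation(hits, [], ann)


class TestGenomicNeighbors:
    def _ann(self):
        return Annotation([
            gene("L1", 100_000, 110_000),
            gene("P_near", 120_000, 125_000, gtype="protein_coding"),   # 10 kb away
            gene("P_far", 170_001, 175_000, gtype="protein_coding"),    # 60 kb away
            gene("P_overlap", 105_000, 108_000, gtype="protein_coding"),
            gene("L_other", 121_000, 122_000),                          # lncRNA, never a neighbor
        ])

    def test_flank_50kb(self):
        nbrs = genomic_neighbors(["L1"], self._ann(), flank=50_000)
        assert nbrs["L1"] == {"P_near", "P_overlap"}

    def test_flank_zero_overlap_only(self):
        nbrs = genomic_neighbors(["L1"], self._ann(), flank=0)
        assert nbrs["L1"] == {"P_overlap"}

    def test_flank_monotonicity(self):
        ann = self._ann()
        prev = set()
        for flank in (0, 10_000, 50_000, 100_000):
            cur = genomic_neighbors(["L1"], ann, flank=flank)["L1"]
            assert prev <= cur
            prev = cur

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            genomic_neighbors(["L1"], self._ann(), flank=-1)


class TestSubclassDistribution:
    def test_example_proportions(self):
        genes = [gene(f"L{i}", i * 1000, i * 1000 + 500, gtype="lincRNA") for i in range(6)]
        genes += [gene(f"A{i}", 100_000 + i * 1000, 100_000 + i * 1000 + 500,
                       gtype="antisense") for i in range(4)]
        ann = Annotation(genes)
        ids = [g.gene_id for g in genes]
        hits = HitList("gene", ids, {i: 1 for i in ids})
        dist = subclass_distribution(hits, ann).set_index("subclass")
        assert dist.loc["lincRNA", "proportion"] == pytest.approx(0.6)
        assert dist.loc["antisense", "proportion"] == pytest.approx(0.4)

    def test_proportions_sum_to_one(self, variants, annotation):
        hits = identify_lncRNAs(variants, annotation, "gene")
        dist = subclass_distribution(hits, annotation)
        assert dist["proportion"].sum() == pytest.approx(1.0)


class TestGtfParsing:
    def test_duplicate_gene_id_rejected(self, tmp_path):
        g = gene("L1", 100, 200)
        path = tmp_path / "dup.gtf"
        lio.write_gtf([g], path)
        content = path.read_text()
        path.write_text(content + content)
        with pytest.raises(ValueError, match="duplicate"):
            lio.read_gtf(path)

    def test_roundtrip(self, tmp_path, annotation):
        path = tmp_path / "roundtrip.gtf"
        lio.write_gtf(annotation, path)
        back = lio.read_gtf(path)
        assert back.gene_ids == annotation.gene_ids
        for gid in annotation.gene_ids:
            assert back[gid] == annotation[gid]
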