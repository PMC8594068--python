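"""Accelerated-region classification/assignment vs per-base brute force."""

import numpy as np
import pytest

from hlscan.intervals import GenomicInterval, TranscriptionalUnit
from hlscan.regions import (AcceleratedRegion, AssignmentMode, CodingClass,
                            TadSet, assign_gene_body,
                            assign_regulatory_domain, assign_tad,
                            build_regulatory_domains, classify_coding,
                            summarize)


def unit(gene, start, end, strand="+", exons=(), chrom="chr1"):
    return TranscriptionalUnit(
        gene_id=gene,
        body=GenomicInterval(chrom, start, end, strand=strand),
        strand=strand,
        exons=[GenomicInterval(chrom, s, e) for s, e in exons],
    )


def region(start, end, chrom="chr1", rid=None):
    return AcceleratedRegion(
        interval=GenomicInterval(chrom, start, end, id=rid))


# ---------------------------------------------------------------------------
# per-base brute-force oracles


def oracle_classify(regions, units):
    out = []
    exon_bases = {}
    for u in units:
        for ex in u.exons:
            exon_bases.setdefault(ex.chrom, set()).update(
                range(ex.start, ex.end))
    for r in regions:
        bases = set(range(r.interval.start, r.interval.end))
        hit = bool(bases & exon_bases.get(r.interval.chrom, set()))
        out.append(CodingClass.CODING if hit else CodingClass.NONCODING)
    return out


def oracle_gene_body(regions, units, noncoding_only):
    out = []
    for r in regions:
        bases = set(range(r.interval.start, r.interval.end))
        assigned = set()
        for u in units:
            if u.body.chrom != r.interval.chrom:
                continue
            body = bases & set(range(u.body.start, u.body.end))
            if not body:
                continue
            if noncoding_only:
                exonic = set()
                for ex in u.exons:
                    exonic |= set(range(ex.start, ex.end))
                if body - exonic:
                    assigned.add(u.gene_id)
            else:
                assigned.add(u.gene_id)
        out.append(assigned)
    return out


def oracle_tad(regions, units, tads):
    out = []
    for r in regions:
        assigned = set()
        for t in tads.tads:
            if t.chrom != r.interval.chrom:
                continue
            if not (set(range(r.interval.start, r.interval.end))
                    & set(range(t.start, t.end))):
                continue
            for u in units:
                if u.body.chrom == t.chrom and t.start <= u.tss < t.end:
                    assigned.add(u.gene_id)
        out.append(assigned)
    return out


# ---------------------------------------------------------------------------


class TestClassifyCoding:
    def test_exon_overlap_is_coding(self):
        u = unit("g", 100, 1000, exons=[(150, 250)])
        (r,) = classify_coding([region(100, 200)], [u])
        assert r.coding_class == CodingClass.CODING

    def test_half_open_adjacency_is_not_overlap(self):
        u = unit("g", 100, 1000, exons=[(200, 300)])
        (r,) = classify_coding([region(100, 200)], [u])
        assert r.coding_class == CodingClass.NONCODING

    def test_partition_always_complete(self):
        rng = np.random.default_rng(2)
        units = [unit("g", 0, 5000, exons=[(100, 300), (2000, 2300)])]
        regions = [region(int(s), int(s) + int(l))
                   for s, l in zip(rng.integers(0, 6000, 50),
                                   rng.integers(1, 400, 50))]
        classify_coding(regions, units)
        n_cod = sum(r.coding_class == CodingClass.CODING for r in regions)
        n_non = sum(r.coding_class == CodingClass.NONCODING for r in regions)
        assert n_cod + n_non == len(regions)

    def test_min_fraction_threshold(self):
        u = unit("g", 0, 1000, exons=[(100, 110)])
        (r,) = classify_coding([region(100, 200)], [u], min_fraction=0.5)
        assert r.coding_class == CodingClass.NONCODING
        (r,) = classify_coding([region(100, 200)], [u], min_fraction=0.05)
        assert r.coding_class == CodingClass.CODING


class TestAssignGeneBody:
    def test_intronic_region_assigned(self):
        u = unit("g", 0, 10000, exons=[(0, 400), (9000, 9400)])
        (r,) = assign_gene_body([region(500, 700)], [u], noncoding_only=True)
        assert r.genes(AssignmentMode.GENE_BODY) == {"g"}

    def test_fully_exonic_region_dropped_when_noncoding_only(self):
        u = unit("g", 0, 10000, exons=[(400, 900)])
        (r,) = assign_gene_body([region(500, 700)], [u], noncoding_only=True)
        assert r.genes(AssignmentMode.GENE_BODY) == set()

    def test_region_spanning_two_genes_assigned_to_both(self):
        u1 = unit("g1", 0, 1000)
        u2 = unit("g2", 800, 2000)
        (r,) = assign_gene_body([region(900, 950)], [u1, u2])
        assert r.genes(AssignmentMode.GENE_BODY) == {"g1", "g2"}


class TestRegulatoryDomains:
    def test_single_gene_worked_example(self):
        """Lone + strand gene, TSS at 2 Mb, 5 kb up / 1 kb down basal and
        1 Mb maximum extension."""
        u = unit("g", 2_000_000, 2_020_000)
        (d,) = build_regulatory_domains([u], basal_up=5000, basal_down=1000,
                                        max_extension=1_000_000)
        assert (d.basal.start, d.basal.end) == (1_995_000, 2_001_000)
        assert (d.extended.start, d.extended.end) == (1_000_000, 3_000_000)

    def test_two_gene_worked_example(self):
        """Two + strand genes with TSSs 200 kb apart stop extending at each
        other's basal edges."""
        a = unit("A", 100_000, 150_000)
        b = unit("B", 300_000, 350_000)
        da, db = build_regulatory_domains([a, b], basal_up=5000,
                                          basal_down=1000,
                                          max_extension=1_000_000)
        assert da.extended.end == 295_000     # B's basal start
        assert db.extended.start == 101_000   # A's basal end
        assert da.extended.start == 0         # capped at chromosome start
        assert db.extended.end == 1_300_000   # TSS + max extension

    def test_zero_extension_means_basal_only(self):
        a = unit("A", 100_000, 150_000)
        b = unit("B", 300_000, 350_000)
        for d in build_regulatory_domains([a, b], 5000, 1000,
                                          max_extension=0):
            assert (d.extended.start, d.extended.end) == \
                (d.basal.start, d.basal.end)

    def test_minus_strand_basal_is_mirrored(self):
        u = unit("g", 100_000, 150_000, strand="-")
        (d,) = build_regulatory_domains([u], basal_up=5000, basal_down=1000,
                                        max_extension=0)
        tss = 149_999
        assert (d.basal.start, d.basal.end) == (tss - 1000 + 1, tss + 5000 + 1)

    def test_domain_assignment_one_base_overlap(self):
        u = unit("g", 2_000_000, 2_020_000)
        domains = build_regulatory_domains([u], 5000, 1000, 1_000_000)
        (r1,) = assign_regulatory_domain([region(999_000, 1_000_001)], domains)
        assert r1.genes(AssignmentMode.REG_DOMAIN) == {"g"}
        (r2,) = assign_regulatory_domain([region(999_000, 1_000_000)], domains)
        assert r2.genes(AssignmentMode.REG_DOMAIN) == set()


class TestAssignTad:
    def test_same_tad_assigned(self):
        u = unit("g", 1000, 2000)
        tads = TadSet([GenomicInterval("chr1", 0, 5000)])
        (r,) = assign_tad([region(4000, 4100)], [u], tads)
        assert r.genes(AssignmentMode.TAD) == {"g"}

    def test_different_tads_not_assigned(self):
        u = unit("g", 1000, 2000)
        tads = TadSet([GenomicInterval("chr1", 0, 3000),
                       GenomicInterval("chr1", 3000, 6000)])
        (r,) = assign_tad([region(4000, 4100)], [u], tads)
        assert r.genes(AssignmentMode.TAD) == set()

    def test_boundary_straddling_region_assigned_to_both(self):
        u1 = unit("g1", 1000, 2000)
        u2 = unit("g2", 4000, 5000)
        tads = TadSet([GenomicInterval("chr1", 0, 3000),
                       GenomicInterval("chr1", 3000, 6000)])
        (r,) = assign_tad([region(2900, 3100)], [u1, u2], tads)
        assert r.genes(AssignmentMode.TAD) == {"g1", "g2"}

    def test_overlapping_tads_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TadSet([GenomicInterval("chr1", 0, 3000),
                    GenomicInterval("chr1", 2000, 6000)])


class TestFuzzAgainstPerBaseOracle:
    def test_randomized_instances_match_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(25):
            n_genes = int(rng.integers(1, 4))
            units = []
            for g in range(n_genes):
                start = int(rng.integers(0, 8000))
                end = start + int(rng.integers(500, 2500))
                exons = []
                for _ in range(int(rng.integers(0, 3))):
                    es = int(rng.integers(start, end - 10))
                    exons.append((es, min(end, es + int(rng.integers(10, 400)))))
                units.append(unit(f"g{g}", start, end,
                                  strand="+" if rng.random() < 0.5 else "-",
                                  exons=exons))
            tad_ivs, prev_end = [], 0
            for s in np.sort(rng.integers(0, 9000, size=3)):
                if s >= prev_end:
                    length = int(rng.integers(500, 2000))
                    tad_ivs.append(GenomicInterval("chr1", int(s),
                                                   int(s) + length))
                    prev_end = int(s) + length
            tads = TadSet(tad_ivs or [GenomicInterval("chr1", 0, 5000)])
            regions = [region(int(s), int(s) + int(l), rid=f"r{i}")
                       for i, (s, l) in enumerate(zip(
                           rng.integers(0, 9500, 12),
                           rng.integers(1, 500, 12)))]
            noncoding_only = bool(rng.random() < 0.5)

            classify_coding(regions, units)
            assert [r.coding_class for r in regions] == \
                oracle_classify(regions, units)

            assign_gene_body(regions, units, noncoding_only=noncoding_only)
            expect = oracle_gene_body(regions, units, noncoding_only)
            assert [r.genes(AssignmentMode.GENE_BODY)
                    for r in regions] == expect

            assign_tad(regions, units, tads)
            assert [r.genes(AssignmentMode.TAD) for r in regions] == \
                oracle_tad(regions, units, tads)


class TestSummarize:
    def test_top_gene_by_region_count(self):
        u = unit("g", 0, 10000, exons=[(0, 100)])
        regions = [region(2000, 2100, rid="a"), region(3000, 3100, rid="b"),
                   region(4000, 4100, rid="c")]
        classify_coding(regions, units=[u])
        assign_gene_body(regions, [u])
        df = summarize(regions)
        row = df[df["mode"] == "GENE_BODY"].iloc[0]
        assert row["n_genes"] == 1 and row["top_genes"].startswith("g:3")
        assert row["n_regions"] == 3

    def test_empty_assignments_all_zero(self):
        regions = [region(0, 10)]
        classify_coding(regions, [])
        df = summarize(regions)
        assert (df["n_genes"] == 0).all()
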