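"""Gene-model intersection: GFF3 loading, footprint construction, context
assignment, allele tables, set-union arithmetic, frequency ranking, and
equivalence with a per-base brute-force overlap oracle."""

import numpy as np
import pytest

from plasmap.delcall import SecondaryDeletion
from plasmap.genemap import (
    DisruptionRecord,
    GeneIndex,
    GeneModel,
    SEVERITY,
    affected_genes,
    build_allele_table,
    disruption_frequency,
    lesion_footprint,
    load_gene_models,
    models_from_synthetic,
    mutant_disruptions,
    union_gene_count,
)
from plasmap.simdata import generate_gene_models, write_gff3
from tests.conftest import make_callset, make_complex, make_two_sided


@pytest.fixture(scope="module")
def synthetic_genes(small_reference):
    return generate_gene_models(small_reference, seed=21)


@pytest.fixture(scope="module")
def gene_index(synthetic_genes):
    return GeneIndex(models_from_synthetic(synthetic_genes))


class TestGFF3:
    def test_roundtrip_preserves_models(self, tmp_path, synthetic_genes):
        path = tmp_path / "genes.gff3"
        write_gff3(synthetic_genes, path)
        loaded = load_gene_models(path)
        assert len(loaded) == len(synthetic_genes)
        by_id = {g.gene_id: g for g in loaded}
        for s in synthetic_genes:
            g = by_id[s.gene_id]
            assert (g.chromosome, g.strand, g.start, g.end) == (
                s.chromosome, s.strand, s.start, s.end,
            )
            assert g.exons == sorted(s.exons)
            assert g.cds == sorted(s.cds)
            assert g.utr5 == sorted(s.utr5)
            assert g.utr3 == sorted(s.utr3)

    def test_exons_within_gene_and_nonoverlapping(self, tmp_path, synthetic_genes):
        path = tmp_path / "genes.gff3"
        write_gff3(synthetic_genes, path)
        for g in load_gene_models(path):
            assert all(g.start <= s < e <= g.end for s, e in g.exons)
            for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
                assert e1 <= s2

    def test_gene_without_utrs_still_loads(self, tmp_path):
        path = tmp_path / "min.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=gX\n"
            "chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=gX.t1;Parent=gX\n"
            "chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=e1;Parent=gX.t1\n"
            "chr1\tsrc\texon\t301\t400\t.\t+\t.\tID=e2;Parent=gX.t1\n"
        )
        (g,) = load_gene_models(path)
        assert g.utr5 == [] and g.utr3 == []
        assert g.exons == [(100, 200), (300, 400)]
        # exon/intron context falls back to exon intervals when CDS absent
        idx = GeneIndex([g])
        recs = affected_genes([("chr1", 150, 150)], idx, "m")
        assert recs[0].context == "exon"
        recs = affected_genes([("chr1", 250, 250)], idx, "m")
        assert recs[0].context == "intron"


class TestFootprints:
    def test_two_sided_deletion_footprint_is_deleted_interval(self):
        ev = make_two_sided("chr1", 10_000, 35_000)
        assert lesion_footprint(ev) == [("chr1", 10_000, 35_000)]

    def test_perfect_insertion_footprint_is_point(self):
        ev = make_two_sided("chr1", 10_000, 10_000)
        fps = lesion_footprint(ev)
        assert fps == [("chr1", 10_000, 10_000), ("chr1", 10_000, 10_000)]

    def test_duplication_footprint_is_junction_points_only(self):
        ev = make_two_sided("chr1", 10_000, 9_900)
        assert all(s == e for _, s, e in lesion_footprint(ev))

    def test_complex_lesion_contributes_all_junction_points(self):
        # four junctions on four chromosomes
        from plasmap.svcall import Lesion
        from tests.conftest import make_site

        lesion = Lesion(
            "complex",
            sites=[make_site(f"chr{i}", 10_000 * i, "left") for i in range(1, 5)],
        )
        fps = lesion_footprint(lesion)
        assert len(fps) == 4
        assert {c for c, *_ in fps} == {"chr1", "chr2", "chr3", "chr4"}

    def test_secondary_deletion_footprint(self):
        d = SecondaryDeletion("m", "chr2", 500, 900, "gapped_read", 3)
        assert lesion_footprint(d) == [("chr2", 500, 900)]


class TestAffectedGenes:
    def test_deletion_covering_genes_marks_whole_gene_deleted(self, gene_index):
        genes = list(gene_index.genes.values())[:5]
        chrom = genes[0].chromosome
        same = [g for g in genes if g.chromosome == chrom]
        lo = min(g.start for g in same) - 10
        hi = max(g.end for g in same) + 10
        recs = affected_genes([(chrom, lo, hi)], gene_index, "m")
        by_id = {r.gene_id: r for r in recs}
        for g in same:
            assert by_id[g.gene_id].context == "whole_gene_deleted"

    def test_point_in_cds_is_exon_context(self, gene_index):
        g = next(iter(gene_index.genes.values()))
        p = g.cds[0][0]  # junction of intron/exon boundary counts as exon
        recs = affected_genes([(g.chromosome, p, p)], gene_index, "m")
        assert any(r.gene_id == g.gene_id and r.context == "exon" for r in recs)

    def test_utr_contexts(self, gene_index):
        g = next(iter(gene_index.genes.values()))
        p5 = g.utr5[0][0]
        p3 = g.utr3[0][0]
        r5 = affected_genes([(g.chromosome, p5, p5)], gene_index, "m")
        r3 = affected_genes([(g.chromosome, p3, p3)], gene_index, "m")
        assert {r.context for r in r5 if r.gene_id == g.gene_id} == {"five_prime_utr"}
        assert {r.context for r in r3 if r.gene_id == g.gene_id} == {"three_prime_utr"}

    def test_intergenic_point_affects_nothing_with_promoter_off(self, gene_index):
        genes = sorted(gene_index.genes.values(), key=lambda g: (g.chromosome, g.start))
        a, b = genes[0], genes[1]
        assert b.start - a.end > 4  # intergenic space exists
        mid = (a.end + b.start) // 2
        assert affected_genes([(a.chromosome, mid, mid)], gene_index, "m") == []

    def test_point_strictly_upstream_not_affected(self, gene_index):
        g = min(gene_index.genes.values(), key=lambda g: g.start)
        p = g.start - 1
        recs = affected_genes([(g.chromosome, p, p)], gene_index, "m")
        assert all(r.gene_id != g.gene_id for r in recs)

    def test_promoter_window_opt_in(self, gene_index):
        g = next(
            g for g in gene_index.genes.values() if g.strand == "+" and g.start > 300
        )
        p = g.start - 100
        recs = affected_genes(
            [(g.chromosome, p, p)], gene_index, "m", promoter_window=500
        )
        assert any(
            r.gene_id == g.gene_id and r.context == "upstream_only" for r in recs
        )

    def test_context_is_total_function(self, gene_index, small_reference):
        rng = np.random.default_rng(9)
        for _ in range(200):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 149_000))
            end = start + int(rng.integers(0, 2_000))
            for r in affected_genes([(chrom, start, end)], gene_index, "m"):
                assert r.context in SEVERITY


class TestBruteForceOracle:
    def test_interval_engine_matches_per_base_oracle(self, gene_index, small_reference):
        """Random footprints on a small genome: the interval engine and a
        per-base membership oracle agree on the affected gene set."""
        rng = np.random.default_rng(12345)
        genes = list(gene_index.genes.values())
        for _ in range(120):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 100_000))
            end = start + int(rng.integers(0, 5_000))
            fast = {r.gene_id for r in affected_genes([(chrom, start, end)], gene_index, "m")}
            qend = max(end, start + 1)
            slow = {
                g.gene_id
                for g in genes
                if g.chromosome == chrom
                and any(g.start <= p < g.end for p in range(start, qend))
            }
            assert fast == slow


class TestAlleleTable:
    def _rec(self, mid, gid, ctx="exon"):
        return DisruptionRecord(mid, gid, ctx)

    def test_three_mutants_three_alleles(self):
        table = build_allele_table([self._rec(f"m{i}", "gX") for i in range(3)])
        assert table.allele_count("gX") == 3
        assert table.histogram() == {"1": 0, "2": 0, "3": 1, ">=4": 0}

    def test_shared_deletion_region_plus_pinpoint_mutant(self):
        """Seven mutants share a 33-gene deletion block; one extra mutant
        hits only the common gene, which then outnumbers every neighbor."""
        records = []
        block = [f"g{i}" for i in range(33)]
        common = "g16"
        for m in range(7):
            for gid in block:
                records.append(self._rec(f"m{m}", gid))
        records.append(self._rec("m7", common))
        table = build_allele_table(records)
        assert table.allele_count(common) == 8
        for gid in block:
            if gid != common:
                assert table.allele_count(gid) < 8

    def test_union_arithmetic(self):
        insertion = {f"i{k}" for k in range(1404)}
        deletion = {f"i{k}" for k in range(11)} | {f"d{k}" for k in range(66)}
        assert len(deletion) == 77
        assert union_gene_count(insertion, deletion) == 1470


class TestDisruptionFrequency:
    def test_gene_hit_in_all_five_ranks_first(self):
        group = {
            f"m{i}": [DisruptionRecord(f"m{i}", "target", "exon"), DisruptionRecord(f"m{i}", f"n{i}", "intron")]
            for i in range(5)
        }
        ranked = disruption_frequency(group)
        assert ranked[0][0] == "target"
        assert ranked[0][1] == 1.0
        assert all(f == 0.2 for _, f, _ in ranked[1:])

    def test_partial_frequency(self):
        group = {f"m{i}": [DisruptionRecord(f"m{i}", "g", "exon")] for i in range(3)}
        group["m3"] = []
        group["m4"] = []
        ranked = disruption_frequency(group)
        assert ranked[0] == ("g", 0.6, SEVERITY["exon"])

    def test_tied_maxima_deterministic_order(self):
        group = {
            "m0": [DisruptionRecord("m0", "a", "exon"), DisruptionRecord("m0", "b", "exon")],
            "m1": [DisruptionRecord("m1", "b", "exon"), DisruptionRecord("m1", "a", "exon")],
        }
        ranked = disruption_frequency(group)
        assert [r[0] for r in ranked] == ["a", "b"]  # gene_id tie-break
        assert ranked[0][1] == ranked[1][1] == 1.0


def test_mutant_disruptions_severity_wins(gene_index):
    g = next(iter(gene_index.genes.values()))
    cs = make_callset("m", [make_two_sided(g.chromosome, g.start - 5, g.end + 5)])
    d = SecondaryDeletion("m", g.chromosome, g.start + 1, g.start + 2, "gapped_read", 2)
    recs = mutant_disruptions(cs, [d], gene_index)
    rec = next(r for r in recs if r.gene_id == g.gene_id)
    assert rec.context == "whole_gene_deleted"
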