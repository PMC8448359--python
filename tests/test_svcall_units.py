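"""Unit-level behavior of the discordant-pair caller: pair partitioning,
clustering thresholds, junction estimation, left/right pairing, gap
classification, mutant classification, and population redundancy."""

import pytest

from plasmap.core import AlignedPair, JunctionEstimate, MateAlignment
from plasmap.svcall import (
    Anchor,
    SvConfig,
    classify_gap,
    classify_mutant,
    cluster_discordant,
    collect_discordant_pairs,
    estimate_junction,
    find_redundant_mutants,
    is_discordant,
    pair_plasmid_sites,
)
from tests.conftest import make_callset, make_one_sided, make_site, make_two_sided

CFG = SvConfig()


def _pair(c1, s1, strand1, c2, s2, strand2, mapq=60, rid="r"):
    m1 = MateAlignment(c1, s1, s1 + 150, strand1, mapq, read_length=150)
    m2 = MateAlignment(c2, s2, s2 + 150, strand2, mapq, read_length=150)
    return AlignedPair(rid, m1, m2)


class TestDiscordance:
    def test_facing_pair_at_normal_distance_is_concordant(self):
        # mate starts 400 bp apart, facing, same contig: implied fragment 550
        assert not is_discordant(_pair("chr1", 10_000, "+", "chr1", 10_400, "-"), CFG)

    def test_implied_fragment_outside_three_sd_is_discordant(self):
        assert is_discordant(_pair("chr1", 10_000, "+", "chr1", 10_250, "-"), CFG)
        assert is_discordant(_pair("chr1", 10_000, "+", "chr1", 10_700, "-"), CFG)

    def test_plasmid_chromosome_pair_is_discordant_and_partitioned(self):
        pairs = [_pair("plasmid", 100, "+", "chr2", 5_000, "-")]
        part = collect_discordant_pairs(pairs, CFG)
        assert len(part.plasmid_paired) == 1
        assert part.plasmid_paired[0].chrom == "chr2"

    def test_same_contig_50kb_apart_is_intrachromosomal_aberrant(self):
        # 50,000 >> 600 + 3*60
        pairs = [_pair("chr1", 10_000, "+", "chr1", 60_000, "-")]
        part = collect_discordant_pairs(pairs, CFG)
        assert len(part.intrachromosomal_aberrant) == 2  # one anchor per mate

    def test_wrong_orientation_is_discordant(self):
        assert is_discordant(_pair("chr1", 10_000, "-", "chr1", 10_250, "+"), CFG)

    def test_low_mapq_plasmid_pairs_go_to_side_channel(self):
        pairs = [_pair("plasmid", 100, "+", "chr2", 5_000, "-", mapq=0)]
        part = collect_discordant_pairs(pairs, CFG)
        assert not part.plasmid_paired
        assert len(part.lowmapq_plasmid) == 1

    def test_unmapped_mate_skipped_and_counted(self):
        m1 = MateAlignment("chr1", 100, 250, "+", 60)
        m2 = MateAlignment(None, 0, 0, "+", 0)
        part = collect_discordant_pairs([AlignedPair("r", m1, m2)], CFG)
        assert part.n_skipped == 1


class TestClustering:
    def _anchor(self, start, side="left", chrom="chr1", partner="plasmid"):
        return Anchor(
            chrom=chrom,
            start=start,
            end=start + 150,
            side=side,
            partner_kind="plasmid" if partner == "plasmid" else "chromosome",
            partner_contig="" if partner == "plasmid" else partner,
        )

    def test_five_colocated_anchors_form_one_left_site(self):
        anchors = [self._anchor(10_000 + 60 * i) for i in range(5)]
        sites, filtered = cluster_discordant(anchors, CFG)
        assert len(sites) == 1 and filtered == 0
        assert sites[0].side == "left"
        assert sites[0].n_support == 5

    def test_single_supporting_pair_is_filtered_and_counted(self):
        sites, filtered = cluster_discordant([self._anchor(10_000)], CFG)
        assert sites == [] and filtered == 1

    def test_sides_cluster_separately(self):
        anchors = [self._anchor(10_000), self._anchor(10_050), self._anchor(10_020, side="right"), self._anchor(10_070, side="right")]
        sites, _ = cluster_discordant(anchors, CFG)
        assert sorted(s.side for s in sites) == ["left", "right"]

    def test_distant_clusters_split(self):
        anchors = [self._anchor(10_000), self._anchor(10_100), self._anchor(30_000), self._anchor(30_100)]
        sites, _ = cluster_discordant(anchors, CFG)
        assert len(sites) == 2


class TestJunctionEstimate:
    class _Clips:
        def __init__(self, coords):
            self.coords = coords

        def query(self, kind, contig, lo, hi):
            return [c for c in self.coords if lo <= c <= hi]

    def _site(self, innermost=10_020):
        return make_site("chr1", innermost, "left")

    def test_three_consistent_clips_give_exact_junction(self):
        est = estimate_junction(self._site(), self._Clips([10_050, 10_050, 10_050]), CFG)
        assert est == JunctionEstimate(10_050, 0, "softclip")

    def test_no_clips_fall_back_to_innermost_with_uncertainty(self):
        site = self._site(10_020)
        site.window = (9_500, 10_020)
        est = estimate_junction(site, self._Clips([]), CFG)
        # fragment 600, reads 150: residual uncertainty 600 - 2*150
        assert est.point == 10_020
        assert est.uncertainty == 300
        assert est.evidence == "discordant_only"

    def test_conflicting_clips_fall_back(self):
        est = estimate_junction(
            self._site(), self._Clips([10_050, 10_050, 10_400, 10_400]), CFG
        )
        assert est.evidence == "discordant_only"


class TestPairingAndGap:
    def test_left_and_right_sites_pair_into_deletion_candidate(self):
        l = make_site("chr1", 10_000, "left")
        r = make_site("chr1", 35_000, "right")
        events, leftovers = pair_plasmid_sites([l, r], CFG)
        assert len(events) == 1 and not leftovers
        assert events[0].gap_class == "deletion"
        assert events[0].gap_size == 25_000

    def test_lone_left_site_is_leftover(self):
        events, leftovers = pair_plasmid_sites([make_site("chr1", 10_000, "left")], CFG)
        assert events == [] and len(leftovers) == 1

    def test_tandem_insertions_do_not_cross_pair(self):
        sites = [
            make_site("chr1", 10_000, "left"),
            make_site("chr1", 10_040, "right"),
            make_site("chr1", 22_000, "left"),
            make_site("chr1", 22_100, "right"),
        ]
        events, leftovers = pair_plasmid_sites(sites, CFG)
        assert len(events) == 2 and not leftovers
        gaps = sorted(ev.gap_size for ev in events)
        assert gaps == [40, 100]

    def test_beyond_max_distance_not_paired(self):
        l = make_site("chr1", 10_000, "left")
        r = make_site("chr1", 300_000, "right")
        events, leftovers = pair_plasmid_sites([l, r], CFG)
        assert events == [] and len(leftovers) == 2

    @pytest.mark.parametrize(
        "left,right,expected_class,expected_size",
        [
            (10_000, 10_000, "perfect", 0),
            (10_000, 10_010, "deletion", 10),   # the minimal-deletion case
            (10_000, 9_993, "duplication", 7),  # negative gap = duplication
        ],
    )
    def test_gap_classification(self, left, right, expected_class, expected_size):
        lj = JunctionEstimate(left, 0, "softclip")
        rj = JunctionEstimate(right, 0, "softclip")
        assert classify_gap(lj, rj, CFG) == (expected_class, expected_size)

    def test_small_gap_with_uncertainty_is_unknown(self):
        lj = JunctionEstimate(10_000, 300, "discordant_only")
        rj = JunctionEstimate(10_010, 0, "softclip")
        assert classify_gap(lj, rj, CFG)[0] == "unknown"

    def test_large_negative_gap_flagged_unknown(self):
        lj = JunctionEstimate(10_000, 0, "softclip")
        rj = JunctionEstimate(5_000, 0, "softclip")
        assert classify_gap(lj, rj, CFG)[0] == "unknown"


class TestMutantClassification:
    def test_single_two_sided_event(self):
        cs = classify_mutant("m", [make_two_sided("chr1", 10_000, 10_100)], [])
        cs2 = make_callset("m", [make_two_sided("chr1", 10_000, 10_100)])
        assert cs.mutant_class == "simple_only" == cs2.mutant_class
        assert cs2.n_discordant_sites == 2
        assert cs2.n_lesions == 1

    def test_mix_with_complex_lesion_is_complex_containing(self):
        cs = make_callset(
            "m",
            [make_two_sided("chr1", 10_000, 10_100), make_complex_ev()],
        )
        assert cs.mutant_class == "complex_containing"

    def test_no_events_is_no_insertion_found(self):
        assert make_callset("m", []).mutant_class == "no_insertion_found"

    def test_classification_closure(self, two_sided_run):
        for cs in two_sided_run.callsets.values():
            total = sum(
                1
                for ev in cs.events
                if ev.classification in ("two_sided", "one_sided", "complex")
            )
            assert total == cs.n_insertions == len(cs.events)


def make_complex_ev():
    from tests.conftest import make_complex

    return make_complex("chr2", 50_000)


class TestRedundancy:
    def _population(self):
        callsets = []
        k = 0
        # 33 duplicated, 3 triplicated, 1 quadruplicated
        for group_size, n_groups in ((2, 33), (3, 3), (4, 1)):
            for g in range(n_groups):
                site = 10_000 + 5_000 * k
                for member in range(group_size):
                    callsets.append(
                        make_callset(
                            f"dup{k}_{member}",
                            [make_two_sided("chr1", site + member, site + member + 50)],
                        )
                    )
                k += 1
        # plus unique mutants
        for u in range(30):
            callsets.append(
                make_callset(f"uniq{u}", [make_two_sided("chr2", 10_000 + 3_000 * u, 10_050 + 3_000 * u)])
            )
        return callsets

    def test_redundant_group_arithmetic(self):
        # 33*2 + 3*3 + 1*4 = 79 mutants removed
        groups, removal = find_redundant_mutants(self._population(), tolerance_bp=10)
        sizes = sorted(len(g) for g in groups)
        assert sizes == [2] * 33 + [3] * 3 + [4]
        assert len(removal) == 79

    def test_all_unique_yields_empty_removal(self):
        callsets = [
            make_callset(f"u{i}", [make_two_sided("chr1", 10_000 + 5_000 * i, 10_100 + 5_000 * i)])
            for i in range(10)
        ]
        assert find_redundant_mutants(callsets) == ([], [])

    def test_partial_site_overlap_is_not_redundant(self):
        a = make_callset(
            "a",
            [make_two_sided("chr1", 10_000, 10_100), make_two_sided("chr2", 50_000, 50_100)],
        )
        b = make_callset("b", [make_two_sided("chr1", 10_000, 10_100)])
        assert find_redundant_mutants([a, b]) == ([], [])

    def test_one_sided_sites_participate(self):
        a = make_callset("a", [make_one_sided("chr1", 10_000, "repeat_flank")])
        b = make_callset("b", [make_one_sided("chr1", 10_004, "repeat_flank")])
        groups, removal = find_redundant_mutants([a, b])
        assert removal == ["a", "b"]
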