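"""Truth-table recovery on simulated data: recall/precision of two-sided
insertion calling, junction exactness, uncertainty calibration, coverage
monotonicity, evidence conservation, and complex-event resolution."""

import numpy as np
import pytest

from plasmap.simdata import (
    SimConfig,
    emit_alignments,
    simulate_mutant,
    simulate_reads,
)
from plasmap.svcall import SvConfig, call_mutant

EXPECTED_CLASS = {
    "two_sided_deletion": "deletion",
    "two_sided_duplication": "duplication",
    "two_sided_perfect": "perfect",
}


def _match_two_sided(truths, callsets, tol=350):
    """Greedy truth-to-call matching by left-junction proximity."""
    tp = fn = fp = 0
    matched_pairs = []
    for mid, events in truths.items():
        calls = [ev for ev in callsets[mid].events if ev.classification == "two_sided"]
        used = set()
        for t in events:
            hit = None
            for ci, c in enumerate(calls):
                if ci in used:
                    continue
                if c.chromosome == t.chromosome and c.left_site and abs(
                    c.left_site.point - t.left_breakpoint
                ) <= tol:
                    hit = ci
                    break
            if hit is None:
                fn += 1
            else:
                used.add(hit)
                tp += 1
                matched_pairs.append((t, calls[hit]))
        fp += len(calls) - len(used)
    return tp, fn, fp, matched_pairs


class TestTwoSidedRecovery:
    def test_recall_and_precision_at_study_coverage(self, two_sided_run):
        tp, fn, fp, _ = _match_two_sided(two_sided_run.truths, two_sided_run.callsets)
        total = tp + fn
        assert total >= 200
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95

    def test_softclip_evidence_recovers_gap_exactly(self, two_sided_run):
        """With soft-clip evidence at both junctions and no read errors, the
        recovered gap class and size equal truth for every event."""
        _, _, _, matched = _match_two_sided(two_sided_run.truths, two_sided_run.callsets)
        n_exact = n_clip = 0
        for t, c in matched:
            if (
                c.left_site.junction.evidence == "softclip"
                and c.right_site.junction.evidence == "softclip"
            ):
                n_clip += 1
                assert c.gap_class == EXPECTED_CLASS[t.event_class]
                assert c.left_site.point == t.left_breakpoint
                assert c.right_site.point == t.right_breakpoint
                expected_size = abs(t.gap_size)
                assert c.gap_size == expected_size
                n_exact += 1
        assert n_clip >= 150  # clip evidence is the norm at 7.44x
        assert n_exact == n_clip

    def test_junctions_recover_truth_exactly_for_most_sites(self, two_sided_run):
        """>=90% of junction estimates hit the true breakpoint exactly."""
        _, _, _, matched = _match_two_sided(two_sided_run.truths, two_sided_run.callsets)
        exact = total = 0
        for t, c in matched:
            for site, bp in ((c.left_site, t.left_breakpoint), (c.right_site, t.right_breakpoint)):
                total += 1
                exact += site.point == bp
        assert total >= 200
        assert exact / total >= 0.90

    def test_discordant_only_uncertainty_covers_truth(self, two_sided_run):
        """Where only discordant evidence exists, the truth breakpoint lies
        within the reported uncertainty interval >=99% of the time."""
        _, _, _, matched = _match_two_sided(two_sided_run.truths, two_sided_run.callsets)
        inside = total = 0
        for t, c in matched:
            for site, bp in ((c.left_site, t.left_breakpoint), (c.right_site, t.right_breakpoint)):
                j = site.junction
                if j.evidence == "discordant_only":
                    total += 1
                    inside += abs(j.point - bp) <= j.uncertainty
        if total:
            assert inside / total >= 0.99

    def test_every_plasmid_site_in_exactly_one_event(self, two_sided_run):
        """Evidence conservation: no discordant site is shared between
        events and none is silently dropped."""
        for cs in two_sided_run.callsets.values():
            seen = []
            for ev in cs.events:
                for s in ev.sites:
                    assert s not in seen
                    seen.append(s)
            for lesion in cs.lesions:
                for ev_site in lesion.sites:
                    assert ev_site in seen

    def test_deletion_size_histogram_is_bimodal(self, two_sided_run):
        from plasmap.stats_report import size_histogram

        events = [ev for cs in two_sided_run.callsets.values() for ev in cs.events]
        hist = size_histogram(events)["deletion"]
        ranked = sorted(hist, key=hist.get, reverse=True)
        assert set(ranked[:2]) == {"11-100", "10001-100000"}


class TestCoverageMonotonicity:
    @pytest.mark.parametrize("seed", [5150])
    def test_recall_nondecreasing_in_coverage(self, study_reference, mixture, seed):
        recalls = []
        rng = np.random.default_rng(seed)
        mutant_seeds = [int(rng.integers(2**31 - 1)) for _ in range(10)]
        read_seeds = [int(rng.integers(2**31 - 1)) for _ in range(10)]
        for coverage in (3.0, 7.44, 15.0):
            cfg = SimConfig(seed=1, coverage=coverage)
            sv = SvConfig()
            truths, callsets = {}, {}
            for m in range(10):
                mid = f"c{m}"
                genome, events = simulate_mutant(
                    study_reference,
                    mixture,
                    mid,
                    seed=mutant_seeds[m],
                    classes=["two_sided_deletion"] * 4,
                )
                frags = simulate_reads(genome, cfg, seed=read_seeds[m])
                pairs = emit_alignments(genome, frags, cfg)
                truths[mid] = events
                callsets[mid] = call_mutant(
                    pairs,
                    sv,
                    mid,
                    repeat_mask=study_reference.repeat_mask,
                    contig_lengths=study_reference.contig_lengths,
                )
            tp, fn, _, _ = _match_two_sided(truths, callsets)
            recalls.append(tp / (tp + fn))
        assert recalls[0] <= recalls[1] <= recalls[2]
        assert recalls[2] >= 0.95


class TestComplexResolution:
    @pytest.fixture(scope="class")
    @staticmethod
    def call_one(study_reference, mixture, study_config):
        def _run(cls, seed):
            genome, events = simulate_mutant(
                study_reference, mixture, "m", seed=seed, classes=[cls]
            )
            frags = simulate_reads(genome, study_config, seed=seed + 1)
            pairs = emit_alignments(genome, frags, study_config)
            cs = call_mutant(
                pairs,
                SvConfig(),
                "m",
                repeat_mask=study_reference.repeat_mask,
                contig_lengths=study_reference.contig_lengths,
            )
            return events, cs

        return _run

    def test_repeat_flank_one_sided(self, call_one):
        events, cs = call_one("one_sided_repeat", 101)
        assert cs.mutant_class == "simple_only"
        assert any(ev.one_sided_reason == "repeat_flank" for ev in cs.events)

    def test_unmappable_flank_one_sided(self, call_one):
        _, cs = call_one("one_sided_complex", 101)
        assert any(ev.one_sided_reason == "no_discordant_reads" for ev in cs.events)

    def test_inversion_yields_single_chromosome_complex_lesion(self, call_one):
        events, cs = call_one("complex_intra", 101)
        assert cs.mutant_class == "complex_containing"
        lesion = next(l for l in cs.lesions if l.lesion_class == "complex")
        assert lesion.chromosomes == {events[0].chromosome}

    def test_interchromosomal_lesion_spans_both_chromosomes(self, call_one):
        events, cs = call_one("complex_inter", 202)
        t = events[0]
        complex_lesions = [l for l in cs.lesions if l.lesion_class != "simple"]
        assert complex_lesions
        spanned = set().union(*(l.chromosomes for l in complex_lesions))
        assert t.chromosome in spanned and t.partner_chromosome in spanned

    def test_reciprocal_translocation_classified(self, call_one):
        events, cs = call_one("translocation", 101)
        t = events[0]
        lesion = next(l for l in cs.lesions if l.lesion_class == "translocation")
        assert lesion.chromosomes == {t.chromosome, t.partner_chromosome}
        # plasmid present at one junction of the exchange, not both
        assert sum(lesion.plasmid_at_junctions) == len(lesion.sites)

    def test_cofragment_detected_interval_overlaps_truth(self, call_one):
        events, cs = call_one("cofragment_insertion", 202)
        t = events[0]
        cof = [ev.cofragment for ev in cs.events if ev.cofragment]
        assert cof
        contig, lo, hi = cof[0]
        assert contig == t.partner_chromosome
        assert lo < t.partner_end and hi > t.partner_start

    def test_no_cofragment_without_links_or_depth(self, study_reference):
        from plasmap.svcall import detect_cofragment

        assert (
            detect_cofragment([], [], {"chr1": np.full(1000, 7)}, SvConfig()) is None
        )

    def test_cofragment_requires_depth_elevation(self, study_reference):
        from plasmap.svcall import DiscordantSite, detect_cofragment

        gg = DiscordantSite(
            mutant_id="m",
            chromosome="chr1",
            window=(50_000, 50_600),
            side="right",
            partner_kind="chromosome",
            partner_contig="chr2",
            partner_window=(80_000, 80_600),
            n_support=8,
        )
        flat = {"chr2": np.full(200_000, 7, dtype=np.int32)}
        # depth ratio ~1.05: below the 1.6x requirement
        flat["chr2"][80_000:80_600] = 8
        assert detect_cofragment([], [gg], flat, SvConfig()) is None
        elevated = {"chr2": np.full(200_000, 7, dtype=np.int32)}
        elevated["chr2"][79_500:81_200] = 14
        assert detect_cofragment([], [gg], elevated, SvConfig()) is not None


class TestNoise:
    def test_no_sites_from_eventless_mutant(self, study_reference, mixture, study_config):
        """Scattered stray discordant pairs (long-fragment tail) never
        assemble into a plasmid insertion call."""
        for seed in (1, 2, 3):
            genome, _ = simulate_mutant(study_reference, mixture, "m", seed=seed, classes=[])
            frags = simulate_reads(genome, study_config, seed=seed + 50)
            pairs = emit_alignments(genome, frags, study_config)
            cs = call_mutant(
                pairs,
                SvConfig(),
                "m",
                repeat_mask=study_reference.repeat_mask,
                contig_lengths=study_reference.contig_lengths,
            )
            assert cs.mutant_class == "no_insertion_found"
            assert cs.events == []
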