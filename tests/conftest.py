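"""Shared fixtures: small references for unit tests and two session-scoped
simulation runs (a two-sided insertion recovery run and an unassociated-
deletion run) reused by the recovery and acceptance tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest

from plasmap.core import JunctionEstimate
from plasmap.delcall import (
    DelConfig,
    call_secondary_deletions,
    partition_by_insertion,
)
from plasmap.simdata import (
    EventMixture,
    SimConfig,
    emit_alignments,
    generate_reference,
    simulate_mutant,
    simulate_reads,
)
from plasmap.svcall import (
    DiscordantSite,
    InsertionEvent,
    Lesion,
    MutantCallSet,
    SvConfig,
    call_mutant,
    compute_depth,
)

TWO_SIDED_CLASS_WEIGHTS = {
    # observed composition of two-sided insertions: 374/29/22 of 425
    "two_sided_deletion": 374,
    "two_sided_duplication": 29,
    "two_sided_perfect": 22,
}


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, n_chromosomes=3, chromosome_length=150_000, plasmid_length=6_000)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def study_config() -> SimConfig:
    """The study's sequencing geometry at the bundled genome scale."""
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def study_reference(study_config):
    return generate_reference(study_config)


@pytest.fixture(scope="session")
def mixture() -> EventMixture:
    return EventMixture()


@dataclass
class RecoveryRun:
    truths: dict[str, list]
    callsets: dict[str, MutantCallSet]
    config: SimConfig
    sv_config: SvConfig


def _draw_two_sided_classes(rng, k=4):
    names = list(TWO_SIDED_CLASS_WEIGHTS)
    w = np.array(list(TWO_SIDED_CLASS_WEIGHTS.values()), dtype=float)
    return list(rng.choice(names, size=k, p=w / w.sum()))


@pytest.fixture(scope="session")
def two_sided_run(study_config, study_reference, mixture) -> RecoveryRun:
    """52 mutants x 4 two-sided insertions = 208 events at 7.44x, no read
    errors: the main insertion-recovery experiment."""
    rng = np.random.default_rng(20210907)
    sv = SvConfig()
    truths, callsets = {}, {}
    for m in range(52):
        mid = f"T{m:03d}"
        classes = _draw_two_sided_classes(rng)
        genome, events = simulate_mutant(
            study_reference, mixture, mid, seed=int(rng.integers(2**31 - 1)), classes=classes
        )
        frags = simulate_reads(genome, study_config, seed=int(rng.integers(2**31 - 1)))
        pairs = emit_alignments(genome, frags, study_config)
        truths[mid] = events
        callsets[mid] = call_mutant(
            pairs,
            sv,
            mid,
            repeat_mask=study_reference.repeat_mask,
            contig_lengths=study_reference.contig_lengths,
        )
    return RecoveryRun(truths, callsets, study_config, sv)


@dataclass
class DeletionRun:
    truths: dict[str, list]
    unassociated: dict[str, list]
    config: SimConfig


@pytest.fixture(scope="session")
def deletion_run(study_config, study_reference, mixture) -> DeletionRun:
    """10 mutants x 10 plasmid-unassociated deletions spanning 20 bp-36 kb."""
    rng = np.random.default_rng(68)
    sv, dc = SvConfig(), DelConfig()
    truths, unassoc_calls = {}, {}
    for m in range(10):
        mid = f"D{m:03d}"
        genome, events = simulate_mutant(
            study_reference,
            mixture,
            mid,
            seed=int(rng.integers(2**31 - 1)),
            classes=["unassociated_deletion"] * 10,
        )
        frags = simulate_reads(genome, study_config, seed=int(rng.integers(2**31 - 1)))
        pairs = emit_alignments(genome, frags, study_config)
        depth = compute_depth(pairs, study_reference.contig_lengths)
        dels = call_secondary_deletions(
            pairs, sv, dc, study_reference.repeat_mask, depth=depth, mutant_id=mid
        )
        cs = call_mutant(
            pairs, sv, mid, repeat_mask=study_reference.repeat_mask, depth=depth
        )
        _, unassoc = partition_by_insertion(dels, cs)
        truths[mid] = events
        unassoc_calls[mid] = unassoc
    return DeletionRun(truths, unassoc_calls, study_config)


# ---------------------------------------------------------------------------
# Constructed call sets (no simulation) for bookkeeping/curation fixtures
# ---------------------------------------------------------------------------


def make_site(chrom: str, point: int, side: str = "left", mutant_id: str = "") -> DiscordantSite:
    return DiscordantSite(
        mutant_id=mutant_id,
        chromosome=chrom,
        window=(point - 400, point) if side == "left" else (point, point + 400),
        side=side,
        partner_kind="plasmid",
        n_support=5,
        junction=JunctionEstimate(point=point, uncertainty=0, evidence="softclip"),
    )


def make_two_sided(chrom: str, left: int, right: int, mutant_id: str = "") -> InsertionEvent:
    gap = right - left
    return InsertionEvent(
        classification="two_sided",
        chromosome=chrom,
        left_site=make_site(chrom, left, "left", mutant_id),
        right_site=make_site(chrom, right, "right", mutant_id),
        gap_class="deletion" if gap > 0 else ("duplication" if gap < 0 else "perfect"),
        gap_size=abs(gap) if gap < 0 else gap,
    )


def make_one_sided(chrom: str, point: int, reason: str, mutant_id: str = "") -> InsertionEvent:
    return InsertionEvent(
        classification="one_sided",
        chromosome=chrom,
        left_site=make_site(chrom, point, "left", mutant_id),
        one_sided_reason=reason,
    )


def make_complex(chrom: str, point: int, mutant_id: str = "") -> InsertionEvent:
    return InsertionEvent(
        classification="complex",
        chromosome=chrom,
        left_site=make_site(chrom, point, "left", mutant_id),
        one_sided_reason="paired_elsewhere",
    )


def make_callset(mutant_id: str, events: list[InsertionEvent]) -> MutantCallSet:
    lesions = []
    for ev in events:
        lclass = "complex" if ev.classification == "complex" else "simple"
        lesions.append(Lesion(lclass, sites=ev.sites))
    if not events:
        mclass = "no_insertion_found"
    elif any(l.lesion_class != "simple" for l in lesions):
        mclass = "complex_containing"
    else:
        mclass = "simple_only"
    return MutantCallSet(
        mutant_id=mutant_id,
        events=events,
        lesions=lesions,
        mutant_class=mclass,
        n_discordant_sites=sum(len(e.sites) for e in events),
        n_insertions=len(events),
        n_lesions=len(lesions),
    )
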