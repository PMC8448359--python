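"""Apply insertional-mutagenesis events to a reference and keep a lossless
segment map from mutated coordinates back to reference coordinates.

The segment map is what lets alignments be emitted from truth: every base of
a mutated chromosome traces to a reference interval (forward or inverted),
to the plasmid, or to novel sequence with no reference origin.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace

import numpy as np

from plasmap.core import IntervalMask, revcomp
from plasmap.simdata.config import EventMixture, SimConfig
from plasmap.simdata.reference import Reference

#: Flank kept clear of repeats and of other events around junctions so that
#: junction-spanning fragments map unambiguously (~ fragment + slack).
_FLANK = 1_000
_MAX_RETRIES = 200


@dataclass(slots=True)
class Segment:
    """A run of mutated sequence with a single origin.

    ``source`` is a contig name, the plasmid name, or ``'novel'``; ``strand``
    is +1 (forward) or -1 (the segment is the reverse complement of the
    reference interval). ``seq`` holds the literal sequence for novel
    segments only.
    """

    source: str
    start: int
    end: int
    strand: int = 1
    seq: str | None = None

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class TruthEvent:
    mutant_id: str
    event_class: str
    chromosome: str
    left_breakpoint: int
    right_breakpoint: int
    gap_size: int = 0
    partner_chromosome: str = ""
    partner_start: int = -1
    partner_end: int = -1

    @property
    def partner_interval(self) -> tuple[str, int, int] | None:
        if self.partner_chromosome:
            return (self.partner_chromosome, self.partner_start, self.partner_end)
        return None


class MutatedGenome:
    """Per-chromosome segment lists plus cached prefix sums and sequences."""

    def __init__(self, reference: Reference, mutant_id: str):
        self.reference = reference
        self.mutant_id = mutant_id
        self.segments: dict[str, list[Segment]] = {
            name: [Segment(name, 0, len(seq))]
            for name, seq in reference.chromosomes.items()
        }
        self.events: list[TruthEvent] = []
        self._prefix: dict[str, list[int]] = {}

    # -- structure ---------------------------------------------------------

    def chrom_length(self, chrom: str) -> int:
        return sum(len(s) for s in self.segments[chrom])

    def total_length(self) -> int:
        return sum(self.chrom_length(c) for c in self.segments)

    def _invalidate(self) -> None:
        self._prefix.clear()

    def prefix(self, chrom: str) -> list[int]:
        if chrom not in self._prefix:
            acc = [0]
            for seg in self.segments[chrom]:
                acc.append(acc[-1] + len(seg))
            self._prefix[chrom] = acc
        return self._prefix[chrom]

    def split_at(self, source_chrom: str, ref_pos: int) -> tuple[str, int]:
        """Split the forward genome segment containing reference ``ref_pos``.

        Searches every derived chromosome (a rearrangement can move a
        reference locus onto another derived molecule) and returns
        ``(derived_chrom, index)`` of the segment now beginning at
        ``ref_pos``.
        """
        for chrom, segs in self.segments.items():
            for i, seg in enumerate(segs):
                if (
                    seg.source == source_chrom
                    and seg.strand == 1
                    and seg.seq is None
                    and seg.start <= ref_pos <= seg.end
                ):
                    if ref_pos == seg.start:
                        return chrom, i
                    if ref_pos == seg.end:
                        return chrom, i + 1
                    right = Segment(seg.source, ref_pos, seg.end)
                    segs[i] = Segment(seg.source, seg.start, ref_pos)
                    segs.insert(i + 1, right)
                    self._invalidate()
                    return chrom, i + 1
        raise LookupError(f"no forward genome segment containing {source_chrom}:{ref_pos}")

    def insert(self, chrom: str, index: int, new: list[Segment]) -> None:
        self.segments[chrom][index:index] = new
        self._invalidate()

    def delete_ref_interval(self, chrom: str, start: int, end: int) -> tuple[str, int]:
        """Remove reference interval [start, end); returns (derived chrom, index)."""
        dchrom, i = self.split_at(chrom, start)
        dchrom2, j = self.split_at(chrom, end)
        if dchrom != dchrom2:  # pragma: no cover - placement forbids this
            raise LookupError("deletion interval spans derived chromosomes")
        del self.segments[dchrom][i:j]
        self._invalidate()
        return dchrom, i

    # -- sequence ----------------------------------------------------------

    def segment_sequence(self, seg: Segment) -> str:
        if seg.source == "novel":
            return seg.seq  # type: ignore[return-value]
        raw = self.reference.sequence(seg.source)[seg.start : seg.end]
        return raw if seg.strand == 1 else revcomp(raw)

    def materialize(self, chrom: str) -> str:
        return "".join(self.segment_sequence(s) for s in self.segments[chrom])

    def sequences(self) -> dict[str, str]:
        return {c: self.materialize(c) for c in self.segments}

    # -- coordinate mapping ------------------------------------------------

    def map_interval(
        self, chrom: str, mstart: int, mend: int
    ) -> list[tuple[int, int, Segment, int, int]]:
        """Map mutated interval [mstart, mend) to origin pieces.

        Yields ``(mut_s, mut_e, segment, ref_s, ref_e)`` pieces in mutated
        order; for strand -1 the reference interval runs antiparallel to the
        mutated interval.
        """
        pre = self.prefix(chrom)
        segs = self.segments[chrom]
        out = []
        i = max(0, bisect_right(pre, mstart) - 1)
        while i < len(segs) and pre[i] < mend:
            seg_ms, seg_me = pre[i], pre[i + 1]
            ov0, ov1 = max(mstart, seg_ms), min(mend, seg_me)
            if ov0 < ov1:
                o0, o1 = ov0 - seg_ms, ov1 - seg_ms
                seg = segs[i]
                if seg.strand == 1:
                    out.append((ov0, ov1, seg, seg.start + o0, seg.start + o1))
                else:
                    out.append((ov0, ov1, seg, seg.end - o1, seg.end - o0))
            i += 1
        return out


# ---------------------------------------------------------------------------
# Event drawing
# ---------------------------------------------------------------------------


def _draw_deletion_size(rng: np.random.Generator, mixture: EventMixture) -> int:
    k = rng.choice(len(mixture.deletion_weights), p=list(mixture.deletion_weights))
    lo, hi = mixture.deletion_components[k]
    size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi + 1)))))
    return max(lo, min(hi, size))


def _draw_loguniform(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


class _Placer:
    """Tracks used intervals per chromosome and rejects overlapping draws."""

    def __init__(self, reference: Reference, rng: np.random.Generator):
        self.reference = reference
        self.rng = rng
        self.used: dict[str, list[tuple[int, int]]] = {
            c: [] for c in reference.chromosomes
        }
        self.names = list(reference.chromosomes)
        self.lengths = np.array(
            [len(reference.chromosomes[c]) for c in self.names], dtype=float
        )

    def _free(self, chrom: str, start: int, end: int) -> bool:
        return all(end <= s or start >= e for s, e in self.used[chrom])

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.used[chrom].append((start, end))

    def draw_point(
        self,
        span: int = 0,
        clear_repeats: bool = True,
        chrom: str | None = None,
        not_chrom: str | None = None,
        max_repeat_overlap: float = 0.3,
    ) -> tuple[str, int]:
        """A position whose [pos-FLANK, pos+span+FLANK) window is unused and
        whose junction flanks avoid the repeat mask."""
        mask = self.reference.repeat_mask
        for _ in range(_MAX_RETRIES):
            c = chrom or str(self.rng.choice(self.names, p=self.lengths / self.lengths.sum()))
            if not_chrom is not None and c == not_chrom:
                continue
            limit = len(self.reference.chromosomes[c]) - span - _FLANK
            if limit <= _FLANK:
                continue
            pos = int(self.rng.integers(_FLANK, limit))
            lo, hi = pos - _FLANK, pos + span + _FLANK
            if not self._free(c, lo, hi):
                continue
            if clear_repeats:
                if mask.overlaps(c, pos - _FLANK, pos + 1):
                    continue
                if mask.overlaps(c, pos + span, pos + span + _FLANK):
                    continue
                if span > 0 and mask.overlap_bp(c, pos, pos + span) > max_repeat_overlap * span:
                    continue
            self.reserve(c, lo, hi)
            return c, pos
        raise RuntimeError("could not place event after bounded retries")

    def draw_repeat_edge(self) -> tuple[str, int]:
        """Insertion point at the right edge of a repeat block, so the left
        flank is unmappable while the right flank is clear."""
        candidates = []
        mask = self.reference.repeat_mask
        for c in self.names:
            for s, e in mask.intervals(c):
                if e - s >= _FLANK and e + _FLANK < len(self.reference.chromosomes[c]):
                    if not mask.overlaps(c, e, e + _FLANK) and self._free(c, s, e + _FLANK):
                        candidates.append((c, e))
        if not candidates:
            raise RuntimeError("no repeat block available for one-sided event")
        c, pos = candidates[int(self.rng.integers(len(candidates)))]
        self.reserve(c, pos - _FLANK, pos + _FLANK)
        return c, pos


# ---------------------------------------------------------------------------
# simulate_mutant
# ---------------------------------------------------------------------------


def simulate_mutant(
    reference: Reference,
    mixture: EventMixture,
    mutant_id: str,
    seed: int,
    classes: list[str] | None = None,
) -> tuple[MutatedGenome, list[TruthEvent]]:
    """Apply a drawn (or forced) set of events to the reference.

    ``classes`` overrides the stochastic class draw for constructed tests;
    the number of events then equals ``len(classes)``.
    """
    rng = np.random.default_rng(seed)
    genome = MutatedGenome(reference, mutant_id)
    if classes is None:
        n_events = 1 + int(rng.poisson(mixture.multi_event_rate))
        names, probs = mixture.prob_vector()
        classes = [str(rng.choice(names, p=probs)) for _ in range(n_events)]

    placer = _Placer(reference, rng)
    plasmid = Segment(reference.plasmid_name, 0, len(reference.plasmid))
    planned: list[TruthEvent] = []
    # Plan all events against reference coordinates first (placement with
    # bounded retries), then apply local events left-to-right and
    # rearrangements last so segment splitting stays well-defined.
    for cls in classes:
        if cls == "two_sided_deletion":
            size = _draw_deletion_size(rng, mixture)
            chrom, pos = placer.draw_point(span=size)
            planned.append(TruthEvent(mutant_id, cls, chrom, pos, pos + size, size))
        elif cls == "two_sided_duplication":
            dup = int(rng.integers(*mixture.duplication_range)) + 1
            dup = min(dup, mixture.duplication_range[1])
            chrom, pos = placer.draw_point(span=0)
            planned.append(TruthEvent(mutant_id, cls, chrom, pos, pos - dup, -dup))
        elif cls == "two_sided_perfect":
            chrom, pos = placer.draw_point()
            planned.append(TruthEvent(mutant_id, cls, chrom, pos, pos, 0))
        elif cls == "one_sided_repeat":
            chrom, pos = placer.draw_repeat_edge()
            planned.append(TruthEvent(mutant_id, cls, chrom, pos, pos, 0))
        elif cls == "one_sided_complex":
            chrom, pos = placer.draw_point()
            planned.append(TruthEvent(mutant_id, cls, chrom, pos, pos, 0))
        elif cls == "cofragment_insertion":
            chrom, pos = placer.draw_point()
            flen = int(rng.integers(*mixture.cofragment_range))
            src_chrom, src = placer.draw_point(span=flen)
            planned.append(
                TruthEvent(
                    mutant_id, cls, chrom, pos, pos, 0, src_chrom, src, src + flen
                )
            )
        elif cls == "complex_intra":
            span = int(rng.integers(*mixture.rearrangement_span))
            chrom, p1 = placer.draw_point(span=span, max_repeat_overlap=1.0)
            planned.append(TruthEvent(mutant_id, cls, chrom, p1, p1 + span, 0, chrom, p1, p1 + span))
        elif cls == "complex_inter":
            chrom, pos = placer.draw_point()
            span = int(rng.integers(*mixture.rearrangement_span))
            src_chrom, src = placer.draw_point(
                span=span, not_chrom=chrom, max_repeat_overlap=1.0
            )
            planned.append(
                TruthEvent(mutant_id, cls, chrom, pos, pos, 0, src_chrom, src, src + span)
            )
        elif cls == "translocation":
            chrom_a, pa = placer.draw_point()
            chrom_b, pb = placer.draw_point(not_chrom=chrom_a)
            planned.append(
                TruthEvent(mutant_id, cls, chrom_a, pa, pa, 0, chrom_b, pb, pb)
            )
        elif cls == "unassociated_deletion":
            lo, hi = mixture.unassociated_deletion_range
            size = _draw_loguniform(rng, lo, hi)
            size = max(lo, min(hi, size))
            chrom, pos = placer.draw_point(span=size)
            planned.append(TruthEvent(mutant_id, cls, chrom, pos, pos + size, size))
        else:
            raise ValueError(f"unknown event class: {cls}")

    local = [e for e in planned if e.event_class not in ("translocation",)]
    rearr = [e for e in planned if e.event_class == "translocation"]
    order = {c: i for i, c in enumerate(genome.segments)}
    local.sort(key=lambda e: (order[e.chromosome], e.left_breakpoint))
    for ev in local:
        _apply_local(genome, ev, plasmid, mixture, rng)
    for ev in rearr:
        _apply_translocation(genome, ev, plasmid, mixture)
    genome.events = planned
    return genome, planned


def _plasmid_segments(plasmid: Segment, mixture: EventMixture) -> list[Segment]:
    return [replace(plasmid) for _ in range(mixture.concatemer_count)]


def _apply_local(
    genome: MutatedGenome,
    ev: TruthEvent,
    plasmid: Segment,
    mixture: EventMixture,
    rng: np.random.Generator,
) -> None:
    cls = ev.event_class
    chrom = ev.chromosome
    P = _plasmid_segments(plasmid, mixture)
    if cls == "two_sided_deletion":
        d, i = genome.delete_ref_interval(chrom, ev.left_breakpoint, ev.right_breakpoint)
        genome.insert(d, i, P)
    elif cls == "two_sided_duplication":
        # Sequence [right_bp, left_bp) ends up flanking the plasmid twice.
        d, i = genome.split_at(chrom, ev.left_breakpoint)
        genome.insert(d, i, P + [Segment(chrom, ev.right_breakpoint, ev.left_breakpoint)])
    elif cls in ("two_sided_perfect", "one_sided_repeat"):
        d, i = genome.split_at(chrom, ev.left_breakpoint)
        genome.insert(d, i, P)
    elif cls == "one_sided_complex":
        # Novel, unmappable sequence trails the plasmid: the downstream
        # junction produces no mappable discordant evidence.
        nlen = int(rng.integers(*mixture.novel_flank_range))
        novel = Segment("novel", 0, nlen, seq=_random_novel(rng, nlen))
        d, i = genome.split_at(chrom, ev.left_breakpoint)
        genome.insert(d, i, P + [novel])
    elif cls == "cofragment_insertion":
        frag = Segment(ev.partner_chromosome, ev.partner_start, ev.partner_end)
        d, i = genome.split_at(chrom, ev.left_breakpoint)
        genome.insert(d, i, P + [frag])
    elif cls == "complex_intra":
        # Inversion of [left, right) with the plasmid at the left junction.
        d, i = genome.delete_ref_interval(chrom, ev.left_breakpoint, ev.right_breakpoint)
        inv = Segment(chrom, ev.left_breakpoint, ev.right_breakpoint, strand=-1)
        genome.insert(d, i, P + [inv])
    elif cls == "complex_inter":
        # Plasmid plus a large copied block from another locus.
        frag = Segment(ev.partner_chromosome, ev.partner_start, ev.partner_end)
        d, i = genome.split_at(chrom, ev.left_breakpoint)
        genome.insert(d, i, P + [frag])
    elif cls == "unassociated_deletion":
        genome.delete_ref_interval(chrom, ev.left_breakpoint, ev.right_breakpoint)
    else:  # pragma: no cover
        raise ValueError(cls)


def _apply_translocation(
    genome: MutatedGenome, ev: TruthEvent, plasmid: Segment, mixture: EventMixture
) -> None:
    """Reciprocal exchange of chromosome arms with the plasmid at one junction."""
    da, ia = genome.split_at(ev.chromosome, ev.left_breakpoint)
    db, ib = genome.split_at(ev.partner_chromosome, ev.partner_start)
    if da == db:  # pragma: no cover - second exchange landing on a chimera
        raise LookupError("translocation endpoints collapsed onto one molecule")
    head_a, tail_a = genome.segments[da][:ia], genome.segments[da][ia:]
    head_b, tail_b = genome.segments[db][:ib], genome.segments[db][ib:]
    genome.segments[da] = head_a + _plasmid_segments(plasmid, mixture) + tail_b
    genome.segments[db] = head_b + tail_a
    genome._invalidate()


def _random_novel(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def expected_length_change(events: list[TruthEvent], plasmid_length: int, mixture: EventMixture) -> int:
    """Net genome-length change implied by a truth list (conservation check)."""
    delta = 0
    pl = plasmid_length * mixture.concatemer_count
    for ev in events:
        c = ev.event_class
        if c in ("two_sided_perfect", "one_sided_repeat", "translocation"):
            delta += pl
        elif c == "two_sided_deletion":
            delta += pl - ev.gap_size
        elif c == "two_sided_duplication":
            delta += pl - ev.gap_size  # gap_size negative: duplication adds bases
        elif c == "complex_intra":
            delta += pl  # inversion is length-neutral
        elif c in ("cofragment_insertion", "complex_inter"):
            delta += pl + (ev.partner_end - ev.partner_start)
        elif c == "unassociated_deletion":
            delta -= ev.right_breakpoint - ev.left_breakpoint
        elif c == "one_sided_complex":
            delta += pl  # plus novel sequence, accounted separately
    return delta
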