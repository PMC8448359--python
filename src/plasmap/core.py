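"""Shared primitive types for alignment evidence and genomic intervals.

All coordinates are 0-based, half-open internally; 1-based inclusive
coordinates appear only at file boundaries (SAM/GFF3/TSV).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(slots=True)
class MateAlignment:
    """One mapped (or unmapped) mate of a read pair.

    ``start``/``end`` delimit the aligned reference span; ``clip_left`` and
    ``clip_right`` are soft-clip lengths in reference orientation, so a read
    running into an insertion junction from the left carries ``clip_right``
    and its aligned ``end`` sits exactly on the junction. ``gaps`` lists
    within-read deletion operations as ``(ref_pos, length)``.
    """

    contig: str | None
    start: int
    end: int
    strand: str  # '+' or '-'
    mapq: int
    clip_left: int = 0
    clip_right: int = 0
    gaps: tuple[tuple[int, int], ...] = ()
    read_length: int = 0

    @property
    def mapped(self) -> bool:
        return self.contig is not None


@dataclass(slots=True)
class AlignedPair:
    """A read pair: the atomic evidence unit for structural-variant calling."""

    read_id: str
    mate1: MateAlignment
    mate2: MateAlignment
    proper_pair: bool = False

    def mates(self) -> tuple[MateAlignment, MateAlignment]:
        return self.mate1, self.mate2


class IntervalMask:
    """Sorted, merged interval set per contig with fast overlap queries.

    Used for repeat masks; intervals are half-open.
    """

    def __init__(self, intervals: dict[str, list[tuple[int, int]]] | None = None):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        if intervals:
            for contig, ivs in intervals.items():
                self.add_many(contig, ivs)

    def add_many(self, contig: str, ivs: list[tuple[int, int]]) -> None:
        merged: list[list[int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self._starts[contig] = [s for s, _ in merged]
        self._ends[contig] = [e for _, e in merged]

    def contigs(self) -> list[str]:
        return list(self._starts)

    def intervals(self, contig: str) -> list[tuple[int, int]]:
        return list(zip(self._starts.get(contig, []), self._ends.get(contig, [])))

    def overlap_bp(self, contig: str, start: int, end: int) -> int:
        starts = self._starts.get(contig)
        if not starts:
            return 0
        ends = self._ends[contig]
        i = max(0, bisect_right(starts, start) - 1)
        total = 0
        while i < len(starts) and starts[i] < end:
            total += max(0, min(ends[i], end) - max(starts[i], start))
            i += 1
        return total

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        return self.overlap_bp(contig, start, end) > 0

    def total_bp(self, contig: str | None = None) -> int:
        contigs = [contig] if contig else list(self._starts)
        return sum(
            e - s
            for c in contigs
            for s, e in zip(self._starts.get(c, []), self._ends.get(c, []))
        )


@dataclass(slots=True)
class JunctionEstimate:
    """Breakpoint estimate for one side of an insertion.

    ``uncertainty`` is zero exactly when soft-clip evidence pinned the
    junction to a base; otherwise the innermost discordant mate boundary is
    reported with the library-geometry uncertainty.
    """

    point: int
    uncertainty: int
    evidence: str  # 'softclip' | 'discordant_only'

    def __post_init__(self) -> None:
        if (self.uncertainty == 0) != (self.evidence == "softclip"):
            raise ValueError("uncertainty must be 0 iff evidence is softclip")
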