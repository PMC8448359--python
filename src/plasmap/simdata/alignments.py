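"""Truth-derived alignment emission, SAM round-trip, and SAM ingest.

Each mate is placed at its true reference origin via the mutated genome's
segment map: reads wholly inside plasmid sequence map to the plasmid contig,
junction-spanning reads are soft-clipped exactly at the breakpoint, reads
from repeat blocks get mapping quality 0, and reads over small colinear
deletions are emitted with within-read deletion (D) operations as a real
gapped aligner would produce. Reads whose mappable portion is shorter than
a minimal anchor are recorded as unmapped.

``read_sam`` is the adapter for externally produced alignments; downstream
callers behave identically on either source.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from plasmap.core import AlignedPair, MateAlignment, revcomp
from plasmap.simdata.config import SimConfig
from plasmap.simdata.mutate import MutatedGenome
from plasmap.simdata.reads import FragmentSet, fragment_sequences
from plasmap.simdata.reference import Reference

#: Shortest mappable stretch an aligner seed could place.
MIN_ANCHOR = 20
#: Largest within-read deletion emitted as a D operation; larger gaps are
#: represented as soft-clipped split evidence, matching short-read aligners.
MAX_READ_GAP = 100


@dataclass(slots=True)
class _Chain:
    strand: int
    source: str
    mut_s: int
    mut_e: int
    pieces: list  # (mut_s, mut_e, ref_s, ref_e)

    def mapped_bp(self) -> int:
        return sum(e - s for s, e, *_ in self.pieces)


def _build_chains(pieces) -> list[_Chain]:
    chains: list[_Chain] = []
    for mut_s, mut_e, seg, ref_s, ref_e in pieces:
        if seg.source == "novel":
            continue
        piece = (mut_s, mut_e, ref_s, ref_e)
        if chains:
            c = chains[-1]
            if c.source == seg.source and c.strand == seg.strand and c.mut_e == mut_s:
                last = c.pieces[-1]
                gap = (ref_s - last[3]) if seg.strand == 1 else (last[2] - ref_e)
                if 0 <= gap <= MAX_READ_GAP:
                    c.pieces.append(piece)
                    c.mut_e = mut_e
                    continue
        chains.append(_Chain(seg.strand, seg.source, mut_s, mut_e, [piece]))
    return chains


def _trim_chain(chain: _Chain) -> None:
    """Drop sub-anchor end pieces that sit across a deletion gap."""

    def gap_between(a, b, strand):
        return (b[2] - a[3]) if strand == 1 else (a[2] - b[3])

    while len(chain.pieces) > 1:
        first, second = chain.pieces[0], chain.pieces[1]
        if first[1] - first[0] < MIN_ANCHOR and gap_between(first, second, chain.strand) > 0:
            chain.pieces.pop(0)
            chain.mut_s = chain.pieces[0][0]
            continue
        last, prev = chain.pieces[-1], chain.pieces[-2]
        if last[1] - last[0] < MIN_ANCHOR and gap_between(prev, last, chain.strand) > 0:
            chain.pieces.pop()
            chain.mut_e = chain.pieces[-1][1]
            continue
        break


def map_mate(
    genome: MutatedGenome,
    chrom: str,
    ms: int,
    me: int,
    mut_strand: str,
    reference: Reference,
) -> MateAlignment:
    """Place one mate interval of the mutated genome onto the reference."""
    pieces = genome.map_interval(chrom, ms, me)
    chains = _build_chains(pieces)
    if not chains:
        return MateAlignment(None, 0, 0, mut_strand, 0, read_length=me - ms)
    best = max(chains, key=_Chain.mapped_bp)
    _trim_chain(best)
    if best.mapped_bp() < MIN_ANCHOR:
        return MateAlignment(None, 0, 0, mut_strand, 0, read_length=me - ms)

    s = best.strand
    if s == 1:
        ref_start = best.pieces[0][2]
        ref_end = best.pieces[-1][3]
        gaps = []
        for a, b in zip(best.pieces, best.pieces[1:]):
            g = b[2] - a[3]
            if g > 0:
                gaps.append((a[3], g))
    else:
        ref_start = best.pieces[-1][2]
        ref_end = best.pieces[0][3]
        gaps = []
        for a, b in zip(best.pieces, best.pieces[1:]):
            g = a[2] - b[3]
            if g > 0:
                gaps.append((b[3], g))
        gaps.sort()

    clip_mut_left = best.mut_s - ms
    clip_mut_right = me - best.mut_e
    if s == 1:
        clip_left, clip_right = clip_mut_left, clip_mut_right
    else:
        clip_left, clip_right = clip_mut_right, clip_mut_left
    strand = mut_strand if s == 1 else ("-" if mut_strand == "+" else "+")
    mapq = 60
    if best.source in reference.chromosomes and reference.repeat_mask.overlaps(
        best.source, ref_start, ref_end
    ):
        mapq = 0
    return MateAlignment(
        contig=best.source,
        start=ref_start,
        end=ref_end,
        strand=strand,
        mapq=mapq,
        clip_left=clip_left,
        clip_right=clip_right,
        gaps=tuple(gaps),
        read_length=me - ms,
    )


def _is_proper(m1: MateAlignment, m2: MateAlignment, config: SimConfig) -> bool:
    if not (m1.mapped and m2.mapped) or m1.contig != m2.contig:
        return False
    left, right = (m1, m2) if m1.start <= m2.start else (m2, m1)
    if left.strand != "+" or right.strand != "-":
        return False
    implied = right.end - left.start
    return config.fragment_lower <= implied <= config.fragment_upper


def emit_alignments(
    genome: MutatedGenome,
    frags: FragmentSet,
    config: SimConfig,
    reference: Reference | None = None,
) -> list[AlignedPair]:
    """Emit one :class:`AlignedPair` per fragment from truth coordinates."""
    reference = reference or genome.reference
    rl = config.read_length
    pairs: list[AlignedPair] = []
    starts = frags.starts
    lengths = frags.lengths
    cidx = frags.chrom_index
    chroms = frags.chroms
    for i in range(len(frags)):
        chrom = chroms[int(cidx[i])]
        fs = int(starts[i])
        fe = fs + int(lengths[i])
        m1 = map_mate(genome, chrom, fs, min(fs + rl, fe), "+", reference)
        m2 = map_mate(genome, chrom, max(fe - rl, fs), fe, "-", reference)
        pairs.append(
            AlignedPair(
                read_id=frags.read_id(i),
                mate1=m1,
                mate2=m2,
                proper_pair=_is_proper(m1, m2, config),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# SAM round-trip
# ---------------------------------------------------------------------------


def _cigar(m: MateAlignment):
    ops = []
    if m.clip_left:
        ops.append((4, m.clip_left))
    pos = m.start
    for gpos, glen in m.gaps:
        ops.append((0, gpos - pos))
        ops.append((2, glen))
        pos = gpos + glen
    ops.append((0, m.end - pos))
    if m.clip_right:
        ops.append((4, m.clip_right))
    return ops


def write_sam(
    path,
    pairs: list[AlignedPair],
    reference: Reference,
    read_seqs: dict[str, tuple[str, str]] | None = None,
) -> None:
    """Write pairs as a coordinate-sorted-header SAM file (1-based on disk)."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": length}
                for name, length in reference.contig_lengths.items()
            ],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pair in pairs:
            seqs = read_seqs.get(pair.read_id) if read_seqs else None
            for idx, (mate, other) in enumerate(
                [(pair.mate1, pair.mate2), (pair.mate2, pair.mate1)]
            ):
                rec = pysam.AlignedSegment(header)
                rec.query_name = pair.read_id
                flag = 0x1 | (0x40 if idx == 0 else 0x80)
                if pair.proper_pair:
                    flag |= 0x2
                if not mate.mapped:
                    flag |= 0x4
                if not other.mapped:
                    flag |= 0x8
                if mate.mapped and mate.strand == "-":
                    flag |= 0x10
                if other.mapped and other.strand == "-":
                    flag |= 0x20
                rec.flag = flag
                anchor = mate if mate.mapped else other
                if anchor.mapped:
                    rec.reference_name = anchor.contig
                    rec.reference_start = anchor.start if mate.mapped else anchor.start
                    if mate.mapped:
                        rec.mapping_quality = mate.mapq
                        rec.cigartuples = _cigar(mate)
                if other.mapped:
                    rec.next_reference_name = other.contig
                    rec.next_reference_start = other.start
                if seqs is not None:
                    seq = seqs[idx]
                    if mate.mapped and mate.strand == "-":
                        # SEQ is stored in reference orientation.
                        seq = revcomp(seq)
                    rec.query_sequence = seq
                    rec.query_qualities = pysam.qualitystring_to_array(
                        "I" * len(seq)
                    )
                out.write(rec)


def read_sam(path, min_mapq_keep: int = 0) -> list[AlignedPair]:
    """Ingest an external SAM/BAM into :class:`AlignedPair` evidence units.

    Secondary and supplementary records are ignored; both primary mates are
    required (singletons are paired with an unmapped placeholder).
    """
    by_name: dict[str, dict[int, MateAlignment]] = {}
    proper: dict[str, bool] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate_no = 1 if rec.is_read2 else 0
            if rec.is_unmapped:
                m = MateAlignment(
                    None, 0, 0, "+", 0, read_length=rec.query_length or 0
                )
            else:
                clip_left = clip_right = 0
                gaps = []
                ct = rec.cigartuples or []
                if ct and ct[0][0] in (4, 5):
                    clip_left = ct[0][1]
                if len(ct) > 1 and ct[-1][0] in (4, 5):
                    clip_right = ct[-1][1]
                pos = rec.reference_start
                for op, ln in ct:
                    if op in (0, 7, 8):
                        pos += ln
                    elif op in (2, 3):
                        gaps.append((pos, ln))
                        pos += ln
                m = MateAlignment(
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    clip_left=clip_left,
                    clip_right=clip_right,
                    gaps=tuple(gaps),
                    read_length=rec.infer_read_length() or rec.query_length or 0,
                )
            slot = by_name.setdefault(rec.query_name, {})
            slot[mate_no] = m
            proper[rec.query_name] = proper.get(rec.query_name, False) or rec.is_proper_pair

    pairs = []
    for name, mates in by_name.items():
        m1 = mates.get(0) or MateAlignment(None, 0, 0, "+", 0)
        m2 = mates.get(1) or MateAlignment(None, 0, 0, "+", 0)
        pairs.append(AlignedPair(name, m1, m2, proper_pair=proper.get(name, False)))
    return pairs
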