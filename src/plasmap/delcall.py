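"""Deletion calling from gapped reads, split/clipped reads, and coverage
drops, and partitioning of calls into insertion-associated vs unassociated.

Three complementary evidence tiers cover the 20 bp - 36 kb size range:

* within-read deletion (D) operations for small deletions a gapped aligner
  spans inside one read;
* paired opposing soft-clip clusters (split-read evidence), corroborated by
  aberrant intra-chromosomal pairs or an internal coverage drop for larger
  gaps -- this covers the band too large for within-read gaps at 150 bp
  reads and too small for robust coverage runs;
* maximal low-depth runs for kilobase-scale deletions, with boundaries
  refined by soft-clips when present.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from plasmap.core import AlignedPair, IntervalMask
from plasmap.svcall import ClipIndex, MutantCallSet, SvConfig, compute_depth


@dataclass
class DelConfig:
    min_size: int = 20
    min_support: int = 2
    coord_tolerance: int = 2      # per-read gaps must agree within +-2 bp
    coverage_min_size: int = 500  # shortest coverage-drop call
    max_depth: int = 1            # tolerate stray mismapped reads
    max_mask_fraction: float = 0.5
    clip_only_max: int = 500      # clip pairs above this need corroboration
    max_size: int = 200_000
    slop: int = 1_000             # association distance to insertion lesions


@dataclass
class SecondaryDeletion:
    mutant_id: str
    chromosome: str
    start: int
    end: int
    evidence: str  # 'gapped_read' | 'coverage_drop' | 'both'
    n_support: int
    linked_to_insertion: bool = False
    affected_genes: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Gapped-read calls
# ---------------------------------------------------------------------------


def call_gap_deletions(
    pairs: list[AlignedPair],
    cfg: DelConfig,
    mutant_id: str = "",
    mapq_min: int = 20,
) -> list[SecondaryDeletion]:
    """Merge per-read deletion gaps that agree within tolerance."""
    gaps: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for pair in pairs:
        for m in pair.mates():
            if not m.mapped or m.mapq < mapq_min:
                continue
            for gpos, glen in m.gaps:
                if glen >= cfg.min_size:
                    gaps[m.contig].append((gpos, glen))
    calls = []
    for chrom, items in sorted(gaps.items()):
        items.sort()
        cluster: list[tuple[int, int]] = []
        for g in items + [(10**15, 0)]:
            if cluster and (
                abs(g[0] - cluster[0][0]) > cfg.coord_tolerance
                or abs(g[1] - cluster[0][1]) > cfg.coord_tolerance
            ):
                if len(cluster) >= cfg.min_support:
                    pos, length = _modal_pair(cluster)
                    calls.append(
                        SecondaryDeletion(
                            mutant_id, chrom, pos, pos + length, "gapped_read", len(cluster)
                        )
                    )
                cluster = []
            if g[1]:
                cluster.append(g)
    return calls


def _modal_pair(items: list[tuple[int, int]]) -> tuple[int, int]:
    counts: dict[tuple[int, int], int] = defaultdict(int)
    for it in items:
        counts[it] += 1
    return min(counts, key=lambda k: (-counts[k], k))


# ---------------------------------------------------------------------------
# Split-read (paired clip) calls
# ---------------------------------------------------------------------------


def _clip_clusters(coords: list[int], tol: int = 2) -> list[tuple[int, int]]:
    """(position, support) clusters of clip coordinates within tolerance."""
    out = []
    cluster: list[int] = []
    for c in sorted(coords) + [10**15]:
        if cluster and c - cluster[-1] > tol:
            counts: dict[int, int] = defaultdict(int)
            for x in cluster:
                counts[x] += 1
            pos = min(counts, key=lambda k: (-counts[k], k))
            out.append((pos, len(cluster)))
            cluster = []
        if c < 10**15:
            cluster.append(c)
    return out


def call_split_deletions(
    pairs: list[AlignedPair],
    sv_cfg: SvConfig,
    cfg: DelConfig,
    depth: dict[str, np.ndarray] | None = None,
    mutant_id: str = "",
) -> list[SecondaryDeletion]:
    """Pair right-clip clusters (deletion start) with downstream left-clip
    clusters (deletion end). Gaps beyond ``clip_only_max`` additionally
    require a spanning aberrant pair or an internal coverage drop."""
    clips = ClipIndex(pairs, sv_cfg)
    spanning = _aberrant_spans(pairs, sv_cfg)
    calls = []
    for chrom in sorted(set(clips.right) | set(clips.left)):
        rights = _clip_clusters(clips.right.get(chrom, []))
        lefts = _clip_clusters(clips.left.get(chrom, []))
        left_pos = [p for p, _ in lefts]
        used_left: set[int] = set()
        for p1, r_support in rights:
            i = bisect_left(left_pos, p1 + cfg.min_size)
            best = None
            while i < len(lefts):
                p2, l_support = lefts[i]
                if p2 - p1 > cfg.max_size:
                    break
                if i not in used_left:
                    best = (i, p2, l_support)
                    break
                i += 1
            if best is None:
                continue
            i, p2, l_support = best
            support = r_support + l_support
            if support < cfg.min_support:
                continue
            size = p2 - p1
            if size > cfg.clip_only_max:
                corroborated = _has_span(spanning.get(chrom, []), p1, p2) or (
                    depth is not None
                    and chrom in depth
                    and float(depth[chrom][p1:p2].mean()) <= cfg.max_depth + 0.5
                )
                if not corroborated:
                    continue
            used_left.add(i)
            calls.append(
                SecondaryDeletion(mutant_id, chrom, p1, p2, "gapped_read", support)
            )
    return calls


def _aberrant_spans(
    pairs: list[AlignedPair], sv_cfg: SvConfig
) -> dict[str, list[tuple[int, int]]]:
    """Inner spans of facing same-contig pairs with too-long implied fragments."""
    spans: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for pair in pairs:
        m1, m2 = pair.mate1, pair.mate2
        if not (m1.mapped and m2.mapped) or m1.contig != m2.contig:
            continue
        if min(m1.mapq, m2.mapq) < sv_cfg.mapq_min:
            continue
        left, right = (m1, m2) if m1.start <= m2.start else (m2, m1)
        if left.strand == "+" and right.strand == "-":
            implied = right.end - left.start
            if implied > sv_cfg.fragment_upper:
                spans[left.contig].append((left.end, right.start))
    for v in spans.values():
        v.sort()
    return spans


def _has_span(spans: list[tuple[int, int]], p1: int, p2: int) -> bool:
    i = bisect_right(spans, (p1, 10**15))
    for s, e in spans[max(0, i - 50) : i + 1]:
        if s <= p1 + 50 and e >= p2 - 50:
            return True
    return False


# ---------------------------------------------------------------------------
# Coverage-drop calls
# ---------------------------------------------------------------------------


def call_coverage_deletions(
    depth: dict[str, np.ndarray],
    repeat_mask: IntervalMask | None,
    cfg: DelConfig,
    pairs: list[AlignedPair] | None = None,
    sv_cfg: SvConfig | None = None,
    mutant_id: str = "",
) -> list[SecondaryDeletion]:
    """Maximal runs of depth <= max_depth, >= coverage_min_size long, with
    < max_mask_fraction repeat overlap; boundaries refined by soft-clips."""
    clips = ClipIndex(pairs, sv_cfg) if pairs is not None and sv_cfg is not None else None
    window = sv_cfg.window if sv_cfg is not None else 780
    plasmid = sv_cfg.plasmid_contig if sv_cfg is not None else "plasmid"
    calls = []
    for chrom, arr in sorted(depth.items()):
        if chrom == plasmid:
            continue  # absent/uncovered plasmid is not a genomic deletion
        low = arr <= cfg.max_depth
        if not low.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            s, e = int(s), int(e)
            if e - s < cfg.coverage_min_size:
                continue
            if repeat_mask is not None and repeat_mask.overlap_bp(
                chrom, s, e
            ) >= cfg.max_mask_fraction * (e - s):
                continue
            start, end, n_support = s, e, 0
            if clips is not None:
                rc = clips.query("right", chrom, s - window, s + window)
                lc = clips.query("left", chrom, e - window, e + window)
                if rc:
                    pos, n = max(
                        ((p, rc.count(p)) for p in set(rc)), key=lambda t: (t[1], -t[0])
                    )
                    start, n_support = pos, n_support + n
                if lc:
                    pos, n = max(
                        ((p, lc.count(p)) for p in set(lc)), key=lambda t: (t[1], t[0])
                    )
                    end = pos
                    n_support += n
            if end - start >= cfg.coverage_min_size:
                calls.append(
                    SecondaryDeletion(
                        mutant_id, chrom, start, end, "coverage_drop", n_support
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# Merge + orchestration
# ---------------------------------------------------------------------------


def _merge_calls(calls: list[SecondaryDeletion]) -> list[SecondaryDeletion]:
    """Collapse overlapping calls; read-evidence intervals win over
    coverage-only intervals, which then mark the merged call as 'both'."""
    calls = sorted(calls, key=lambda c: (c.chromosome, c.start, c.end))
    out: list[SecondaryDeletion] = []
    for c in calls:
        if out and c.chromosome == out[-1].chromosome and c.start < out[-1].end:
            prev = out[-1]
            if prev.evidence != c.evidence:
                prev.evidence = "both"
            if c.evidence == "gapped_read" and prev.evidence == "both":
                # prefer base-exact read evidence for boundaries
                if (prev.end - prev.start) >= (c.end - c.start):
                    prev.start, prev.end = c.start, c.end
            prev.n_support = max(prev.n_support, c.n_support)
            continue
        out.append(c)
    return out


def call_secondary_deletions(
    pairs: list[AlignedPair],
    sv_cfg: SvConfig,
    cfg: DelConfig | None = None,
    repeat_mask: IntervalMask | None = None,
    contig_lengths: dict[str, int] | None = None,
    depth: dict[str, np.ndarray] | None = None,
    mutant_id: str = "",
) -> list[SecondaryDeletion]:
    cfg = cfg or DelConfig()
    if depth is None and contig_lengths is not None:
        depth = compute_depth(pairs, contig_lengths)
    calls = call_gap_deletions(pairs, cfg, mutant_id, mapq_min=sv_cfg.mapq_min)
    calls += call_split_deletions(pairs, sv_cfg, cfg, depth, mutant_id)
    if depth is not None:
        calls += call_coverage_deletions(
            depth, repeat_mask, cfg, pairs, sv_cfg, mutant_id
        )
    return [c for c in _merge_calls(calls) if c.size >= cfg.min_size]


def partition_by_insertion(
    deletions: list[SecondaryDeletion],
    callset: MutantCallSet | None,
    slop: int = 1_000,
) -> tuple[list[SecondaryDeletion], list[SecondaryDeletion]]:
    """Split calls into (insertion_associated, unassociated).

    A deletion within ``slop`` of any insertion junction, or inside any
    lesion footprint, is insertion-associated.
    """
    points: list[tuple[str, int]] = []
    if callset is not None:
        for lesion in callset.lesions:
            points.extend(lesion.footprint_points())
        for ev in callset.events:
            points.extend(ev.junction_points)
    associated, unassociated = [], []
    for d in deletions:
        hit = any(
            c == d.chromosome and d.start - slop <= p <= d.end + slop
            for c, p in points
        )
        d.linked_to_insertion = hit
        (associated if hit else unassociated).append(d)
    return associated, unassociated
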