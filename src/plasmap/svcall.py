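"""Plasmid insertion-site calling from discordant read pairs.

The caller detects clusters of co-located discordant pairs ("discordant
sites"), refines junctions with soft-clip evidence, pairs left/right plasmid
sites into two-sided insertions, sizes the junction gap (deletion /
duplication / perfect), resolves leftover sites into one-sided insertions or
complex lesions (including reciprocal translocations and co-inserted genome
fragments), classifies each mutant as simple or complex, and flags redundant
mutants across a population.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from plasmap.core import AlignedPair, IntervalMask, JunctionEstimate, MateAlignment

logger = logging.getLogger(__name__)


@dataclass
class SvConfig:
    plasmid_contig: str = "plasmid"
    fragment_mean: int = 600
    fragment_sd: int = 60
    read_length: int = 150
    mapq_min: int = 20
    min_support: int = 2
    min_clip: int = 5
    window_bp: int | None = None  # default fragment_mean + 3*fragment_sd
    max_pair_distance: int = 200_000
    duplication_cap: int = 1_000
    cofragment_depth_ratio: float = 1.6
    cofragment_max_len: int = 10_000
    redundancy_tolerance: int = 10
    #: fraction of clip coordinates that must agree (within +-2 bp) for a
    #: soft-clip junction call; a wider spread falls back to discordant-only
    clip_consensus: float = 0.67

    @property
    def window(self) -> int:
        return self.window_bp if self.window_bp is not None else (
            self.fragment_mean + 3 * self.fragment_sd
        )

    @property
    def fragment_upper(self) -> int:
        return self.fragment_mean + 3 * self.fragment_sd

    @property
    def fragment_lower(self) -> int:
        return max(0, self.fragment_mean - 3 * self.fragment_sd)


# ---------------------------------------------------------------------------
# Evidence containers
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class Anchor:
    """Chromosomal footprint of one discordant pair on one contig."""

    chrom: str
    start: int
    end: int
    side: str  # 'left' (+ strand, junction to the right) | 'right'
    partner_kind: str  # 'plasmid' | 'chromosome'
    partner_contig: str = ""
    partner_start: int = -1
    partner_end: int = -1
    pair_id: str = ""


@dataclass
class DiscordantSite:
    mutant_id: str
    chromosome: str
    window: tuple[int, int]
    side: str
    partner_kind: str
    partner_contig: str = ""
    partner_window: tuple[int, int] | None = None
    n_support: int = 0
    junction: JunctionEstimate | None = None
    anchors: list[Anchor] = field(default_factory=list)

    @property
    def innermost(self) -> int:
        return self.window[1] if self.side == "left" else self.window[0]

    @property
    def point(self) -> int:
        return self.junction.point if self.junction else self.innermost


@dataclass
class InsertionEvent:
    classification: str  # 'two_sided' | 'one_sided' | 'complex'
    chromosome: str
    left_site: DiscordantSite | None = None
    right_site: DiscordantSite | None = None
    gap_class: str = "unknown"  # 'deletion'|'duplication'|'perfect'|'unknown'
    gap_size: int = 0
    one_sided_reason: str = "n/a"
    ambiguous_pairing: bool = False
    cofragment: tuple[str, int, int] | None = None
    lesion_index: int = -1

    @property
    def sites(self) -> list[DiscordantSite]:
        return [s for s in (self.left_site, self.right_site) if s is not None]

    @property
    def junction_points(self) -> list[tuple[str, int]]:
        return [(s.chromosome, s.point) for s in self.sites]


@dataclass
class Lesion:
    lesion_class: str  # 'simple' | 'complex' | 'translocation'
    sites: list[DiscordantSite] = field(default_factory=list)
    gg_sites: list[DiscordantSite] = field(default_factory=list)
    plasmid_at_junctions: list[bool] = field(default_factory=list)

    @property
    def chromosomes(self) -> set[str]:
        return {s.chromosome for s in self.sites} | {
            s.chromosome for s in self.gg_sites
        }

    def footprint_points(self) -> list[tuple[str, int]]:
        pts = [(s.chromosome, s.point) for s in self.sites]
        for s in self.gg_sites:
            pts.append((s.chromosome, s.innermost))
        return pts


@dataclass
class MutantCallSet:
    mutant_id: str
    events: list[InsertionEvent]
    lesions: list[Lesion]
    mutant_class: str  # 'simple_only' | 'complex_containing' | 'no_insertion_found'
    n_discordant_sites: int = 0
    n_insertions: int = 0
    n_lesions: int = 0
    n_filtered_clusters: int = 0
    n_skipped_pairs: int = 0
    secondary_deletions: list = field(default_factory=list)
    affected_genes: list = field(default_factory=list)

    def insertion_sites(self) -> list[tuple[str, int]]:
        """One representative junction per insertion event (for redundancy)."""
        out = []
        for ev in self.events:
            site = ev.left_site or ev.right_site
            if site is not None:
                out.append((site.chromosome, site.point))
        return sorted(out)


# ---------------------------------------------------------------------------
# Pair collection
# ---------------------------------------------------------------------------


@dataclass
class PartitionedPairs:
    plasmid_paired: list[Anchor] = field(default_factory=list)
    interchromosomal: list[Anchor] = field(default_factory=list)
    intrachromosomal_aberrant: list[Anchor] = field(default_factory=list)
    lowmapq_plasmid: list[Anchor] = field(default_factory=list)
    n_skipped: int = 0
    n_concordant: int = 0
    n_discordant_pairs: int = 0


def _anchor_from(mate: MateAlignment, other: MateAlignment, kind: str, pid: str) -> Anchor:
    return Anchor(
        chrom=mate.contig,
        start=mate.start,
        end=mate.end,
        side="left" if mate.strand == "+" else "right",
        partner_kind=kind,
        partner_contig=other.contig or "",
        partner_start=other.start,
        partner_end=other.end,
        pair_id=pid,
    )


def is_discordant(pair: AlignedPair, cfg: SvConfig) -> bool:
    """Different contigs, non-facing orientation, or aberrant implied fragment."""
    m1, m2 = pair.mate1, pair.mate2
    if m1.contig != m2.contig:
        return True
    left, right = (m1, m2) if m1.start <= m2.start else (m2, m1)
    if left.strand != "+" or right.strand != "-":
        return True
    implied = right.end - left.start
    return not (cfg.fragment_lower <= implied <= cfg.fragment_upper)


def collect_discordant_pairs(
    pairs: list[AlignedPair], cfg: SvConfig
) -> PartitionedPairs:
    out = PartitionedPairs()
    pl = cfg.plasmid_contig
    for pair in pairs:
        m1, m2 = pair.mate1, pair.mate2
        if not (m1.mapped and m2.mapped):
            out.n_skipped += 1
            continue
        if not is_discordant(pair, cfg):
            out.n_concordant += 1
            continue
        out.n_discordant_pairs += 1
        low = m1.mapq < cfg.mapq_min or m2.mapq < cfg.mapq_min
        if (m1.contig == pl) != (m2.contig == pl):
            chrom_mate, pl_mate = (m2, m1) if m1.contig == pl else (m1, m2)
            anchor = _anchor_from(chrom_mate, pl_mate, "plasmid", pair.read_id)
            (out.lowmapq_plasmid if low else out.plasmid_paired).append(anchor)
        elif m1.contig == pl and m2.contig == pl:
            continue  # internal plasmid structure is out of scope
        elif low:
            continue
        elif m1.contig != m2.contig:
            out.interchromosomal.append(_anchor_from(m1, m2, "chromosome", pair.read_id))
            out.interchromosomal.append(_anchor_from(m2, m1, "chromosome", pair.read_id))
        else:
            out.intrachromosomal_aberrant.append(
                _anchor_from(m1, m2, "chromosome", pair.read_id)
            )
            out.intrachromosomal_aberrant.append(
                _anchor_from(m2, m1, "chromosome", pair.read_id)
            )
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_discordant(
    anchors: list[Anchor],
    cfg: SvConfig,
    mutant_id: str = "",
    min_support: int | None = None,
) -> tuple[list[DiscordantSite], int]:
    """Single-linkage clustering of anchors within ``cfg.window`` bp, split by
    (chromosome, side, partner contig). Returns (sites, n_filtered)."""
    if min_support is None:
        min_support = cfg.min_support
    groups: dict[tuple, list[Anchor]] = defaultdict(list)
    for a in anchors:
        key = (a.chrom, a.side, a.partner_kind, a.partner_contig)
        groups[key].append(a)
    sites: list[DiscordantSite] = []
    n_filtered = 0
    for (chrom, side, kind, pcontig), members in sorted(groups.items()):
        members.sort(key=lambda a: (a.start, a.end))
        cluster: list[Anchor] = []
        max_end = -(10**12)
        for a in members + [None]:  # sentinel flush
            if a is not None and (not cluster or a.start - max_end <= cfg.window):
                cluster.append(a)
                max_end = max(max_end, a.end)
            else:
                for sub in _split_by_partner(cluster, kind, cfg):
                    if len(sub) >= min_support:
                        sites.append(_make_site(sub, mutant_id))
                    else:
                        n_filtered += 1
                if a is not None:
                    cluster = [a]
                    max_end = a.end
    return sites, n_filtered


def _split_by_partner(
    cluster: list[Anchor], kind: str, cfg: SvConfig
) -> list[list[Anchor]]:
    """Co-located anchors whose partners sit at distant loci are distinct
    sites (e.g. a rearrangement junction next to a stray long fragment)."""
    if not cluster:
        return []
    if kind != "chromosome":
        return [cluster]
    ordered = sorted(cluster, key=lambda a: a.partner_start)
    subs: list[list[Anchor]] = [[ordered[0]]]
    max_end = ordered[0].partner_end
    for a in ordered[1:]:
        if a.partner_start - max_end <= cfg.window:
            subs[-1].append(a)
        else:
            subs.append([a])
            max_end = a.partner_end
        max_end = max(max_end, a.partner_end)
    return subs


def _make_site(cluster: list[Anchor], mutant_id: str) -> DiscordantSite:
    a0 = cluster[0]
    window = (min(a.start for a in cluster), max(a.end for a in cluster))
    pwindow = None
    if a0.partner_kind == "chromosome":
        pwindow = (
            min(a.partner_start for a in cluster),
            max(a.partner_end for a in cluster),
        )
    return DiscordantSite(
        mutant_id=mutant_id,
        chromosome=a0.chrom,
        window=window,
        side=a0.side,
        partner_kind=a0.partner_kind,
        partner_contig=a0.partner_contig,
        partner_window=pwindow,
        n_support=len(cluster),
        anchors=cluster,
    )


# ---------------------------------------------------------------------------
# Junction estimation
# ---------------------------------------------------------------------------


class ClipIndex:
    """Per-contig sorted soft-clip coordinates from all confident alignments."""

    def __init__(self, pairs: list[AlignedPair], cfg: SvConfig):
        right: dict[str, list[int]] = defaultdict(list)
        left: dict[str, list[int]] = defaultdict(list)
        for pair in pairs:
            for m in pair.mates():
                if not m.mapped or m.mapq < cfg.mapq_min:
                    continue
                if m.clip_right >= cfg.min_clip:
                    right[m.contig].append(m.end)
                if m.clip_left >= cfg.min_clip:
                    left[m.contig].append(m.start)
        self.right = {c: sorted(v) for c, v in right.items()}
        self.left = {c: sorted(v) for c, v in left.items()}

    def query(self, kind: str, contig: str, lo: int, hi: int) -> list[int]:
        coords = (self.right if kind == "right" else self.left).get(contig, [])
        return coords[bisect_left(coords, lo) : bisect_right(coords, hi)]


def _modal_cluster(coords: list[int]) -> tuple[int, int]:
    """(mode coordinate, size of the +-2 bp cluster around it)."""
    best_val, best_n = coords[0], 0
    coords = sorted(coords)
    for c in coords:
        n = bisect_right(coords, c + 2) - bisect_left(coords, c - 2)
        if n > best_n:
            best_val, best_n = c, n
    window = [c for c in coords if abs(c - best_val) <= 2]
    # most frequent exact coordinate inside the cluster, lowest on ties
    counts = defaultdict(int)
    for c in window:
        counts[c] += 1
    mode = min(counts, key=lambda c: (-counts[c], c))
    return mode, len(window)


def estimate_junction(
    site: DiscordantSite, clips: ClipIndex | None, cfg: SvConfig
) -> JunctionEstimate:
    """Soft-clip refined junction when clips agree; else the innermost
    discordant mate boundary with library-geometry uncertainty."""
    inner = site.innermost
    uncertainty = max(1, cfg.fragment_mean - 2 * cfg.read_length)
    if clips is not None:
        if site.side == "left":
            coords = clips.query(
                "right", site.chromosome, site.window[1] - cfg.window, site.window[1] + cfg.window
            )
        else:
            coords = clips.query(
                "left", site.chromosome, site.window[0] - cfg.window, site.window[0] + cfg.window
            )
        if coords:
            mode, n = _modal_cluster(coords)
            if n / len(coords) >= cfg.clip_consensus:
                return JunctionEstimate(point=mode, uncertainty=0, evidence="softclip")
            logger.warning(
                "conflicting clip coordinates near %s:%s; falling back to "
                "discordant-only junction",
                site.chromosome,
                inner,
            )
    return JunctionEstimate(point=inner, uncertainty=uncertainty, evidence="discordant_only")


# ---------------------------------------------------------------------------
# Two-sided pairing and gap classification
# ---------------------------------------------------------------------------


def classify_gap(
    left: JunctionEstimate, right: JunctionEstimate, cfg: SvConfig
) -> tuple[str, int]:
    g = right.point - left.point
    combined = left.uncertainty + right.uncertainty
    if combined > 0 and abs(g) <= combined:
        return "unknown", g
    if g > 0:
        return "deletion", g
    if g < 0:
        if -g < cfg.duplication_cap:
            return "duplication", -g
        return "unknown", g  # large negative gap: flagged for review
    return "perfect", 0


def pair_plasmid_sites(
    sites: list[DiscordantSite], cfg: SvConfig
) -> tuple[list[InsertionEvent], list[DiscordantSite]]:
    """Greedy nearest left/right pairing of plasmid sites per chromosome."""
    lefts = [s for s in sites if s.side == "left"]
    rights = [s for s in sites if s.side == "right"]
    candidates = []
    for li, l in enumerate(lefts):
        for ri, r in enumerate(rights):
            if l.chromosome != r.chromosome:
                continue
            d = r.point - l.point
            if -cfg.duplication_cap < d <= cfg.max_pair_distance:
                candidates.append((abs(d), l.point, r.point, li, ri))
    candidates.sort()
    used_l: set[int] = set()
    used_r: set[int] = set()
    events = []
    for k, (dist, lp, rp, li, ri) in enumerate(candidates):
        if li in used_l or ri in used_r:
            continue
        ambiguous = any(
            c[0] == dist and (c[3] == li or c[4] == ri) and c[1:3] != (lp, rp)
            for c in candidates[max(0, k - 4) : k + 5]
        )
        used_l.add(li)
        used_r.add(ri)
        l, r = lefts[li], rights[ri]
        gap_class, gap_size = classify_gap(l.junction, r.junction, cfg)
        events.append(
            InsertionEvent(
                classification="two_sided",
                chromosome=l.chromosome,
                left_site=l,
                right_site=r,
                gap_class=gap_class,
                gap_size=gap_size,
                ambiguous_pairing=ambiguous,
            )
        )
    leftovers = [s for i, s in enumerate(lefts) if i not in used_l]
    leftovers += [s for i, s in enumerate(rights) if i not in used_r]
    return events, leftovers


# ---------------------------------------------------------------------------
# Complex resolution
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _near(a: tuple[str, int], b: tuple[str, int], window: int) -> bool:
    return a[0] == b[0] and abs(a[1] - b[1]) <= window


def detect_cofragment(
    component_plasmid: list[DiscordantSite],
    component_gg: list[DiscordantSite],
    depth: dict[str, np.ndarray] | None,
    cfg: SvConfig,
) -> tuple[str, int, int] | None:
    """Identify a co-inserted genome fragment: a short distal interval linked
    to the insertion junction whose depth is elevated (an extra copy)."""
    if depth is None or not component_gg:
        return None
    # Wide anchor/partner windows mean mates scattered over kilobases --
    # the signature of an inversion or a large duplicated block, never of a
    # short co-inserted fragment whose junction mates stay within a window.
    wide = 4 * cfg.window
    for gg in component_gg:
        if gg.window[1] - gg.window[0] > wide:
            return None
        if gg.partner_window is not None and (
            gg.partner_window[1] - gg.partner_window[0] > wide
        ):
            return None
    candidates: list[tuple[str, int, int]] = []
    for gg in component_gg:
        if gg.partner_window is not None:
            candidates.append((gg.partner_contig, *gg.partner_window))
    for contig, lo, hi in candidates:
        # absorb plasmid sites on the partner contig that flank the fragment
        for s in component_plasmid:
            if s.chromosome == contig and (
                lo - cfg.cofragment_max_len <= s.point <= hi + cfg.cofragment_max_len
            ):
                lo, hi = min(lo, s.point), max(hi, s.point)
        if hi - lo >= cfg.cofragment_max_len:
            continue
        arr = depth.get(contig)
        if arr is None or hi > len(arr):
            continue
        inner = float(arr[lo:hi].mean()) if hi > lo else 0.0
        # contig-wide median is a robust 1x baseline (events are local)
        baseline = float(np.median(arr))
        if baseline <= 0 or inner / baseline < cfg.cofragment_depth_ratio:
            continue
        ext_lo, ext_hi = _elevated_extent(arr, lo, hi, baseline, cfg)
        if ext_hi - ext_lo < cfg.cofragment_max_len:
            return (contig, ext_lo, ext_hi)
    return None


def _elevated_extent(
    arr: np.ndarray, lo: int, hi: int, baseline: float, cfg: SvConfig, bin_bp: int = 500
) -> tuple[int, int]:
    """Maximal run of elevated depth around [lo, hi).

    A true co-inserted fragment is an extra copy of a short interval, so
    depth drops back to baseline just outside it; a large duplicated block
    (a complex rearrangement) stays elevated far beyond the candidate.
    """
    threshold = baseline * (1.0 + (cfg.cofragment_depth_ratio - 1.0) / 2.4)
    ext_lo, ext_hi = lo, hi
    limit = cfg.cofragment_max_len
    while ext_lo > 0 and (hi - ext_lo) < limit + bin_bp:
        b = arr[max(0, ext_lo - bin_bp) : ext_lo]
        if len(b) == 0 or float(b.mean()) < threshold:
            break
        ext_lo = max(0, ext_lo - bin_bp)
    while ext_hi < len(arr) and (ext_hi - lo) < limit + bin_bp:
        b = arr[ext_hi : ext_hi + bin_bp]
        if len(b) == 0 or float(b.mean()) < threshold:
            break
        ext_hi = min(len(arr), ext_hi + bin_bp)
    return ext_lo, ext_hi


def resolve_complex(
    leftover_sites: list[DiscordantSite],
    gg_sites: list[DiscordantSite],
    repeat_mask: IntervalMask | None,
    lowmapq_plasmid: list[Anchor],
    depth: dict[str, np.ndarray] | None,
    cfg: SvConfig,
) -> tuple[list[InsertionEvent], list[Lesion]]:
    """Link leftover plasmid sites with genome-genome discordant clusters into
    complex lesions (following chains transitively); classify isolated
    leftovers as one-sided insertions with a diagnosed reason."""
    n = len(leftover_sites) + len(gg_sites)
    uf = _UnionFind(n)
    loci: list[list[tuple[str, int]]] = []
    for s in leftover_sites:
        loci.append([(s.chromosome, s.point)])
    for g in gg_sites:
        anchor = (g.chromosome, g.innermost)
        partner = (
            g.partner_contig,
            (g.partner_window[0] + g.partner_window[1]) // 2 if g.partner_window else 0,
        )
        loci.append([anchor, partner])
    for i in range(n):
        for j in range(i + 1, n):
            if any(
                _near(a, b, cfg.window) for a in loci[i] for b in loci[j]
            ):
                uf.union(i, j)

    components: dict[int, tuple[list[DiscordantSite], list[DiscordantSite]]] = (
        defaultdict(lambda: ([], []))
    )
    for i in range(n):
        root = uf.find(i)
        if i < len(leftover_sites):
            components[root][0].append(leftover_sites[i])
        else:
            components[root][1].append(gg_sites[i - len(leftover_sites)])

    events: list[InsertionEvent] = []
    lesions: list[Lesion] = []
    cofragment_intervals: list[tuple[str, int, int]] = []
    linked = [c for c in components.values() if c[0] and c[1]]
    isolated = [c for c in components.values() if c[0] and not c[1]]
    for plasmid_sites, gg_members in linked:
        cofragment = detect_cofragment(plasmid_sites, gg_members, depth, cfg)
        if cofragment is not None:
            ev, lesion = _cofragment_event(plasmid_sites, gg_members, cofragment, cfg)
            events.append(ev)
            lesions.append(lesion)
            cofragment_intervals.append(cofragment)
            continue
        lesion_class = "complex"
        if len(plasmid_sites) == 2:
            a, b = plasmid_sites
            if a.chromosome != b.chromosome and any(
                _near((g.chromosome, g.innermost), (a.chromosome, a.point), cfg.window)
                and g.partner_contig == b.chromosome
                or _near((g.chromosome, g.innermost), (b.chromosome, b.point), cfg.window)
                and g.partner_contig == a.chromosome
                for g in gg_members
            ):
                lesion_class = "translocation"
        for s in plasmid_sites:
            events.append(
                InsertionEvent(
                    classification="complex",
                    chromosome=s.chromosome,
                    left_site=s if s.side == "left" else None,
                    right_site=s if s.side == "right" else None,
                    one_sided_reason="paired_elsewhere",
                )
            )
        lesions.append(
            Lesion(
                lesion_class,
                sites=plasmid_sites,
                gg_sites=gg_members,
                plasmid_at_junctions=[True] * len(plasmid_sites)
                + [False] * len(gg_members),
            )
        )
    for plasmid_sites, _ in isolated:
        for s in plasmid_sites:
            if any(
                c == s.chromosome and lo - cfg.window <= s.point <= hi + cfg.window
                for c, lo, hi in cofragment_intervals
            ):
                continue  # site flanks a detected co-inserted fragment
            events.append(_one_sided(s, repeat_mask, lowmapq_plasmid, cfg))
            lesions.append(Lesion("simple", sites=[s], plasmid_at_junctions=[True]))
    return events, lesions


def _one_sided(
    site: DiscordantSite,
    repeat_mask: IntervalMask | None,
    lowmapq_plasmid: list[Anchor],
    cfg: SvConfig,
) -> InsertionEvent:
    j = site.point
    if site.side == "left":
        flank = (j, j + cfg.window)
    else:
        flank = (j - cfg.window, j)
    reason = "no_discordant_reads"
    if repeat_mask is not None and repeat_mask.overlap_bp(
        site.chromosome, *flank
    ) >= 0.5 * (flank[1] - flank[0]):
        reason = "repeat_flank"
    else:
        n_low = sum(
            1
            for a in lowmapq_plasmid
            if a.chrom == site.chromosome and flank[0] <= a.start <= flank[1]
        )
        if n_low >= cfg.min_support:
            reason = "repeat_flank"
    return InsertionEvent(
        classification="one_sided",
        chromosome=site.chromosome,
        left_site=site if site.side == "left" else None,
        right_site=site if site.side == "right" else None,
        one_sided_reason=reason,
    )


def _cofragment_event(
    plasmid_sites: list[DiscordantSite],
    gg_members: list[DiscordantSite],
    cofragment: tuple[str, int, int],
    cfg: SvConfig,
) -> tuple[InsertionEvent, Lesion]:
    contig = cofragment[0]
    # the insertion locus is the plasmid site NOT on the fragment contig,
    # or failing that the gg anchor locus
    host = [s for s in plasmid_sites if s.chromosome != contig] or plasmid_sites
    primary = host[0]
    gg_here = [g for g in gg_members if g.chromosome == primary.chromosome]
    right_site = None
    left_site = primary if primary.side == "left" else None
    if left_site is None:
        right_site = primary
    # opposite junction from the genome-genome anchor on the host chromosome
    for g in gg_here:
        if g.side != primary.side:
            if g.side == "left" and left_site is None:
                left_site = g
            elif g.side == "right" and right_site is None:
                right_site = g
    gap_class, gap_size = "unknown", 0
    if left_site is not None and right_site is not None:
        lj = left_site.junction or JunctionEstimate(left_site.innermost, 1, "discordant_only")
        rj = right_site.junction or JunctionEstimate(right_site.innermost, 1, "discordant_only")
        gap_class, gap_size = classify_gap(lj, rj, cfg)
    ev = InsertionEvent(
        classification="two_sided" if (left_site and right_site) else "one_sided",
        chromosome=primary.chromosome,
        left_site=left_site,
        right_site=right_site,
        gap_class=gap_class,
        gap_size=gap_size,
        one_sided_reason="n/a" if (left_site and right_site) else "no_discordant_reads",
        cofragment=cofragment,
    )
    lesion = Lesion(
        "simple",
        sites=plasmid_sites,
        gg_sites=gg_members,
        plasmid_at_junctions=[True] * len(plasmid_sites),
    )
    return ev, lesion


# ---------------------------------------------------------------------------
# Depth
# ---------------------------------------------------------------------------


def compute_depth(
    pairs: list[AlignedPair], contig_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Per-base aligned depth (M bases only) from primary alignments."""
    deltas = {c: np.zeros(n + 1, dtype=np.int32) for c, n in contig_lengths.items()}
    for pair in pairs:
        for m in pair.mates():
            if not m.mapped or m.contig not in deltas:
                continue
            d = deltas[m.contig]
            d[m.start] += 1
            d[m.end] -= 1
            for gpos, glen in m.gaps:
                d[gpos] -= 1
                d[gpos + glen] += 1
    return {c: np.cumsum(d[:-1]).astype(np.int32) for c, d in deltas.items()}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def classify_mutant(
    mutant_id: str,
    events: list[InsertionEvent],
    lesions: list[Lesion],
    n_filtered: int = 0,
    n_skipped: int = 0,
) -> MutantCallSet:
    if not events:
        mclass = "no_insertion_found"
    elif any(l.lesion_class in ("complex", "translocation") for l in lesions):
        mclass = "complex_containing"
    else:
        mclass = "simple_only"
    n_sites = sum(len(ev.sites) for ev in events)
    return MutantCallSet(
        mutant_id=mutant_id,
        events=events,
        lesions=lesions,
        mutant_class=mclass,
        n_discordant_sites=n_sites,
        n_insertions=len(events),
        n_lesions=len(lesions),
        n_filtered_clusters=n_filtered,
        n_skipped_pairs=n_skipped,
    )


def call_mutant(
    pairs: list[AlignedPair],
    cfg: SvConfig,
    mutant_id: str = "",
    repeat_mask: IntervalMask | None = None,
    contig_lengths: dict[str, int] | None = None,
    depth: dict[str, np.ndarray] | None = None,
) -> MutantCallSet:
    """Full insertion-calling pipeline for one mutant's alignments."""
    part = collect_discordant_pairs(pairs, cfg)
    plasmid_sites, nf1 = cluster_discordant(part.plasmid_paired, cfg, mutant_id)
    gg_anchors = part.interchromosomal + part.intrachromosomal_aberrant
    gg_sites, nf2 = cluster_discordant(gg_anchors, cfg, mutant_id)
    clips = ClipIndex(pairs, cfg)
    for s in plasmid_sites:
        s.junction = estimate_junction(s, clips, cfg)
    for s in gg_sites:
        s.junction = estimate_junction(s, clips, cfg)

    events, leftovers = pair_plasmid_sites(plasmid_sites, cfg)
    if depth is None and contig_lengths is not None:
        depth = compute_depth(pairs, contig_lengths)
    complex_events, complex_lesions = resolve_complex(
        leftovers, gg_sites, repeat_mask, part.lowmapq_plasmid, depth, cfg
    )
    lesions = [
        Lesion("simple", sites=ev.sites, plasmid_at_junctions=[True, True])
        for ev in events
    ] + complex_lesions
    all_events = events + complex_events
    for i, lesion in enumerate(lesions):
        for ev in all_events:
            if ev.lesion_index < 0 and any(s in lesion.sites for s in ev.sites):
                ev.lesion_index = i
    return classify_mutant(
        mutant_id, all_events, lesions, nf1 + nf2, part.n_skipped
    )


# ---------------------------------------------------------------------------
# Population-level redundancy
# ---------------------------------------------------------------------------


def find_redundant_mutants(
    callsets: list[MutantCallSet], tolerance_bp: int = 10
) -> tuple[list[list[str]], list[str]]:
    """Group mutants whose full insertion-site sets match within tolerance.

    All members of each multi-mutant group are listed for removal (entire
    groups are excluded, since shared sites indicate sample duplication).
    """
    sigs = [(cs.mutant_id, cs.insertion_sites()) for cs in callsets]
    n = len(sigs)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if _sites_match(sigs[i][1], sigs[j][1], tolerance_bp):
                uf.union(i, j)
    by_root: dict[int, list[str]] = defaultdict(list)
    for i in range(n):
        if sigs[i][1]:  # mutants with no insertions cannot be matched
            by_root[uf.find(i)].append(sigs[i][0])
    groups = sorted(
        (sorted(v) for v in by_root.values() if len(v) > 1), key=lambda g: g[0]
    )
    removal = sorted(m for g in groups for m in g)
    return groups, removal


def _sites_match(
    a: list[tuple[str, int]], b: list[tuple[str, int]], tol: int
) -> bool:
    if len(a) != len(b) or not a:
        return False
    return all(
        ca == cb and abs(pa - pb) <= tol for (ca, pa), (cb, pb) in zip(a, b)
    )
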