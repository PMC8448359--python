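"""Gene-model intersection: lesion footprints, disruption records with
feature context, population allele tables, and disruption-frequency ranking.

A gene counts as affected when a lesion footprint intersects its gene body
(UTRs included -- insertions in either UTR are disruptive here). Context is
the most severe overlapped feature: whole-gene deletion > exon (CDS) >
5'-UTR > 3'-UTR > intron. Point insertions strictly upstream of a gene are
not affected unless a promoter window is configured.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree

from plasmap.delcall import SecondaryDeletion
from plasmap.svcall import InsertionEvent, Lesion, MutantCallSet

SEVERITY = {
    "whole_gene_deleted": 5,
    "exon": 4,
    "five_prime_utr": 3,
    "three_prime_utr": 2,
    "intron": 1,
    "upstream_only": 0,
}


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    source_line: int = -1


@dataclass(slots=True)
class DisruptionRecord:
    mutant_id: str
    gene_id: str
    context: str
    lesion_ref: str = ""  # free-form provenance (event/deletion descriptor)

    @property
    def severity(self) -> int:
        return SEVERITY[self.context]


class GeneIndex:
    """Interval-tree lookup over gene bodies."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        self.trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in genes:
            self.trees[g.chromosome].addi(g.start, g.end, g.gene_id)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        if end <= start:  # zero-length junction point p intersects [a,b) iff a<=p<b
            end = start + 1
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (self.genes[iv.data] for iv in tree.overlap(start, end)),
            key=lambda g: (g.start, g.gene_id),
        )


def load_gene_models(gff3_path) -> list[GeneModel]:
    """Parse a GFF3 into gene models (internal 0-based half-open coords).

    Orphan sub-features are skipped with a log; malformed lines raise with a
    line number (via the underlying GFF parser).
    """
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for grec in db.features_of_type("gene"):
        g = GeneModel(
            gene_id=grec.id,
            chromosome=grec.seqid,
            strand=grec.strand,
            start=grec.start - 1,
            end=grec.end,
        )
        for ftype, bucket in (
            ("exon", g.exons),
            ("CDS", g.cds),
            ("five_prime_UTR", g.utr5),
            ("three_prime_UTR", g.utr3),
        ):
            for child in db.children(grec, featuretype=ftype):
                bucket.append((child.start - 1, child.end))
            bucket.sort()
        genes.append(g)
    return sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id))


def models_from_synthetic(syn_genes) -> list[GeneModel]:
    """Adapt simulator gene models without a file round-trip."""
    return [
        GeneModel(
            gene_id=s.gene_id,
            chromosome=s.chromosome,
            strand=s.strand,
            start=s.start,
            end=s.end,
            exons=list(s.exons),
            cds=list(s.cds),
            utr5=list(s.utr5),
            utr3=list(s.utr3),
        )
        for s in syn_genes
    ]


# ---------------------------------------------------------------------------
# Footprints
# ---------------------------------------------------------------------------


def lesion_footprint(
    obj: InsertionEvent | Lesion | SecondaryDeletion,
) -> list[tuple[str, int, int]]:
    """Genomic intervals a lesion or deletion touches.

    Two-sided deletions contribute the deleted interval plus both junction
    points; perfect insertions and duplications only junction points (a
    tandem micro-duplication deletes nothing); complex lesions all member
    junction points; secondary deletions their interval.
    """
    if isinstance(obj, SecondaryDeletion):
        return [(obj.chromosome, obj.start, obj.end)]
    if isinstance(obj, Lesion):
        return [(c, p, p) for c, p in obj.footprint_points()]
    out: list[tuple[str, int, int]] = []
    if obj.classification == "two_sided" and obj.gap_class == "deletion":
        l, r = obj.left_site.point, obj.right_site.point
        out.append((obj.chromosome, min(l, r), max(l, r)))
    else:
        out.extend((c, p, p) for c, p in obj.junction_points)
    return out


def affected_genes(
    footprints: list[tuple[str, int, int]],
    index: GeneIndex,
    mutant_id: str = "",
    lesion_ref: str = "",
    promoter_window: int = 0,
) -> list[DisruptionRecord]:
    """One record per gene touched by any footprint interval; context is the
    most severe feature overlapped across all touching footprints."""
    best: dict[str, str] = {}
    for chrom, start, end in footprints:
        qstart, qend = start, max(end, start + 1)
        for g in index.overlapping(chrom, qstart, qend):
            ctx = _context(g, start, end)
            if ctx is None:
                continue
            prev = best.get(g.gene_id)
            if prev is None or SEVERITY[ctx] > SEVERITY[prev]:
                best[g.gene_id] = ctx
        if promoter_window > 0:
            for g in _promoter_hits(index, chrom, start, end, promoter_window):
                best.setdefault(g.gene_id, "upstream_only")
    return [
        DisruptionRecord(mutant_id, gid, ctx, lesion_ref)
        for gid, ctx in sorted(best.items())
    ]


def _context(g: GeneModel, start: int, end: int) -> str | None:
    qend = max(end, start + 1)
    if start <= g.start and end >= g.end and end > start:
        return "whole_gene_deleted"
    if not (qend > g.start and start < g.end):
        return None
    if any(qend > s and start < e for s, e in g.cds):
        return "exon"
    if any(qend > s and start < e for s, e in g.utr5):
        return "five_prime_utr"
    if any(qend > s and start < e for s, e in g.utr3):
        return "three_prime_utr"
    if not g.cds and any(qend > s and start < e for s, e in g.exons):
        return "exon"
    return "intron"


def _promoter_hits(
    index: GeneIndex, chrom: str, start: int, end: int, window: int
) -> list[GeneModel]:
    qend = max(end, start + 1)
    hits = []
    tree = index.trees.get(chrom)
    if tree is None:
        return []
    for iv in tree.overlap(start - window, qend + window):
        g = index.genes[iv.data]
        prom = (g.start - window, g.start) if g.strand == "+" else (g.end, g.end + window)
        if qend > prom[0] and start < prom[1]:
            hits.append(g)
    return hits


def mutant_disruptions(
    callset: MutantCallSet,
    unassociated_deletions: list[SecondaryDeletion],
    index: GeneIndex,
    promoter_window: int = 0,
) -> list[DisruptionRecord]:
    """All disruption records for one mutant (insertions + secondary dels)."""
    records: dict[str, DisruptionRecord] = {}
    sources: list[tuple[str, list[tuple[str, int, int]]]] = []
    for i, ev in enumerate(callset.events):
        sources.append((f"event:{i}:{ev.classification}", lesion_footprint(ev)))
    for i, d in enumerate(unassociated_deletions):
        sources.append((f"deletion:{i}", lesion_footprint(d)))
    for ref, fps in sources:
        for rec in affected_genes(
            fps, index, callset.mutant_id, ref, promoter_window
        ):
            prev = records.get(rec.gene_id)
            if prev is None or rec.severity > prev.severity:
                records[rec.gene_id] = rec
    return sorted(records.values(), key=lambda r: r.gene_id)


# ---------------------------------------------------------------------------
# Population tables
# ---------------------------------------------------------------------------


@dataclass
class AlleleTable:
    alleles: dict[str, list[DisruptionRecord]] = field(default_factory=dict)

    def allele_count(self, gene_id: str) -> int:
        return len({r.mutant_id for r in self.alleles.get(gene_id, [])})

    def genes(self) -> list[str]:
        return sorted(self.alleles)

    def histogram(self) -> dict[str, int]:
        """Genes binned by allele count: 1, 2, 3, >=4."""
        bins = {"1": 0, "2": 0, "3": 0, ">=4": 0}
        for gid in self.alleles:
            n = self.allele_count(gid)
            if n >= 4:
                bins[">=4"] += 1
            elif n > 0:
                bins[str(n)] += 1
        return bins


def build_allele_table(records: list[DisruptionRecord]) -> AlleleTable:
    table: dict[str, list[DisruptionRecord]] = defaultdict(list)
    for r in records:
        table[r.gene_id].append(r)
    return AlleleTable(dict(table))


def union_gene_count(insertion_genes: set[str], deletion_genes: set[str]) -> int:
    """Total affected genes with set-union semantics."""
    return len(insertion_genes | deletion_genes)


def disruption_frequency(
    group_records: dict[str, list[DisruptionRecord]],
) -> list[tuple[str, float, int]]:
    """Rank genes by the fraction of group mutants that disrupt them.

    ``group_records`` maps mutant_id -> its disruption records. Returns
    (gene_id, frequency, max severity) sorted by descending frequency, then
    descending severity, then gene_id.
    """
    n = len(group_records)
    if n == 0:
        return []
    per_gene: dict[str, set[str]] = defaultdict(set)
    severity: dict[str, int] = defaultdict(int)
    for mid, recs in group_records.items():
        for r in recs:
            per_gene[r.gene_id].add(mid)
            severity[r.gene_id] = max(severity[r.gene_id], r.severity)
    ranked = [
        (gid, len(mids) / n, severity[gid]) for gid, mids in per_gene.items()
    ]
    ranked.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return ranked
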