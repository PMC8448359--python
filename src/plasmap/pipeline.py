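"""End-to-end orchestration: simulate -> call -> call-deletions -> annotate
-> curate -> report, with deterministic seeding and TSV outputs.

Population tables are sorted by mutant then coordinate so per-mutant work
can be reordered or parallelized without changing any output byte.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from plasmap.core import AlignedPair, IntervalMask
from plasmap.curate import (
    CandidateDecision,
    CurateConfig,
    GeneFlags,
    candidate_report,
    select_candidates,
)
from plasmap.delcall import (
    DelConfig,
    SecondaryDeletion,
    call_secondary_deletions,
    partition_by_insertion,
)
from plasmap.genemap import (
    DisruptionRecord,
    GeneIndex,
    build_allele_table,
    mutant_disruptions,
)
from plasmap.simdata import (
    EventMixture,
    SimConfig,
    emit_alignments,
    generate_reference,
    simulate_mutant,
    simulate_reads,
    write_truth,
)
from plasmap.simdata.reference import Reference, reference_to_fasta
from plasmap.stats_report import summarize_population
from plasmap.svcall import (
    MutantCallSet,
    SvConfig,
    call_mutant,
    compute_depth,
    find_redundant_mutants,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    mixture: EventMixture = field(default_factory=EventMixture)
    sv: SvConfig = field(default_factory=SvConfig)
    dels: DelConfig = field(default_factory=DelConfig)
    curate: CurateConfig = field(default_factory=CurateConfig)
    n_mutants: int = 20
    seed: int = 0
    promoter_window: int = 0
    max_failure_fraction: float = 0.2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub in (
            ("sim", SimConfig),
            ("mixture", EventMixture),
            ("sv", SvConfig),
            ("dels", DelConfig),
            ("curate", CurateConfig),
        ):
            if key in raw:
                kwargs[key] = sub(**raw[key])
        for key in ("n_mutants", "seed", "promoter_window", "max_failure_fraction"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class MutantResult:
    callset: MutantCallSet
    deletions_associated: list[SecondaryDeletion]
    deletions_unassociated: list[SecondaryDeletion]
    disruptions: list[DisruptionRecord]


@dataclass
class PopulationResult:
    mutants: dict[str, MutantResult]
    redundancy_groups: list[list[str]]
    removed: list[str]
    allele_table: object
    decisions: dict[str, CandidateDecision]
    flags: dict[str, GeneFlags]
    summary: dict

    def analyzed(self) -> dict[str, MutantResult]:
        removed = set(self.removed)
        return {m: r for m, r in self.mutants.items() if m not in removed}


def run_mutant(
    pairs: list[AlignedPair],
    mutant_id: str,
    cfg: PipelineConfig,
    gene_index: GeneIndex | None = None,
    repeat_mask: IntervalMask | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> MutantResult:
    """Insertion calling, secondary deletions, and gene annotation for one
    mutant's alignments."""
    if contig_lengths is not None and cfg.sv.plasmid_contig not in contig_lengths:
        raise ValueError(
            f"plasmid contig '{cfg.sv.plasmid_contig}' absent from alignments "
            f"for {mutant_id}; set sv.plasmid_contig to the plasmid's name"
        )
    depth = compute_depth(pairs, contig_lengths) if contig_lengths else None
    callset = call_mutant(
        pairs,
        cfg.sv,
        mutant_id,
        repeat_mask=repeat_mask,
        contig_lengths=contig_lengths,
        depth=depth,
    )
    dels = call_secondary_deletions(
        pairs,
        cfg.sv,
        cfg.dels,
        repeat_mask,
        contig_lengths=contig_lengths,
        depth=depth,
        mutant_id=mutant_id,
    )
    assoc, unassoc = partition_by_insertion(dels, callset, cfg.dels.slop)
    records: list[DisruptionRecord] = []
    if gene_index is not None:
        records = mutant_disruptions(
            callset, unassoc, gene_index, cfg.promoter_window
        )
        callset.affected_genes = [r.gene_id for r in records]
    callset.secondary_deletions = unassoc
    return MutantResult(callset, assoc, unassoc, records)


def run_population(
    per_mutant_pairs: dict[str, list[AlignedPair]],
    cfg: PipelineConfig,
    gene_index: GeneIndex | None = None,
    repeat_mask: IntervalMask | None = None,
    contig_lengths: dict[str, int] | None = None,
    flags: dict[str, GeneFlags] | None = None,
) -> PopulationResult:
    """Call every mutant, remove redundant ones, and build population tables."""
    if not per_mutant_pairs:
        raise ValueError("no mutant alignment sets provided")
    results: dict[str, MutantResult] = {}
    failures: list[str] = []
    for mid in sorted(per_mutant_pairs):
        try:
            results[mid] = run_mutant(
                per_mutant_pairs[mid], mid, cfg, gene_index, repeat_mask, contig_lengths
            )
        except Exception:
            logger.exception("mutant %s failed", mid)
            failures.append(mid)
    if failures and len(failures) > cfg.max_failure_fraction * len(per_mutant_pairs):
        raise RuntimeError(f"too many mutant failures: {failures}")

    groups, removed = find_redundant_mutants(
        [r.callset for r in results.values()], cfg.sv.redundancy_tolerance
    )
    removed_set = set(removed)
    kept = {m: r for m, r in results.items() if m not in removed_set}

    all_records = [rec for r in kept.values() for rec in r.disruptions]
    allele_table = build_allele_table(all_records)
    flags = flags or {}
    decisions = select_candidates(
        {m: r.callset for m in sorted(kept) for r in [kept[m]]},
        {m: r.disruptions for m, r in kept.items()},
        flags,
        cfg.curate,
    )
    summary = summarize_population(
        [r.callset for r in kept.values()], n_redundant_removed=len(removed)
    )
    return PopulationResult(
        mutants=results,
        redundancy_groups=groups,
        removed=removed,
        allele_table=allele_table,
        decisions=decisions,
        flags=flags,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# Simulation front-end
# ---------------------------------------------------------------------------


def simulate_population(
    cfg: PipelineConfig,
    out_dir: Path | None = None,
    classes_per_mutant: dict[str, list[str]] | None = None,
):
    """Reference, mutant genomes, truth tables, and truth-derived alignments
    for ``cfg.n_mutants`` mutants; deterministic in ``cfg.seed``.

    Returns (reference, per-mutant AlignedPair lists, per-mutant truth).
    """
    sim = cfg.sim
    reference = generate_reference(sim)
    rng = np.random.default_rng(cfg.seed)
    per_mutant: dict[str, list[AlignedPair]] = {}
    truths = {}
    ids = [f"M{i:04d}" for i in range(cfg.n_mutants)]
    for mid in ids:
        ev_seed, read_seed = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
        classes = classes_per_mutant.get(mid) if classes_per_mutant else None
        genome, events = simulate_mutant(
            reference, cfg.mixture, mid, ev_seed, classes=classes
        )
        frags = simulate_reads(genome, sim, read_seed)
        per_mutant[mid] = emit_alignments(genome, frags, sim)
        truths[mid] = events
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            write_truth(events, out_dir / f"{mid}.truth.tsv")
    if out_dir is not None:
        reference_to_fasta(reference, out_dir / "reference.fasta")
    return reference, per_mutant, truths


# ---------------------------------------------------------------------------
# TSV writers (S1/S2/S3/S4-style tables)
# ---------------------------------------------------------------------------


def _write_tsv(path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def write_events_table(result: PopulationResult, path) -> None:
    """Per-discordant-site table: coordinates are 1-based on disk."""
    header = [
        "mutant",
        "discordant_site",
        "sides_paired_with_plasmid",
        "paired_with_other_site",
        "classification",
        "gap_class",
        "gap_size",
        "one_sided_reason",
        "n_discordant_sites_for_mutant",
        "n_lesions_for_mutant",
        "mutant_class",
    ]
    rows = []
    for mid in sorted(result.mutants):
        cs = result.mutants[mid].callset
        for ev in cs.events:
            for site in ev.sites:
                rows.append(
                    [
                        mid,
                        f"{site.chromosome}:{site.point + 1}",
                        2 if ev.classification == "two_sided" else 1,
                        "yes" if ev.classification in ("two_sided", "complex") else "no",
                        ev.classification,
                        ev.gap_class if ev.classification == "two_sided" else "",
                        ev.gap_size if ev.classification == "two_sided" else "",
                        ev.one_sided_reason,
                        cs.n_discordant_sites,
                        cs.n_lesions,
                        cs.mutant_class,
                    ]
                )
    _write_tsv(path, header, rows)


def write_deletions_table(result: PopulationResult, path) -> None:
    header = ["mutant", "chromosome", "start", "end", "size", "evidence", "n_support", "affected_genes"]
    rows = []
    for mid in sorted(result.mutants):
        r = result.mutants[mid]
        gene_by_ref = {}
        for rec in r.disruptions:
            gene_by_ref.setdefault(rec.lesion_ref, []).append(rec.gene_id)
        for i, d in enumerate(r.deletions_unassociated):
            rows.append(
                [
                    mid,
                    d.chromosome,
                    d.start + 1,
                    d.end,
                    d.size,
                    d.evidence,
                    d.n_support,
                    ",".join(gene_by_ref.get(f"deletion:{i}", [])),
                ]
            )
    _write_tsv(path, header, rows)


def write_genes_table(result: PopulationResult, path) -> None:
    header = ["mutant", "gene_id", "context", "source"]
    rows = [
        [mid, rec.gene_id, rec.context, rec.lesion_ref]
        for mid in sorted(result.analyzed())
        for rec in result.mutants[mid].disruptions
    ]
    _write_tsv(path, header, rows)


def write_candidates_table(result: PopulationResult, path, annotation=None) -> None:
    rows = candidate_report(result.decisions, result.flags, annotation)
    header = [
        "gene_id",
        "description",
        "greencut2",
        "crosslib",
        "keyword",
        "coexpression",
        "multiple",
        "mutants",
    ]
    _write_tsv(path, header, [[r[h] for h in header] for r in rows])


def write_summary(result: PopulationResult, path) -> None:
    _write_tsv(path, ["metric", "value"], [[k, v] for k, v in result.summary.items()])


def write_manifest(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, default=str)
        fh.write("\n")


def write_all_tables(result: PopulationResult, cfg: PipelineConfig, out_dir: Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "events.tsv": write_events_table,
        "secondary_deletions.tsv": write_deletions_table,
        "affected_genes.tsv": write_genes_table,
        "candidates.tsv": write_candidates_table,
        "summary.tsv": write_summary,
    }
    written = []
    for name, writer in paths.items():
        p = out_dir / name
        writer(result, p)
        written.append(p)
    _write_tsv(
        out_dir / "redundant_mutants.tsv",
        ["group", "mutant"],
        [[i + 1, m] for i, grp in enumerate(result.redundancy_groups) for m in grp],
    )
    written.append(out_dir / "redundant_mutants.tsv")
    write_manifest(cfg, out_dir / "manifest.json")
    written.append(out_dir / "manifest.json")
    return written
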