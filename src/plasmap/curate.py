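"""Rule-based selection of higher-confidence candidate genes.

The selection codifies the curation logic of a forward-genetics screen as a
deterministic, auditable procedure:

R1  a simple mutant disrupting exactly one gene -> that gene;
R2  a mutant in a group with overlapping disrupted genes -> the gene with
    the uniquely highest disruption frequency (complex mutants may join
    such groups -- a single shared gene across many overlapping deletions
    is strong evidence even in a rearranged background);
R3  multiple disrupted genes -> rank by evidence flags (conserved-green-
    lineage membership weighs 2; photosynthesis keyword, co-expression and
    each cross-library hit weigh 1); a unique maximum wins;
R4  a tie at the maximum -> all tied genes reported as multiple candidates;
R5  otherwise no candidate.

After all mutants are decided, genes co-disrupted alongside any R1/R2
winner are demoted population-wide and decisions are re-evaluated once.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field

from plasmap.genemap import DisruptionRecord, disruption_frequency
from plasmap.svcall import MutantCallSet


@dataclass
class GeneFlags:
    gene_id: str
    greencut2: bool = False
    coexpression_hit: bool = False
    keyword_hit: bool = False
    crosslib_hits: frozenset[str] = frozenset()  # subset of {'Cr','Zm','At'}

    def score(self, weights: "CurateConfig") -> int:
        return (
            weights.greencut_weight * self.greencut2
            + weights.keyword_weight * self.keyword_hit
            + weights.coexpression_weight * self.coexpression_hit
            + weights.crosslib_weight * len(self.crosslib_hits)
        )


@dataclass
class CurateConfig:
    greencut_weight: int = 2
    keyword_weight: int = 1
    coexpression_weight: int = 1
    crosslib_weight: int = 1
    keywords: tuple[str, ...] = (
        "redox",
        "chlorophyll a/b-binding",
        "Fe-S",
        "iron-sulfur",
        "photosystem",
        "thylakoid",
    )


@dataclass
class CandidateDecision:
    mutant_id: str
    candidates: list[str]
    basis: str  # single_gene_simple | frequency_winner | flag_winner | multiple_candidates | none
    demoted_neighbors: list[str] = field(default_factory=list)
    audit: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Flags
# ---------------------------------------------------------------------------


def _read_gene_column(path) -> list[dict]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "gene_id" not in reader.fieldnames:
            raise ValueError(f"{path}: missing required 'gene_id' column")
        return list(reader)


def flag_genes(
    gene_ids: list[str],
    config: CurateConfig | None = None,
    annotation: dict[str, str] | None = None,
    greencut_ids: set[str] | None = None,
    coexpression_ids: set[str] | None = None,
    crosslib: dict[str, set[str]] | None = None,
) -> dict[str, GeneFlags]:
    """One GeneFlags per gene; genes absent from every list get all-false."""
    config = config or CurateConfig()
    annotation = annotation or {}
    greencut_ids = greencut_ids or set()
    coexpression_ids = coexpression_ids or set()
    crosslib = crosslib or {}
    keywords = [k.lower() for k in config.keywords]
    out = {}
    for gid in gene_ids:
        desc = annotation.get(gid, "").lower()
        out[gid] = GeneFlags(
            gene_id=gid,
            greencut2=gid in greencut_ids,
            coexpression_hit=gid in coexpression_ids,
            keyword_hit=any(k in desc for k in keywords),
            crosslib_hits=frozenset(crosslib.get(gid, set())),
        )
    return out


def flags_from_tsv(
    gene_ids: list[str],
    config: CurateConfig | None = None,
    annotation_tsv=None,
    greencut_tsv=None,
    coexpression_tsv=None,
    crosslib_tsv=None,
) -> dict[str, GeneFlags]:
    """File-based entry point: membership lists are TSVs with a ``gene_id``
    column (crosslib rows also carry a ``library`` column: Cr/Zm/At)."""
    annotation = {}
    if annotation_tsv:
        for row in _read_gene_column(annotation_tsv):
            annotation[row["gene_id"]] = row.get("description", "")
    greencut = {r["gene_id"] for r in _read_gene_column(greencut_tsv)} if greencut_tsv else set()
    coexp = {r["gene_id"] for r in _read_gene_column(coexpression_tsv)} if coexpression_tsv else set()
    crosslib: dict[str, set[str]] = defaultdict(set)
    if crosslib_tsv:
        for row in _read_gene_column(crosslib_tsv):
            crosslib[row["gene_id"]].add(row.get("library", "Cr"))
    return flag_genes(
        gene_ids,
        config,
        annotation,
        greencut_ids=greencut,
        coexpression_ids=coexp,
        crosslib=dict(crosslib),
    )


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------


def _overlap_groups(
    disruptions: dict[str, list[DisruptionRecord]],
) -> list[set[str]]:
    """Connected components of mutants sharing at least one disrupted gene."""
    gene_to_mutants: dict[str, set[str]] = defaultdict(set)
    for mid, recs in disruptions.items():
        for r in recs:
            gene_to_mutants[r.gene_id].add(mid)
    uf: dict[str, str] = {m: m for m in disruptions}

    def find(x: str) -> str:
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    for mids in gene_to_mutants.values():
        mids = sorted(mids)
        for other in mids[1:]:
            ra, rb = find(mids[0]), find(other)
            if ra != rb:
                uf[rb] = ra
    groups: dict[str, set[str]] = defaultdict(set)
    for m in disruptions:
        groups[find(m)].add(m)
    return [g for g in groups.values() if len(g) > 1]


def _decide_one(
    mid: str,
    callset: MutantCallSet,
    recs: list[DisruptionRecord],
    group: set[str] | None,
    disruptions: dict[str, list[DisruptionRecord]],
    flags: dict[str, GeneFlags],
    config: CurateConfig,
    demoted: set[str],
) -> CandidateDecision:
    audit: list[str] = []
    all_genes = sorted({r.gene_id for r in recs})
    genes = sorted(set(all_genes) - demoted)
    simple = callset.mutant_class == "simple_only"
    if not genes:
        audit.append("R5: no (non-demoted) disrupted genes")
        return CandidateDecision(mid, [], "none", audit=audit)
    if simple and len(all_genes) == 1:
        audit.append(f"R1: simple mutant, single gene {genes[0]}")
        return CandidateDecision(mid, [genes[0]], "single_gene_simple", audit=audit)
    if group is not None:
        ranked = disruption_frequency({m: disruptions[m] for m in sorted(group)})
        ranked = [r for r in ranked if r[0] not in demoted]
        if ranked:
            top = [r for r in ranked if r[1] == ranked[0][1]]
            if len(top) == 1 and top[0][0] in genes:
                audit.append(
                    f"R2: frequency winner {top[0][0]} at {top[0][1]:.2f} "
                    f"in group of {len(group)}"
                )
                return CandidateDecision(mid, [top[0][0]], "frequency_winner", audit=audit)
            audit.append(f"R2: no unique frequency maximum ({len(top)} tied)")
    if not simple:
        audit.append("R5: complex mutant outside a resolving group")
        return CandidateDecision(mid, [], "none", audit=audit)
    scored = [(flags.get(g, GeneFlags(g)).score(config), g) for g in genes]
    best = max(s for s, _ in scored)
    winners = sorted(g for s, g in scored if s == best)
    if best > 0 and len(winners) == 1:
        audit.append(f"R3: flag winner {winners[0]} score {best}")
        return CandidateDecision(mid, winners, "flag_winner", audit=audit)
    if best > 0:
        audit.append(f"R4: {len(winners)} genes tied at flag score {best}")
        return CandidateDecision(mid, winners, "multiple_candidates", audit=audit)
    audit.append("R5: multiple genes, no distinguishing evidence")
    return CandidateDecision(mid, [], "none", audit=audit)


def select_candidates(
    callsets: dict[str, MutantCallSet],
    disruptions: dict[str, list[DisruptionRecord]],
    flags: dict[str, GeneFlags],
    config: CurateConfig | None = None,
) -> dict[str, CandidateDecision]:
    """Deterministic candidate decisions with one demotion re-pass.

    Iteration order never affects the result: mutants are processed in
    sorted order and demotion is applied population-wide between passes.
    """
    config = config or CurateConfig()
    mids = sorted(callsets)
    groups = _overlap_groups({m: disruptions.get(m, []) for m in mids})
    group_of: dict[str, set[str]] = {}
    for grp in groups:
        for m in grp:
            group_of[m] = grp

    def run(demoted: set[str]) -> dict[str, CandidateDecision]:
        return {
            m: _decide_one(
                m,
                callsets[m],
                disruptions.get(m, []),
                group_of.get(m),
                disruptions,
                flags,
                config,
                demoted,
            )
            for m in mids
        }

    first = run(set())
    demoted: set[str] = set()
    for m, dec in first.items():
        if dec.basis in ("single_gene_simple", "frequency_winner"):
            winner = dec.candidates[0]
            neighbors = {r.gene_id for r in disruptions.get(m, [])} - {winner}
            if m in group_of:
                for gm in group_of[m]:
                    neighbors |= {r.gene_id for r in disruptions.get(gm, [])}
                winners_in_group = {
                    first[gm].candidates[0]
                    for gm in group_of[m]
                    if first[gm].basis in ("single_gene_simple", "frequency_winner")
                    and first[gm].candidates
                }
                neighbors -= winners_in_group
            demoted |= neighbors
    # winners of the first pass are never demoted by their own neighbors
    protected = {
        dec.candidates[0]
        for dec in first.values()
        if dec.basis in ("single_gene_simple", "frequency_winner") and dec.candidates
    }
    demoted -= protected
    final = run(demoted)
    for m, dec in final.items():
        hit = sorted(
            {r.gene_id for r in disruptions.get(m, [])} & demoted
        )
        dec.demoted_neighbors = hit
        if demoted:
            dec.audit.append(f"demotion pass removed {len(hit)} neighbor gene(s)")
    return final


def candidate_report(
    decisions: dict[str, CandidateDecision],
    flags: dict[str, GeneFlags],
    annotation: dict[str, str] | None = None,
) -> list[dict]:
    """One row per candidate gene with flag letters, a multiple-candidate
    marker, and the supporting mutants."""
    annotation = annotation or {}
    per_gene: dict[str, dict] = {}
    for mid in sorted(decisions):
        dec = decisions[mid]
        for gid in dec.candidates:
            row = per_gene.setdefault(
                gid,
                {
                    "gene_id": gid,
                    "description": annotation.get(gid, ""),
                    "greencut2": "G" if flags.get(gid, GeneFlags(gid)).greencut2 else "",
                    "crosslib": "".join(
                        sorted(flags.get(gid, GeneFlags(gid)).crosslib_hits)
                    ),
                    "keyword": "K" if flags.get(gid, GeneFlags(gid)).keyword_hit else "",
                    "coexpression": "C"
                    if flags.get(gid, GeneFlags(gid)).coexpression_hit
                    else "",
                    "multiple": "",
                    "mutants": [],
                },
            )
            row["mutants"].append(mid)
            if dec.basis == "multiple_candidates":
                row["multiple"] = "M"
    rows = list(per_gene.values())
    for r in rows:
        r["mutants"] = ",".join(r["mutants"])
    return sorted(rows, key=lambda r: r["gene_id"])
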