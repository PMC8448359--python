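"""Population summaries and closed-form screen statistics.

Includes the Poisson saturation estimate for an insertional library (the
probability that a library of n insertions hits a gene with exonic target
L in a genome of size G is 1 - exp(-nL/G)), the tetrad-based linkage
resolution bound, hypergeometric candidate-set overlap significance, and
the binned size histograms used to describe junction deletions and
duplications.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
from scipy import stats as sps

from plasmap.svcall import InsertionEvent, MutantCallSet


@dataclass
class SaturationParams:
    n_insertions: int
    exon_len_per_gene: int = 1_583
    genome_size: int = 111_000_000

    def __post_init__(self) -> None:
        if self.n_insertions < 0 or self.exon_len_per_gene <= 0 or self.genome_size <= 0:
            raise ValueError("saturation parameters must be positive")


@dataclass
class LinkageParams:
    n_zygospores: int
    resistant_progeny_per_zygospore: int = 2
    n_recombinants: int = 0
    kb_per_cM: float = 100.0

    def __post_init__(self) -> None:
        if self.n_zygospores < 0 or self.n_recombinants < 0:
            raise ValueError("counts must be non-negative")
        total = self.n_zygospores * self.resistant_progeny_per_zygospore
        if self.n_recombinants > total:
            raise ValueError("more recombinants than tested progeny")


def poisson_hit_probability(params: SaturationParams) -> float:
    """P(gene hit at least once) = 1 - exp(-n*L/G)."""
    lam = params.n_insertions * params.exon_len_per_gene / params.genome_size
    return 1.0 - float(np.exp(-lam))


def saturation_percent(params: SaturationParams) -> int:
    """Hit probability as an integer percent.

    The rate is quoted to 0.1% and then rounded to the nearest percent
    (half-even), the convention used when reporting a probability like
    0.575 as "58%".
    """
    pct = Decimal(poisson_hit_probability(params) * 100)
    tenth = pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN)
    return int(tenth.quantize(Decimal("1"), rounding=ROUND_HALF_EVEN))


def linkage_resolution(params: LinkageParams) -> tuple[float, float]:
    """(cM bound or estimate, kb equivalent).

    With zero recombinants among 2n selected progeny the recombination
    frequency is bounded below 1/(2n); with r recombinants the point
    estimate is r/(2n). Expressed in cM (x100) and kb via kb_per_cM.
    """
    total = params.n_zygospores * params.resistant_progeny_per_zygospore
    if total == 0:
        raise ValueError("no tested progeny")
    if params.n_recombinants == 0:
        cm = 100.0 / total
    else:
        cm = 100.0 * params.n_recombinants / total
    return cm, cm * params.kb_per_cM


def overlap_significance(n_a: int, n_b: int, overlap: int, universe: int) -> float:
    """One-sided hypergeometric tail P(X >= overlap), X ~ HG(universe, n_a, n_b)."""
    if not (0 <= overlap <= min(n_a, n_b) <= universe) or max(n_a, n_b) > universe:
        raise ValueError("inconsistent overlap counts")
    return float(sps.hypergeom.sf(overlap - 1, universe, n_a, n_b))


def percentage(numerator: float, denominator: float, digits: int = 0) -> float:
    """100*num/den rounded half-to-even at ``digits`` decimal places."""
    if denominator == 0:
        raise ValueError("denominator is zero")
    value = Decimal(100 * numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-digits)
    out = float(value.quantize(q, rounding=ROUND_HALF_EVEN))
    return int(out) if digits == 0 else out


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

SIZE_BIN_EDGES = (1, 11, 101, 1_001, 10_001, 100_001)
SIZE_BIN_LABELS = (
    "1-10",
    "11-100",
    "101-1000",
    "1001-10000",
    "10001-100000",
    ">100000",
)


def size_bin(size: int) -> str:
    for edge, label in zip(SIZE_BIN_EDGES[1:], SIZE_BIN_LABELS[:-1]):
        if size < edge:
            return label
    return SIZE_BIN_LABELS[-1]


def size_histogram(events: list[InsertionEvent]) -> dict[str, dict[str, int]]:
    """Binned junction gap sizes, separate series per gap class."""
    out = {
        "deletion": {label: 0 for label in SIZE_BIN_LABELS},
        "duplication": {label: 0 for label in SIZE_BIN_LABELS},
    }
    for ev in events:
        if ev.gap_class in out and ev.gap_size != 0:
            out[ev.gap_class][size_bin(abs(ev.gap_size))] += 1
    return out


def genes_per_insertion_histogram(
    insertion_gene_counts: list[int],
) -> dict[int, int]:
    """Counts of two-sided insertions affecting 0, 1, 2, ... genes (0 =
    intergenic, reported separately from genic bins)."""
    return dict(sorted(Counter(insertion_gene_counts).items()))


# ---------------------------------------------------------------------------
# Population summary
# ---------------------------------------------------------------------------


def summarize_population(
    callsets: list[MutantCallSet], n_redundant_removed: int = 0
) -> dict[str, float | int]:
    """S1-figure style totals over a called population."""
    counts = Counter()
    n_mut_multi = 0
    for cs in callsets:
        counts[cs.mutant_class] += 1
        n = 0
        for ev in cs.events:
            counts[ev.classification] += 1
            n += 1
            if ev.classification == "one_sided" and ev.one_sided_reason in (
                "repeat_flank",
                "no_discordant_reads",
            ):
                counts["one_sided_unmappable"] += 1
        if n > 1:
            n_mut_multi += 1
    n_insertions = counts["two_sided"] + counts["one_sided"] + counts["complex"]
    analyzed = [cs for cs in callsets if cs.mutant_class != "no_insertion_found"]
    mean_ins = (
        float(
            Decimal(sum(len(cs.events) for cs in analyzed)) / Decimal(len(analyzed))
        )
        if analyzed
        else 0.0
    )
    return {
        "n_mutants": len(callsets),
        "n_mutants_analyzed": len(analyzed),
        "n_no_insertion": counts["no_insertion_found"],
        "n_redundant_removed": n_redundant_removed,
        "n_two_sided": counts["two_sided"],
        "n_one_sided": counts["one_sided"],
        "n_complex": counts["complex"],
        "n_insertions": n_insertions,
        "n_simple_insertions": counts["two_sided"] + counts["one_sided_unmappable"],
        "n_mutants_simple_only": counts["simple_only"],
        "n_mutants_complex": counts["complex_containing"],
        "n_mutants_multi_insertion": n_mut_multi,
        "mean_insertions_per_mutant": round(mean_ins, 1),
    }
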