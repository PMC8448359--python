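"""Simulation configuration: sequencing geometry and the event-class mixture."""

from __future__ import annotations

from dataclasses import dataclass, field


#: Event classes a mutant genome can carry. The first eight involve the
#: mutagenesis plasmid; ``unassociated_deletion`` is a secondary lesion with
#: no plasmid sequence at its breakpoints.
INSERTION_CLASSES = (
    "two_sided_deletion",
    "two_sided_duplication",
    "two_sided_perfect",
    "one_sided_repeat",
    "one_sided_complex",
    "complex_intra",
    "complex_inter",
    "translocation",
    "cofragment_insertion",
)

EVENT_CLASSES = INSERTION_CLASSES + ("unassociated_deletion",)


@dataclass
class SimConfig:
    """Reference geometry and sequencing parameters.

    Defaults reproduce the screen's library preparation: mean depth 7.44,
    600 bp fragments (sd 60), 2x150 paired-end reads.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 500_000
    repeat_fraction: float = 0.05
    plasmid_length: int = 8_000
    coverage: float = 7.44
    fragment_mean: int = 600
    fragment_sd: int = 60
    read_length: int = 150
    base_error_rate: float = 0.0
    plasmid_name: str = "plasmid"

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.fragment_mean < 2 * self.read_length:
            raise ValueError("fragment_mean must be >= 2*read_length")
        if not (0 <= self.repeat_fraction < 0.5):
            raise ValueError("repeat_fraction must be in [0, 0.5)")
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        if self.plasmid_length < 100:
            raise ValueError("plasmid_length too small")
        if not (0 <= self.base_error_rate < 0.2):
            raise ValueError("base_error_rate out of range")

    @property
    def fragment_upper(self) -> int:
        """Concordance bound on implied fragment length (mean + 3 sd)."""
        return self.fragment_mean + 3 * self.fragment_sd

    @property
    def fragment_lower(self) -> int:
        return max(0, self.fragment_mean - 3 * self.fragment_sd)


@dataclass
class EventMixture:
    """Per-mutant event spectrum.

    ``class_probs`` give the probability that a drawn event belongs to each
    class; defaults follow the observed insertion spectrum (two-sided events
    dominate, ~88/7/5% deletion/duplication/perfect among them, a minority
    of one-sided and complex events, rare co-inserted fragments) plus a
    small rate of plasmid-unassociated deletions. Deletion sizes follow a
    two-component log-uniform mixture matching the observed bimodality.
    """

    class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "two_sided_deletion": 0.600,
            "two_sided_duplication": 0.050,
            "two_sided_perfect": 0.038,
            "one_sided_repeat": 0.028,
            "one_sided_complex": 0.014,
            "complex_intra": 0.070,
            "complex_inter": 0.070,
            "translocation": 0.025,
            "cofragment_insertion": 0.018,
            "unassociated_deletion": 0.087,
        }
    )
    # Junction-deletion size model: log-uniform components with weights.
    deletion_components: tuple[tuple[int, int], ...] = ((11, 100), (10_000, 100_000))
    deletion_weights: tuple[float, ...] = (0.5, 0.5)
    duplication_range: tuple[int, int] = (1, 999)
    unassociated_deletion_range: tuple[int, int] = (20, 36_000)
    # Extra events per mutant beyond the first are Poisson with this rate,
    # giving a mean of ~1.1 events per mutant.
    multi_event_rate: float = 0.1
    # Plasmid copies inserted per event. Concatemers are known to occur but
    # their copy number is not characterized; single copy is the default.
    concatemer_count: int = 1
    cofragment_range: tuple[int, int] = (500, 5_000)
    novel_flank_range: tuple[int, int] = (1_000, 3_000)
    rearrangement_span: tuple[int, int] = (20_000, 80_000)

    def __post_init__(self) -> None:
        unknown = set(self.class_probs) - set(EVENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown event classes: {sorted(unknown)}")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities must sum to 1, got {total}")
        if any(p < 0 for p in self.class_probs.values()):
            raise ValueError("negative class probability")
        if len(self.deletion_components) != len(self.deletion_weights):
            raise ValueError("deletion component/weight length mismatch")
        for lo, hi in self.deletion_components:
            if not (0 < lo <= hi):
                raise ValueError("deletion component ranges must be positive, ordered")
        if abs(sum(self.deletion_weights) - 1.0) > 1e-9:
            raise ValueError("deletion weights must sum to 1")
        if self.concatemer_count < 1:
            raise ValueError("concatemer_count must be >= 1")

    def prob_vector(self) -> tuple[tuple[str, ...], tuple[float, ...]]:
        classes = tuple(sorted(self.class_probs))
        return classes, tuple(self.class_probs[c] for c in classes)
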