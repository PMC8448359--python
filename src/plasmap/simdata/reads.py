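"""Paired-end fragment/read simulation over a mutated genome.

Fragments are drawn uniformly over the mutated genome with
Normal(fragment_mean, fragment_sd) lengths truncated at 2*read_length; each
fragment yields a forward read at its 5' end and a reverse-complement read
at its 3' end. Fragment provenance (mutated chromosome + coordinates) is
retained so alignments can be emitted from truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from plasmap.core import revcomp
from plasmap.simdata.config import SimConfig
from plasmap.simdata.mutate import MutatedGenome


@dataclass
class FragmentSet:
    """Vectorized fragment provenance for one mutant."""

    mutant_id: str
    chroms: list[str]                # per-chromosome order
    chrom_index: np.ndarray          # int index into chroms, per fragment
    starts: np.ndarray               # fragment start in mutated coords
    lengths: np.ndarray              # fragment length

    def __len__(self) -> int:
        return len(self.starts)

    def read_id(self, i: int) -> str:
        return f"{self.mutant_id}:{i}"


def n_pairs_for(coverage: float, genome_length: int, read_length: int) -> int:
    return int(round(coverage * genome_length / (2 * read_length)))


def simulate_reads(
    genome: MutatedGenome, config: SimConfig, seed: int
) -> FragmentSet:
    """Draw fragments over the mutated genome; deterministic per seed."""
    rng = np.random.default_rng(seed)
    chroms = list(genome.segments)
    lengths = np.array([genome.chrom_length(c) for c in chroms], dtype=np.int64)
    total = int(lengths.sum())
    n = n_pairs_for(config.coverage, total, config.read_length)

    frag_len = rng.normal(config.fragment_mean, config.fragment_sd, size=n)
    frag_len = np.maximum(np.round(frag_len), 2 * config.read_length).astype(np.int64)
    # Uniform position over the concatenated genome, then split per chromosome.
    pos = rng.integers(0, total, size=n)
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    cidx = np.searchsorted(bounds, pos, side="right") - 1
    starts = pos - bounds[cidx]
    # Clip fragments that would run off the chromosome end.
    ends = np.minimum(starts + frag_len, lengths[cidx])
    starts = np.maximum(0, ends - frag_len)
    frag_len = ends - starts
    return FragmentSet(
        mutant_id=genome.mutant_id,
        chroms=chroms,
        chrom_index=cidx.astype(np.int32),
        starts=starts.astype(np.int64),
        lengths=frag_len,
    )


def fragment_sequences(
    genome: MutatedGenome, frags: FragmentSet, config: SimConfig, seed: int
):
    """Yield (read_id, seq1, seq2) with substitution errors applied."""
    rng = np.random.default_rng(seed)
    seqs = genome.sequences()
    rl = config.read_length
    for i in range(len(frags)):
        chrom = frags.chroms[int(frags.chrom_index[i])]
        s = int(frags.starts[i])
        length = int(frags.lengths[i])
        frag = seqs[chrom][s : s + length]
        r1 = frag[:rl]
        r2 = revcomp(frag[-rl:])
        if config.base_error_rate > 0:
            r1 = _mutate_read(r1, config.base_error_rate, rng)
            r2 = _mutate_read(r2, config.base_error_rate, rng)
        yield frags.read_id(i), r1, r2


_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _mutate_read(read: str, rate: float, rng: np.random.Generator) -> str:
    k = rng.binomial(len(read), rate)
    if k == 0:
        return read
    out = list(read)
    for pos in rng.choice(len(read), size=k, replace=False):
        base = out[pos]
        out[pos] = _OTHER.get(base, ["N"])[int(rng.integers(3)) % len(_OTHER.get(base, ["N"]))]
    return "".join(out)


def write_fastq(
    genome: MutatedGenome,
    frags: FragmentSet,
    config: SimConfig,
    seed: int,
    path_r1,
    path_r2,
) -> None:
    qual = "I" * config.read_length
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for rid, r1, r2 in fragment_sequences(genome, frags, config, seed):
            f1.write(f"@{rid}/1\n{r1}\n+\n{qual[: len(r1)]}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{qual[: len(r2)]}\n")
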