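"""Synthetic reference genomes: random chromosomes, exact-duplication repeat
blocks (standing in for low-complexity, unmappable regions), and a plasmid
contig guaranteed to share no long k-mer with the nuclear sequence."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from plasmap.core import IntervalMask
from plasmap.simdata.config import SimConfig

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Repeat blocks are placed as identical pairs; a mapper cannot place reads
# from either copy uniquely, which we model as mapping quality 0.
_REPEAT_BLOCK_RANGE = (800, 2_500)
_KMER = 31


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def shared_kmers(a: str, b: str, k: int = _KMER) -> set[str]:
    """Exact k-mer set intersection between two sequences (both strands of b)."""
    from plasmap.core import revcomp

    if len(a) < k or len(b) < k:
        return set()
    kmers_a = {a[i : i + k] for i in range(len(a) - k + 1)}
    found = set()
    for strand in (b, revcomp(b)):
        for i in range(len(strand) - k + 1):
            km = strand[i : i + k]
            if km in kmers_a:
                found.add(km)
    return found


@dataclass
class Reference:
    chromosomes: dict[str, str]
    plasmid: str
    repeat_mask: IntervalMask
    plasmid_name: str = "plasmid"

    @property
    def contig_lengths(self) -> dict[str, int]:
        out = {name: len(seq) for name, seq in self.chromosomes.items()}
        out[self.plasmid_name] = len(self.plasmid)
        return out

    def total_chromosome_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def sequence(self, contig: str) -> str:
        if contig == self.plasmid_name:
            return self.plasmid
        return self.chromosomes[contig]


def generate_reference(config: SimConfig) -> Reference:
    """Generate chromosomes, repeat mask, and plasmid for a :class:`SimConfig`.

    Deterministic for a fixed seed. Repeat blocks are exact internal
    duplications placed in pairs; the masked fraction approximates
    ``config.repeat_fraction``. The plasmid shares no 31-mer with the
    chromosomes (resampled until true; vanishingly rare for random sequence).
    """
    rng = np.random.default_rng(config.seed)
    names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chroms = {name: bytearray(_random_seq(rng, config.chromosome_length), "ascii") for name in names}

    target_repeat = config.repeat_fraction * config.n_chromosomes * config.chromosome_length
    mask: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    placed = 0
    attempts = 0
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    while placed < target_repeat - _REPEAT_BLOCK_RANGE[0]:
        attempts += 1
        if attempts > 10_000:
            raise ValueError(
                "chromosome_length too small to place requested repeat blocks"
            )
        block_len = int(rng.integers(*_REPEAT_BLOCK_RANGE))
        if 2 * block_len > config.chromosome_length - 2:
            raise ValueError(
                "chromosome_length too small to place requested repeat blocks"
            )
        block = _random_seq(rng, block_len)
        spots = []
        ok = True
        for _ in range(2):  # two identical copies
            for _try in range(50):
                name = names[int(rng.integers(len(names)))]
                start = int(rng.integers(0, config.chromosome_length - block_len))
                iv = (start, start + block_len)
                if all(
                    iv[1] + 10 <= s or iv[0] >= e + 10
                    for s, e in occupied[name] + spots_on(spots, name)
                ):
                    spots.append((name, iv))
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        for name, (s, e) in spots:
            chroms[name][s:e] = block.encode()
            occupied[name].append((s, e))
            mask[name].append((s, e))
            placed += block_len

    plasmid = _random_seq(rng, config.plasmid_length)
    genome = "".join(bytes(b).decode() for b in chroms.values())
    for _ in range(20):
        if not shared_kmers(genome, plasmid):
            break
        plasmid = _random_seq(rng, config.plasmid_length)
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not generate plasmid free of shared 31-mers")

    return Reference(
        chromosomes={name: bytes(b).decode() for name, b in chroms.items()},
        plasmid=plasmid,
        repeat_mask=IntervalMask(mask),
        plasmid_name=config.plasmid_name,
    )


def spots_on(spots: list[tuple[str, tuple[int, int]]], name: str) -> list[tuple[int, int]]:
    return [iv for n, iv in spots if n == name]


def write_fasta(path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reference_to_fasta(reference: Reference, path) -> None:
    seqs = dict(reference.chromosomes)
    seqs[reference.plasmid_name] = reference.plasmid
    write_fasta(path, seqs)
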