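"""Synthetic gene models over a simulated reference, with GFF3 output.

Genes are tiled with intergenic spacing, each carrying a 5'-UTR, a few CDS
exons separated by introns, and a 3'-UTR, so every disruption-context class
(exon / intron / UTR / whole-gene deletion) can occur and be recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from plasmap.simdata.reference import Reference


@dataclass
class SyntheticGene:
    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)


def generate_gene_models(
    reference: Reference,
    seed: int,
    mean_spacing: int = 4_000,
    n_exons_range: tuple[int, int] = (2, 8),
    exon_len_range: tuple[int, int] = (100, 400),
    intron_len_range: tuple[int, int] = (80, 300),
    utr_len_range: tuple[int, int] = (50, 250),
) -> list[SyntheticGene]:
    rng = np.random.default_rng(seed)
    genes: list[SyntheticGene] = []
    counter = 1
    for chrom, seq in reference.chromosomes.items():
        pos = int(rng.integers(200, mean_spacing))
        while True:
            n_exons = int(rng.integers(*n_exons_range))
            utr5_len = int(rng.integers(*utr_len_range))
            utr3_len = int(rng.integers(*utr_len_range))
            exon_lens = rng.integers(*exon_len_range, size=n_exons)
            intron_lens = rng.integers(*intron_len_range, size=max(0, n_exons - 1))
            glen = utr5_len + utr3_len + int(exon_lens.sum()) + int(intron_lens.sum())
            if pos + glen >= len(seq) - 200:
                break
            g = SyntheticGene(
                gene_id=f"g{chrom[3:]}.{counter:04d}",
                chromosome=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                start=pos,
                end=pos + glen,
            )
            cur = pos
            g.utr5.append((cur, cur + utr5_len))
            first_exon_start = cur
            cur += utr5_len
            for k in range(n_exons):
                elen = int(exon_lens[k])
                g.cds.append((cur, cur + elen))
                if k == 0:
                    g.exons.append((first_exon_start, cur + elen))
                else:
                    g.exons.append((cur, cur + elen))
                cur += elen
                if k < n_exons - 1:
                    cur += int(intron_lens[k])
            # 3'-UTR extends the last exon.
            last_s, last_e = g.exons[-1]
            g.exons[-1] = (last_s, last_e + utr3_len)
            g.utr3.append((cur, cur + utr3_len))
            cur += utr3_len
            assert cur == g.end
            genes.append(g)
            counter += 1
            pos = g.end + int(rng.integers(mean_spacing // 4, 2 * mean_spacing))
    return genes


def write_gff3(genes: list[SyntheticGene], path) -> None:
    """1-based inclusive coordinates, gene/mRNA/exon/CDS/UTR hierarchy."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            mrna = f"{g.gene_id}.t1"
            fh.write(_line(g, "gene", g.start, g.end, g.gene_id, None))
            fh.write(_line(g, "mRNA", g.start, g.end, mrna, g.gene_id))
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(_line(g, "exon", s, e, f"{mrna}.exon{i}", mrna))
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(_line(g, "CDS", s, e, f"{mrna}.cds{i}", mrna))
            for i, (s, e) in enumerate(g.utr5, 1):
                fh.write(_line(g, "five_prime_UTR", s, e, f"{mrna}.utr5.{i}", mrna))
            for i, (s, e) in enumerate(g.utr3, 1):
                fh.write(_line(g, "three_prime_UTR", s, e, f"{mrna}.utr3.{i}", mrna))


def _line(g: SyntheticGene, ftype: str, s: int, e: int, fid: str, parent: str | None) -> str:
    attrs = f"ID={fid}" + (f";Parent={parent}" if parent else "")
    return "\t".join(
        [g.chromosome, "plasmap_sim", ftype, str(s + 1), str(e), ".", g.strand, ".", attrs]
    ) + "\n"
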