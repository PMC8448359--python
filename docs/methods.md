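# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `plasmap`.

## Problem setting

A haploid organism is mutagenized by random integration of a linearized
plasmid; mutants with a phenotype of interest are sequenced at low coverage
(~5–10×) with paired-end reads against a combined reference in which the
plasmid is an extra contig. Insertion loci reveal themselves as clusters of
discordant pairs (one mate chromosomal, one plasmid). Integration is
usually accompanied by structural damage — junction deletions spanning five
orders of magnitude, short target-site duplications, inversions,
translocations, co-inserted genome fragments — and independent secondary
deletions occur elsewhere. The pipeline reconstructs these lesions, maps
them onto gene models, and ranks candidate causative genes across the
population.

## Coordinates

All internal coordinates are 0-based, half-open. Files (SAM, GFF3, truth
and output TSVs) are 1-based inclusive. A zero-length junction point `p`
intersects an interval `[a, b)` iff `a <= p < b`.

## The simulator

The simulator defines the study conditions; its defaults are the screen's
library geometry and observed event spectrum, not tuning knobs.

* **Reference.** Random uniform-composition chromosomes (default 3 × 500
  kb — a desk-scale stand-in for a ~111 Mb genome; all algorithms are
  per-locus, so genome size affects runtime, not logic). Repeat blocks
  (800–2,500 bp) are planted as *exact* internal duplications covering
  ~5% of the genome; reads originating in them get mapping quality 0,
  modeling unmappable low-complexity sequence. The plasmid (default 8 kb)
  is resampled until it shares no 31-mer with the chromosomes, so
  plasmid/chromosome assignment of a mate is never ambiguous.
* **Sequencing.** Fragments are uniform over the mutated genome with
  Normal(600, 60) lengths truncated at 2·read_length; 2×150 bp mates; pair
  count = coverage·genome/(2·150) at a default mean depth of 7.44.
  Sequencing error is uniform substitution only (default rate 0; no
  indel errors, GC bias, adapters, or quality decay — passing tests
  therefore show algorithmic correctness under clean evidence, not
  robustness to every real-data artifact).
* **Events per mutant.** 1 + Poisson(0.1) events, giving a mean of ~1.1.
  The class mixture puts ~69% of probability on two-sided insertions
  (split ~88/7/5% deletion/duplication/perfect, as observed for such
  screens), ~4% on one-sided insertions (repeat flank or unmappable novel
  flank), ~17% on complex events (inversion with plasmid at one junction,
  interchromosomal block copy, reciprocal translocation), ~2% on
  co-inserted genome fragments (0.5–5 kb), and ~9% on plasmid-unassociated
  deletions. Junction deletion sizes follow a two-component log-uniform
  mixture, 11–100 bp and 10–100 kb with equal weight — the minimal model
  reproducing the observed bimodal size spectrum. Duplications are uniform
  1–999 bp; unassociated deletions log-uniform 20 bp–36 kb. Event loci are
  redrawn (bounded retries) to keep junction flanks clear of repeats and
  of each other; an error is raised if placement fails.
* **Alignments from truth.** The mutated genome is a segment map (source
  contig, interval, strand, or novel sequence), so each mate is placed at
  its true origin: junction-spanning reads are soft-clipped exactly at the
  breakpoint (the longer side anchors; ties anchor left), small colinear
  gaps (≤100 bp) are emitted as within-read D operations as a gapped
  aligner would produce, sub-20 bp mappable portions are unmapped, and
  proper-pair flags require same contig, facing orientation, and implied
  fragment within mean ± 3 sd. An aligner is deliberately not
  reimplemented — alignment is commodity tooling; the contribution starts
  at discordant-pair analysis — and `read_sam` ingests externally produced
  SAM/BAM with identical downstream behavior. The plasmid is inserted as a
  single copy by default; a concatemer-count knob exists but no fidelity
  to real concatemer structure is claimed.

## Insertion calling

* **Discordance.** A pair is discordant iff mates map to different
  contigs, or are non-facing, or the implied fragment falls outside
  mean ± 3 sd. Pairs with a mate below `mapq_min = 20` are excluded from
  clustering but kept as a side channel that diagnoses repeat flanks. The
  threshold codifies the common practice of discarding low-complexity
  placements; no published cutoff exists for this screen type.
* **Clustering.** Single-linkage over chromosomal mate intervals within
  `window = fragment_mean + 3·sd` (780 bp), split by (chromosome, side,
  partner contig); genome–genome clusters are further split by partner
  locus so a stray long-fragment pair cannot widen a junction cluster's
  partner window. `min_support = 2` balances sensitivity and noise at ~15×
  physical coverage of 600 bp fragments; sub-threshold clusters are
  counted, not silently dropped.
* **Junctions.** Soft-clip coordinates near the cluster's inner boundary
  vote; if the modal ±2 bp cluster holds ≥2/3 of votes the junction is
  exact (uncertainty 0), otherwise the innermost mate boundary is used
  with uncertainty `fragment_mean − 2·read_length` = 300 bp. Clip
  refinement is this pipeline's stated mechanism for the base-exact small
  gaps such screens report; the hierarchy is always soft-clip over
  discordant-only.
* **Pairing and gaps.** Left/right plasmid sites on one chromosome pair
  greedily by distance (candidates within `(−1000, 200 kb]`; 200 kb sits
  above the largest observed deletion; ties break to the lower coordinate
  and are flagged). Gap `g = right − left`: deletion, duplication
  (capped at 1,000 bp — larger negative gaps are flagged `unknown` for
  review, since observed duplications are all sub-kilobase), or perfect;
  when junction uncertainty covers `|g|`, the class is `unknown` rather
  than a guess.
* **Complex resolution.** Leftover plasmid sites and genome–genome
  clusters are chained transitively through shared loci (union–find).
  Components are classified as: co-inserted fragment — partner interval
  < 10 kb whose smoothed depth is ≥1.6× the contig median and returns to
  baseline within the 10 kb cap (the extent check distinguishes a short
  extra copy from a large duplicated block), yielding a two-sided event;
  reciprocal translocation — exactly two plasmid sites on different
  chromosomes linked by a genome–genome cluster (plasmid at one junction
  only); otherwise a complex lesion, possibly spanning several
  chromosomes. Isolated leftovers become one-sided insertions:
  `repeat_flank` if the opposite flank is ≥50% repeat-masked or carries
  low-mapq plasmid evidence, else `no_discordant_reads`.
* **Mutant class and redundancy.** A mutant is `simple_only` iff it has
  events and no complex lesion. Mutants whose complete insertion-site sets
  match within 10 bp form redundancy groups; *all* members are removed,
  since identical coordinates across independent transformants indicate
  sample duplication rather than biology.

## Secondary deletions

Three evidence tiers cover 20 bp–36 kb: (1) within-read D operations
agreeing within ±2 bp across ≥2 reads (base-exact); (2) paired opposing
soft-clip clusters — a right-clip cluster at the deletion start matched to
the nearest downstream left-clip cluster — with gaps >500 bp requiring a
spanning aberrant pair or an internal depth ≤1 (this split-read tier
covers the 100–500 bp band too large for within-read gaps at 150 bp reads
and too small for robust coverage runs); (3) maximal runs of depth ≤1
(tolerating one stray mismapped read) of ≥500 bp with <50% repeat-mask
overlap, boundaries refined by nearby clips. Overlapping calls merge with
read evidence taking precedence over coverage boundaries. Calls within
1 kb of any insertion junction or lesion footprint are insertion-
associated; the rest are the unassociated set. Detection necessarily
degrades with coverage — verified as a property (recall at 3× ≤ recall at
7.44×) rather than patched over; the null-simulation false-positive check
stands in for the visual confirmation used in manual workflows.

## Gene mapping

Footprints: a two-sided deletion contributes its deleted interval plus
junction points; perfect insertions and duplications junction points only
(a tandem micro-duplication deletes nothing); complex lesions all member
junction points; secondary deletions their intervals. A gene is affected
iff a footprint intersects its gene body — UTRs count as gene body, since
UTR insertions are disruptive in practice. Context is the most severe
overlapped feature (whole-gene deletion > CDS exon > 5′-UTR > 3′-UTR >
intron); for gene models without CDS records, exon intervals stand in.
Points strictly upstream are not "affected"; whether promoter-only lesions
should count is genuinely unclear, so the promoter window defaults to off
and `upstream_only` is opt-in. Interval queries run on interval trees and
are tested against a per-base brute-force oracle.

## Curation

The rule cascade (R1 single-gene simple mutant; R2 unique disruption-
frequency maximum within a group of mutants with overlapping disrupted
genes, which complex mutants may join — a single shared gene across many
overlapping deletions is strong evidence even in a rearranged background;
R3 unique flag-score maximum; R4 tie → multiple candidates; R5 none) is a
codification of what is, in practice, expert manual analysis. The flag
weights (conserved-lineage membership 2; keyword, co-expression, and each
cross-library hit 1) are this package's own scoring, exposed in config,
with a per-mutant audit trail making every decision reviewable; fidelity
to any particular manually curated list is not claimed. After the first
pass, genes co-disrupted alongside R1/R2 winners are demoted
population-wide and decisions are re-evaluated exactly once (first-pass
winners are protected) — a single sweep guarantees termination and matches
how a manual curation round proceeds. R1 counts a mutant's full disrupted
gene set, so demotion never reclassifies a frequency winner as a
single-gene call. Decisions are invariant to input ordering.

## Closed forms and reporting conventions

* Library saturation: `P(hit) = 1 − exp(−nL/G)` with n insertions, L mean
  exonic target per gene, G genome size; strictly increasing in n and L,
  decreasing in G; equals `1 − 1/e` at unit exposure. For reporting, the
  rate is quoted to 0.1% and then rounded to an integer percent
  (half-even, via decimal arithmetic) — the convention under which an
  exposure of 0.8557 (probability 0.575) reads as 58%.
* Linkage: zero recombinants among `2·n_zygospores` selected progeny bound
  the recombination frequency below `1/(2n)` — 0.5 cM at n = 100 — and
  ~100 kb/cM converts to ~50 kb. The bound formula is this package's
  reconstruction of standard tetrad arithmetic. With r > 0 recombinants
  the point estimate `r/(2n)` is returned instead.
* Candidate-set overlap: one-sided hypergeometric upper tail
  `P(X ≥ overlap)` with `X ~ HG(universe, n_a, n_b)` (scipy), tested to
  1e−12 against exhaustive subset enumeration for universes ≤ 25. The gene
  universe is a required explicit argument — there is no defensible
  default.
* All percentages round half-to-even. Size histograms use decade bins
  1–10, 11–100, …, >100,000 bp.

## Problem sizes in the test suite

The recovery experiments run at 3 × 500 kb with an 8 kb plasmid: 52
mutants × 4 two-sided insertions (208 events, ~1.9 M read pairs) for
insertion recovery, 10 mutants × 10 deletions (100 events) for secondary-
deletion recovery, and 10-mutant populations at 3×/7.44×/15× for the
coverage-monotonicity property. These sizes give binomial standard errors
comfortably below the asserted margins while each experiment completes in
about a minute on one core.

## Known limitations

* The simulator's aligner model is idealized: no mismapping outside
  planted repeats, no error-induced clips, no chimeric alignments;
  precision estimates on simulated data are therefore optimistic upper
  bounds for real libraries.
* Complex-lesion resolution reports junction graphs, not reconstructed
  sequence; validating rearranged structures would require de novo
  assembly, which is out of scope.
* A co-inserted fragment on the same chromosome within a cluster window of
  its source locus can be indistinguishable from a tandem duplication; the
  depth-extent criterion handles the observed regime (distal, <10 kb).
* One-sided "no discordant reads" calls conflate unmappable novel junction
  sequence with genuine coverage gaps; at ~7× the two cannot be separated
  from alignment evidence alone.
* Deletions whose junction reads happen to anchor only on one side (an
  ~0.5% occurrence per junction at 7.44×) are missed by the split-read
  tier; recall targets account for this.
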