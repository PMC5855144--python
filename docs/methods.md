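# Methods

## The genotyping model

`ssrgeno` genotypes microsatellites from amplicon sequencing by sequence
content and read length, not by electropherogram peaks. Each targeted locus
is a short amplicon (≤ 200 bp here) containing a tract of ≥ 7 tandem copies
of a tri- or tetra-nucleotide motif, bounded by locus-specific PCR primers.
A sequencing read yields an allele observation when it spans the entire
tract plus eight reference bases on each side; the allele is defined as the
tract length in bases (so an `ATT`×4 tract is allele 12, and alleles of the
same locus differ by whole motif units unless a true indel variant is
present). Diploid genotypes are then called per individual and locus from
the spanning-read tally under three filters:

1. **depth** — at least `min_reads` spanning reads (default 10), else `NA`;
2. **allele count** — more than two alleles each holding at least the
   heterozygote fraction of reads makes the cell `NA` (an unresolvable
   mixture or contamination);
3. **allele fraction** — a second allele is accepted only at
   ≥ `het_min_fraction` of the locus's spanning reads (default 20 %);
   below that it is treated as noise and the call is homozygous.

Both thresholds are inclusive. The 20 % denominator is the locus's total
spanning reads, not the top allele's count. Minor alleles *below* the 20 %
threshold — typically PCR stutter — are ignored entirely: they neither join
the genotype nor count against the two-allele limit. Count ties rank the
shorter allele first so calls are deterministic.

## Stage order and the anchor construction

The pipeline runs: quality filter → spacer stripping → locus assignment →
allele measurement → tallying → genotype filter → summaries/exports.

**Quality filter.** "Remove bases below Phred 30" is implemented as 3′-end
trimming: scan from the last base toward the 5′ end and cut at the first
base ≥ `min_qual`; then drop reads shorter than `min_len` (default 75 bp).
Interior low-quality bases are retained — the anchor matcher tolerates
isolated mismatches, and discarding a whole read for one bad interior call
wastes depth. A `strict_mode` that drops any read containing a sub-threshold
base is available but off by default. Input is Phred+33 FASTQ, gzipped or
not.

**Locus assignment.** Instead of alignment to a reference, reads are
assigned by primer-prefix matching: a read whose prefix matches a locus's
forward primer within `max_primer_mismatch` (default 2) substitutions is
forward; a prefix matching the reverse primer means the read is the reverse
complement of the amplicon and is flipped. The fewest-mismatch candidate
wins; exact ties leave the read unassigned. When 3-nt spacers (e.g. AAA/TTT)
were used to sub-demultiplex samples sharing an index pair, a leading spacer
is stripped — but only when immediately followed by a panel forward primer,
so spacer-like genomic prefixes are untouched.

**Allele measurement.** Each locus carries two 8-base anchors: the
reference bases immediately 5′ and 3′ of the repeat tract. In a
forward-oriented read the caller finds the leftmost occurrence of the 5′
anchor within `max_anchor_mismatch` (default 1) substitutions, then the
leftmost occurrence of the 3′ anchor strictly after it; the allele is the
number of bases between them. Reads missing either anchor are
`non_spanning` and never count — this is exactly the "whole repeat plus
eight bases each side" spanning contract, enforced directly rather than
through mapping, variant discovery and realignment. Anchor matching is
substitution-only: a read with an indel inside a flank fails to span, a
deliberately conservative choice mirroring the removal of reads that fail
realignment in mapping-based pipelines. The bases between the anchors must
also match the best circular phase of the motif at ≥ `purity_min` (default
0.9) — tracts interrupted by more noise than that are `impure` and dropped.
Allele lengths that are not motif multiples are kept as distinct alleles
rather than rounded, since rounding would hide true indel variants.

Mismatch tolerances (1 per anchor, 2 per primer) are pragmatic defaults —
tight enough that a random 150-mer essentially never matches (verified
empirically over 10⁴ random reads), loose enough to survive a typical
substitution error — and are all config-exposed.

## The built-in panel

The shipped panel reproduces an eight-locus design for the Neotropical fish
*Prochilodus costatus*: published primer pairs, motifs (ATT, CCGT, AATG,
AAG, TTTA, AAC, AAAG, AAAG) and amplicon sizes (130–197 bp). The flanking
sequence between the primers is **synthetic**: only primers, motifs and
sizes are public, so the interior is generated pseudo-randomly from a fixed
documented seed, with the tract fixed at eight motif copies (satisfying the
≥ 7-copy marker rule with headroom for one-unit deletion alleles) and
centred. Generation rejects candidate flanks whose tract-adjacent 8-mers
resemble the motif run, and requires each anchor to be unique in the
amplicon even under the caller's 1-mismatch tolerance — otherwise every
read at the locus would be systematically mis-measured. The panel is a pure
function of its seed. User panels load from a TSV
(`name, primer_f, primer_r, motif, repeat_start, repeat_end`; coordinates
1-based inclusive) plus a FASTA of reference amplicons, and are validated
against the same invariants.

## The simulator

The simulator is the package's stand-in for a real sequencing run and
defines the conditions the test suite measures under. Per locus it draws
diploid genotypes from an allele pool (uniform frequencies by default);
the default pool sizes per locus are 4, 6, 6, 7, 6, 7, 7 and 10 (ProC10 …
ProC49), totalling 53 distinct alleles — the published run-wide total with
its extremes at the right loci; only the total and the two extremes are
public, the interior split is this package's fixture choice. Read counts
per individual × locus cell are Poisson with mean
`total_reads × locus_share / n_individuals`, scaled by a per-individual
lognormal yield factor (CV 0.3 — a plausible inter-sample dispersion; the
source runs report only totals). The default locus shares are the
empirical shares of the published 384-individual run (5.44, 3.01, 14.52,
19.02, 0.21, 2.49, 3.81, 51.50 %), reproducing its extreme unevenness; the
default run scale is 384 individuals and ~991 k usable reads.

Each read is the full reference amplicon with the tract resized to the
sampled allele — reads are single-end, forward-orientation and cover the
whole amplicon, since 300-cycle chemistry covers these ≤ 200 bp targets
without merging. A cell's reads split as evenly as the count allows
between the two haplotypes (both alleles amplify equally; the odd read is
assigned at random), so a heterozygote's minor allele holds ~50 % of clean
reads and the 20 % rule recovers it whenever depth is adequate. Noise
enters as:

* **stutter** — per-read Bernoulli (`p_stutter`, default 0.02); an event
  shifts the tract by exactly one motif unit, shortening with probability
  `1 − p_expand` (default `p_expand` 0.25). No stutter model is published
  for these loci; one-unit slippage biased toward contraction is the
  standard behaviour of tri-/tetra-nucleotide repeats, and both knobs are
  config-exposed. Shifts below one motif copy are suppressed.
* **substitution error** — per-base at `sub_error` (default 0.001).
* **qualities** — per-position normal around a profile (Q37 plateau,
  declining 3′ tail), clipped to [2, 41].

A fixed-depth mode (`reads_per_cell`) bypasses the yield model and emits an
exact per-cell read count; recovery experiments use it to guarantee the
depth floor everywhere. `force_allele_coverage` reassigns haplotypes (still
seeded) until every pool allele is carried by at least two individuals,
which makes allele-richness recovery a deterministic property of the
configuration rather than a lottery. All randomness flows from one seeded
generator; identical config and seed give byte-identical FASTQ.

What the simulator does **not** model: indel sequencing errors outside
stutter, adapter/index read-through, chimeric amplicons, cross-sample
contamination, and locus-specific stutter-rate differences. Passing tests
therefore demonstrate the pipeline's logic — boundary behaviour of every
filter, exact recovery when the data match the model — not robustness to
every artefact of real libraries.

## Summaries and capacity arithmetic

Amplification efficiency per locus is 100 × (non-NA cells) / individuals;
efficiency and the locus's NA share are complementary by construction.
Read shares are spanning-read totals normalized to percentages. Percentages
print at two decimals, rounded half-up (spreadsheet convention). Mean depth
divides total spanning reads by the **full** grid (individuals × loci,
empty cells count as zero), matching how run-wide averages are quoted for
complete designs. The reads-versus-cohort-size relation is an ordinary
least-squares fit (scipy).

Capacity planning: with budget R, N individuals, L loci and depth floor m,
expected depth at a locus with share w is R·w/N. The design is feasible
when the minimum over loci clears m; `scale_factor` = min(expected)/m says
how many times the design could be scaled. Under uniform shares the closed
forms are `floor(R/(N·m))` loci or `floor(R/(L·m))` individuals. Both the
optimistic uniform bound and the weighted bound are always reported,
because real per-locus yields are uneven enough (0.21 %–51.5 % in the
default profile) to change the answer by an order of magnitude.

## Numerical and design choices

* Threshold comparisons (`≥ 10` reads, `≥ 20 %`) are inclusive; the
  fraction test uses exact division, and the exhaustive test-suite oracle
  restates it in integer arithmetic (`5·c ≥ total`) to rule out float
  boundary drift.
* Genotype ranking ties break toward the shorter allele; anchor and primer
  searches take the leftmost / fewest-mismatch candidate, with exact ties
  unassigned — every path is deterministic.
* `na_reason` (low_depth, excess_alleles, no_majority, no_data,
  ambiguous_tie) is diagnostic metadata; it never changes which cells are
  NA. The ambiguous-tie branch is unreachable under the two-allele limit
  and kept only to make the contract explicit.
* Degenerate inputs: empty panels load fine; a locus with zero spanning
  reads produces no tally and genotypes as NA/no_data; an all-bad read
  trims to empty and is removed by the length filter; `read_distribution`
  and the regression refuse empty/degenerate input with a clear error.
* Problem sizes in the test suite are chosen desk-scale: the full-cohort
  recovery check runs 384 individuals × 8 loci at 25 clean reads per cell
  (76,800 reads, a few seconds); property checks use 8–24 individuals.

## Known limitations

* Anchor matching does not tolerate indels in the flanks; a single
  sequencing indel there discards the read (conservative, loses depth).
* Primer-prefix assignment assumes reads start at a primer (true for
  amplicon protocols after adapter removal); arbitrarily fragmented input
  would need a mapper.
* Homoplasy detection by flank-variant content is limited to the purity
  score; the caller measures length, it does not phase internal SNPs.
* The GenePop export uses 3-digit allele codes, capping alleles at 999
  bases.
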