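# Methods

## Scope and model

The package genotypes diploid individuals at single-locus amplicon targets
(~350 bp: an MHC class II exon-2 peptide-binding region or a proximal
promoter) from pooled dual-barcoded reads, then computes the population and
molecular-evolution statistics that such genotypes feed. Each amplicon is
assumed to amplify one locus (at most two true alleles per individual); the
reads span the full amplicon (no fragmentation), so a read is a complete
observation of one template molecule plus sequencing artefacts.

## Demultiplexing

Reads shorter than `min_len` (default 350 bp — full amplicon length, kept
permissive to allow for deletions) are discarded before barcode search.
A read is assigned iff its first 10 bp match a forward barcode and its last
10 bp the reverse complement of a reverse barcode, both exactly (0
mismatches), testing the read in both orientations; matching reads are
orientation-normalised, trimmed of exactly 10 bp per end (all barcodes are
exactly 10 bp, so fixed-width trimming equals matched-string trimming) and
their original strand is kept for strand-aware pileups. Combinations of
valid barcodes not assigned to any sample are tallied separately: their
maximum read count is reported as a contamination/chimera background
benchmark against which the per-sample cutoff (`min_reads`, default 500)
can be judged. Every length-passing read lands in exactly one of
{assigned, unused-combination, unassigned} (tested invariant).

## Alignment and pileups

Reads equal in length to the reference are mapped column-to-column and
screened at ≥ 80% identity. Length-discordant reads (homopolymer
deletions) are aligned with an affine-gap glocal aligner (match +1,
mismatch −2, gap open −4, gap extend −1, end gaps free; Biopython's
`PairwiseAligner`). Deletions are left-aligned within homopolymer runs
before being recorded, removing alignment-dialect ambiguity. Pileups keep
per-base counts split by strand, per-strand deletion counts, and a
homopolymer-context flag for columns inside or adjacent to runs of length
≥ 4 (the threshold at which single-base deletion artefacts appear).

## The two callers

*Ratio caller.* Per site, with minor-base fraction m: heterozygote when
m ≥ `het_minor_frac` (default 0.35 — "nearly 50%"), homozygote when
m ≤ `max_minor_frac_hom` (default 0.05 — "nearly 100%"), otherwise
**no-call** with a ratio-distortion flag. The deliberate blindness of this
caller to intermediate ratios is what makes it robust to sequencing error
and what makes it miss chimera-distorted sites.

*Likelihood caller.* Standard diploid genotype likelihood: per-read error
probability from the column's mean Phred quality, P(base b | genotype
{a₁,a₂}) = ½P(b|a₁) + ½P(b|a₂) with P(b|a) = 1−e if b = a else e/3,
uniform prior over the 10 unordered base pairs. Calls are suppressed when
the Phred-scaled margin over the runner-up genotype or over homozygous
reference falls below `min_qual` (default 40, the published LOD cutoff).
This caller handles genotypes where both bases differ from the reference
(tri-allelic sites).

Neither caller replicates the *bugs* of the published tools (homopolymer
blindness; forcing the reference allele at tri-allelic sites): the
reconciliation taxonomy captures those error classes instead, which is the
methodological contribution being reimplemented.

## Reconciliation taxonomy

Concordant calls pass through. Disagreements are resolved in this order:

1. **chimera** (before per-site rules): reads are clustered by their bases
   at candidate variant sites; among clusters holding ≥ 5% of reads
   ("dominant"), a third cluster is chimeric iff some crossover index k
   makes it equal the largest cluster before k and the second-largest at or
   after k (or vice versa) — an exhaustive scan over k. Chimeric clusters'
   reads are removed and both callers rerun. With < 2 variant sites the
   verdict is "indeterminate" (a crossover is undetectable).
2. **strand_bias_misalignment**: a variant base (or deletion) supported on
   one strand while the other strand is clean with ≥ 10× coverage; the
   genotype is recomputed by likelihood on the clean strand only.
3. **sequencing_error**: a likelihood-only call whose minor fraction is
   below `min_minor_frac` (0.20) with no dominant-cluster support is
   rejected.
4. **tri_allelic**: both-non-reference genotypes are accepted from the
   likelihood caller.
5. **homopolymer**: ratio-caller variants in homopolymer context are kept
   when their allele fractions are consistent on both strands.

A disagreement matched by no rule is flagged `manual_review` and the sample
is not genotyped at that site. Finally, no emitted genotype may contain a
non-reference base seen in fewer than `min_minor_frac` of post-filter reads
(tested invariant). The distinction between `het_minor_frac` (the ratio
caller's heterozygote band) and `min_minor_frac` (the global support floor)
is intentional: the published procedure describes a caller that ignores
sites away from 50/100%, while disagreement resolution only requires 20%
support.

## Phasing

Reads covering all heterozygous sites are clustered by their base patterns.
The best-supported pattern consistent with the genotypes fixes one
haplotype; the second is forced site-by-site (at every heterozygous site,
including tri-allelic columns, the two genotype bases are split between the
haplotypes), so phasing reduces to validating that the complementary
pattern has adequate support. If the complement is unseen, or a rival
consistent pattern comes within 10% of its support, phasing errors out as
ambiguous rather than guessing — the published workflow resolved such ties
manually, and there is no principled automatic tie-break.

## Allele typing

Identical haplotypes across samples merge into catalogue records named
`<Taxon>-<Locus>*NN` in descending frequency order. Coding haplotypes are
translated (after partial-codon trimming, below); a stop codon excludes the
haplotype as non-functional. An allele is `confirmed` with ≥ 2 supporting
individuals or one independent-method confirmation, else `provisional`.

Sanger IUPAC consensus resolution enumerates unordered pairs of known
alleles whose position-wise union reproduces the consensus; failing that,
it infers at most **one** novel allele as the position-wise complement of a
compatible known allele (at a two-base ambiguity code the complement base
is forced). Multiple zero-novel pairs are ranked by summed catalogue
support; an unresolvable tie or multiple distinct one-novel complements is
surfaced as an error — predictions are conservative by design, two novel
alleles are never inferred.

## Coding-region statistics

Both exon-2 targets start and end mid-codon, so the first two and last one
nucleotide are trimmed before codon-level work (249 nt → 82 codons for
DQA, 270 nt → 89 for DQB). Pocket masks ship as editable config; the
defaults carry the published *counts* (15 residues over DQA pockets
P1/P6/P9; 19 over DQB P1/P4/P6/P7/P9) and positions are validated against
those totals at load — the residue indices themselves are configuration
data, not results. The enrichment G-test is the uncorrected two-cell
goodness-of-fit (zero cells contribute 0), with an optional Williams
correction flag; G and χ² agree within 10% whenever expected counts are
≥ 10 (tested property).

dN:dS uses Nei–Gojobori counting: per-codon synonymous-site fractions
(changes to stop codons count as nonsynonymous), difference counts by
equal-weight averaging over mutation orders with stop-crossing paths
excluded, Jukes–Cantor correction, and ω = mean dN / mean dS over pairs
(dS = 0 → ω flagged undefined, never infinity). The `tstv-weighted`
variant weights site counting by the estimated transition/transversion
ratio (κ = R/0.5) to soften the equal-rates assumption. R itself is the
K2P-corrected s/v averaged over pairs, falling back to direct
transition/transversion counting when the K2P logarithms are undefined.

The per-site scan is an explicit counting approximation of a codon-model
site analysis (the full ML/empirical-Bayes machinery is out of scope):
per codon column, substitutions from every allele to the modal codon are
counted and the nonsynonymous excess tested against the modal codon's
site-count expectation with a binomial test; output is the three-way
class w<1 / w≈1 / w>1. It has reasonable power only at codons with
several observed changes.

Codon usage: RSCU relative to uniform synonymous use; Wright's
N_c = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ with F̂ = (nΣp²−1)/(n−1) per amino
acid (n ≥ 2), the 3-fold class substituted by (F̄₂+F̄₄)/2 when absent and
other missing classes by the mean of observed classes (logged); clamped to
[20, 61] and NaN when no amino acid repeats. CBI follows Bennetzen–Hall
with "optimal" codons defaulting to the most frequent codon per amino acid
within the analysed set (the DnaSP convention); both the limits N_c → 61
(uniform) and → 20 (one codon per amino acid) are exact (tested).

## Population genetics

Expected heterozygosity is Nei's unbiased form [2n/(2n−1)](1 − Σpᵢ²) with
2n = gene copies; this reproduces the published per-stratum values exactly
at 3 decimals from the published count table. The geographic scheme is
ATL/ML/NIRL/SIRL with derived unions IRL = NIRL+SIRL and EST =
ML+NIRL+SIRL computed as exact elementwise sums. Allelic representation is
the whole-percent (half-up) share of the 33-allele catalogue present per
stratum.

The HWE exact test conditions on allele counts. When the genotype-table
state space is ≤ 10⁵ (generic DFS enumeration over tables with the
observed margins) the p-value is the exact mass of tables no more probable
than the observed. Otherwise an MCMC estimate is used: conditional on
allele counts, every slot-ordered arrangement of gene copies is equally
likely, so a chain that swaps one random gene copy between two random
individuals has a uniform target under a symmetric proposal — every move
is accepted and the table probability is only tracked as the test
statistic. Agreement with enumeration is within ±0.02 at 100k steps
(tested on a stratified set of 2-allele tables with n ≤ 30; checking every
such table is deliberately not attempted — the stratified set spans the
balanced, deficient and skewed corners).

F_ST is Weir–Cockerham θ from variance components (a, b, c) summed over
alleles, multi-locus by ratio of summed components across loci; loci
monomorphic across the compared strata drop out (logged). Significance
permutes *individuals* (genotype pairs, jointly across loci) between
strata, p = fraction of permuted θ ≥ observed; under a null split of one
pooled population the permutation p-values are uniform (KS-tested over 200
seeded replicates at 500 permutations).

## Promoter analyses

Motif consensi, windows (bp upstream of the transcription start, i.e. the
3′ end of the scanned region) and mismatch tolerances are configuration
data seeded from model-species class II promoter literature — the scanner
is deliberately data-driven because full consensus strings are not part of
the published record. Scanning is a position-complete Hamming window scan
on the coding strand only (promoters are orientation-defined); overlapping
hits are reported separately so duplications surface as multiple hits.
Default mismatch tolerance is 2 (cross-species scanning tolerates
divergence).

The duplication detector enumerates every repeated unit of length 11–22 bp
whose copies are separated by ≤ 30 bp, then greedily keeps chains by most
copies first, then longest unit, skipping spans already explained — so an
11-bp unit repeated three times is preferred over a chance 12-bp extension
seen twice. Reports include copy starts, spacer lengths, any catalogued
motif contained in the unit, and (given the unduplicated homolog) the net
inserted length. On seeded repeat-free random 200-mers the false-positive
rate is zero (tested against a brute-force oracle over 1,000 draws).

Column entropy is H = −Σ p log₂ p per alignment column, with gaps either
excluded (renormalised, H ≤ 2 bits) or treated as a fifth state; all-gap
columns are masked. Cross-species promoter alignment is accepted as input,
not computed — entropy is alignment-conditional.

## Synthetic data: what it does and does not emulate

The generator reproduces the study conditions the pipeline must survive:
diploid sampling from per-stratum allele frequencies with P(homozygote i)
= pᵢ² + F·pᵢ(1−pᵢ); dual 10-bp barcodes (10 forward × 10 reverse, ≤ 100
samples per panel); random read orientation (probability 0.5); uniform
per-base substitution errors (default 0.001); intra-sample single-crossover
PCR chimeras at a configurable rate (default 0.05 — the real rate is not
published, this is a fixture choice); and single-base deletions restricted
to homopolymer runs ≥ 4 and to one strand chosen per run site. Quality
strings are constant Q30 and errors are realised independently of the
written qualities, so the simulator controls truth while callers still
consume qualities. Barcode hopping is off by default (an optional rate
exists to emulate unused-combination background). Not emulated:
chromatogram traces, instrument flow-space signal, coverage ramps along
the amplicon, inter-sample contamination, read fragmentation. Passing
round-trip tests therefore demonstrates correctness of the *algorithms*
under the modelled artefact classes, not performance on any particular
instrument's error profile.

Determinism: one `numpy` Generator seeded from the configuration drives
all randomness; identical configuration and seed give byte-identical
FASTQ.

## Numerical and interface conventions

Coordinates are 0-based half-open internally; VCF output is 1-based, with
multi-allelic ALTs and phased genotypes once phasing succeeds, and INFO
carrying caller provenance and reconciliation class. Every CLI run writes
a JSON manifest (parameters, seed, input SHA-256 hashes). Stage counters
mirror a sequencing run report (reads in, length-passing, barcode-matched,
per-sample counts) so real-data runs can be compared against published run
statistics.

## Problem sizes used by the test suite

Round-trip concordance runs 200 simulated samples (two 100-sample panels)
at depth 500, substitution error 0.001, chimera rate 0.05; chimera-detector
recovery uses 200 seeded 3-cluster cases; permutation calibration uses 200
replicates × 500 permutations; HWE agreement uses ~10 tables × 100k MCMC
steps. These sizes are the package's chosen balance between statistical
resolution (binomial error ≲ 1% on the 99% concordance bound) and a test
suite that runs in about a minute.

## Known limitations

- Indels are treated as artefacts: true indel alleles are not called
  (amplicon alleles are assumed equal-length), matching the biology of the
  targets but limiting generality.
- The per-site selection scan is a low-power counting approximation; its
  classes should not be read as posterior probabilities.
- The ratio caller's bands, the 5% dominant-cluster threshold and the 10%
  phase-ambiguity margin are heuristics chosen to reproduce the published
  decision behaviour; all are configurable.
- Exact reproduction of the published F_ST matrix is impossible from
  printed data (it requires the individual genotypes), so F_ST is validated
  by construction (hand-computed toys, fixed-difference limit, null
  calibration) instead.
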