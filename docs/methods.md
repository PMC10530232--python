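# Methods

## Scope and data model

The package operates on panels of annotated mitogenomes: circular DNA
sequences with typed gene features in 0-based half-open coordinates on the
forward strand. GenBank I/O converts the format's 1-based inclusive spans
(and `complement(...)` / origin-wrapping `join(...)` locations) at the
boundary, which removes every off-by-one ambiguity from the statistics
downstream. Gene labels are normalized through an editable synonym table
shipped as package data (`data/gene_synonyms.yaml`), because public
annotations mix dialects (ND2/NAD2, COX1/COI, COB/CYTB, product-name
strings); labels outside the table stay explicitly unresolved rather than
being guessed. Gene boundaries are taken verbatim from each record's own
annotation. Translation uses the vertebrate mitochondrial code (NCBI
table 2): trailing incomplete codons (the common polyadenylation-completed
partial stops) are dropped before translation, a terminal stop closing a
non-empty protein is dropped, and internal stops are retained as `*` and
flagged.

## Alignment

Pairwise alignment is affine-gap Needleman–Wunsch (Gotoh), maximization
convention, with a gap of length k costing `gap_open + (k−1)·gap_extend`.
Defaults: match +1, mismatch −1, gap_open −4, gap_extend −1 — conservative
affine gaps suited to closely related coding sequences. Ambiguity codes
match only themselves (mismatch otherwise): the simplest defensible rule,
and ambiguous sites are excluded from the distance statistics anyway.
Traceback tie-breaking is fixed (diagonal > up > left), so alignments are
bit-reproducible. The DP kernels are numba-compiled; an optional diagonal
band (half-width plus the length difference) trades the optimality
guarantee for speed on near-identical sequences and is verified against the
full matrix in tests.

Progressive MSA builds an NJ guide tree from pairwise p-distances, then
merges profiles by profile–profile Needleman–Wunsch with column-frequency
scoring (gap mass scores zero; new gaps pay the affine penalties); output
row order equals input order. When sequences exceed ~3 kb, or when a band
is requested (the caller signalling speed over exactness), guide-tree
distances come from a unit-cost edit-distance global aligner (edlib); the
profile merges always use the package's own kernel. Whole-mitogenome
pairwise comparison (~16–17 kb) always uses the unit-cost aligner: at
genome scale the affine O(n·m) matrix is wasteful and the downstream
statistics are aligner-agnostic consumers of the `Alignment` container.
Externally produced aligned FASTA is accepted everywhere an alignment is.

## Divergence battery and marker ranking

* p-distance: pairwise deletion — sites with a gap or ambiguity in either
  row are excluded from numerator and denominator; undefined (NaN) when no
  site is comparable.
* Whole-genome Hamming dissimilarity: percent of alignment columns that
  differ, *including* gap columns. The two conventions are deliberate:
  indels carry signal genome-wide, but within a single gene's alignment
  they usually reflect annotation-boundary noise, so the per-gene
  statistics exclude them. Both are exposed as explicit options.
* TN93: computed from the two transition proportions, the transversion
  proportion and base frequencies pooled over the compared rows (an
  explicit frequency override exists). A non-positive logarithm argument
  (saturation) yields NaN rather than a clamped value.
* Variable sites: complete deletion first (every column with any gap or
  ambiguity removed), then columns with ≥ 2 states; the same operation
  serves nucleotide and amino-acid alignments with different alphabets.
* The target's *nearest relative* is read from the whole-genome TN93 NJ
  tree (cherry partner if the target sits in a cherry, else the minimal
  patristic distance, ties alphabetical), not hard-coded — the principle
  that the closest relative drives marker choice is thereby general.
* Ranking: p-to-nearest (desc), then mean panel p (desc), then nucleotide
  variable-site fraction (desc), then gene name. Reported percentages are
  rounded to integer percent for presentation; raw proportions are kept in
  machine output.

Neighbor joining is the standard Saitou–Nei agglomeration with the
Q-criterion, implemented in-package so tie-breaking (lowest index pair) and
negative-branch clamping (to zero) are pinned; on additive matrices it
provably recovers the generating tree, which the tests exploit as an exact
oracle.

## Primer design

A *diagnostic position* is an alignment column where the target base
differs from every ungapped non-target row (gapped rows are counted and
reported). Candidate windows are enumerated over the de-gapped target
sequence; a window qualifies as a forward (reverse) primer when at least
one diagnostic position falls in its 3′-terminal window (5 nt default) —
3′ mismatches are what block extension in non-target templates. Individual
constraints: length 18–32 nt, GC 30–70 %, Tm 50–80 °C, self-dimer and
hairpin-stem runs ≤ 6. Pairs require product length (inclusive of both
footprints, measured on the de-gapped target — the biological amplicon)
within 80–400 bp, Tm difference ≤ 8 °C, cross-dimer run ≤ 6 and 3′-anchored
cross run ≤ 4. The 3′-anchored default is 4, not lower, because the
published Pink dentex set-1 pair — which the thresholds must admit —
carries a 3′-anchored run of 4. Ranking: 3′-proximal diagnostic count,
then total diagnostic count, then Tm balance. Because thermodynamic checks
dominate cost, windows are evaluated in diagnosticity order and at most 300
per orientation enter the pairing stage.

Complementarity runs are brute-forced as the longest common substring of
one oligo and the reverse complement of the other — exactly the
antiparallel Watson–Crick duplex; a poly-A oligo therefore has self-dimer
run 0 (A·A is not a pair), while a palindromic oligo scores its full
length. Melting temperatures offer Wallace (2AT+4GC), the GC/salt formula
(81.5 + 0.41·GC% − 675/N + 16.6·log10[Na+]), and unified nearest-neighbor
thermodynamics (default; 50 mM monovalent cation, 250 nM oligo), checked in
tests against an independently hand-summed SantaLucia parameter set. No Tm
model reproduces the Tm column printed alongside the published primer set
(whose formula is unstated); Tm values are therefore pinned only to the
nearest-neighbor calculation and never treated as exact targets.

## In-silico PCR

The mismatch model is ungapped — standard in-silico PCR practice: a primer
footprint is compared base-by-base at every offset on both strands,
wrapping the origin on circular templates. Defaults: ≤ 2 total mismatches,
0 in the 3′-terminal 5 nt. Products pair a plus-strand forward site with a
downstream minus-strand reverse site, may cross the circular origin, and
run from the forward 5′ end to the reverse primer's 5′ end on the sense
strand inclusive — so a pair whose footprints sit 290 bp apart yields
exactly 290 bp. Rotating a circular template leaves predictions invariant
(tested). Amplicon melt temperature uses the long-duplex %GC formula and
is flagged indicative (±2 °C), never a validation quantity. Intraspecific
variability of a set of amplicons is the maximum (and full matrix of)
pairwise p-distances after global alignment, in percent.

## Synthetic panels

The generator emulates the study input: annotated circular genomes carrying
the 13 PCGs in canonical vertebrate order (NAD6 on the minus strand) with
30 nt spacer tracts, evolved along a known tree. Defaults: gene lengths
typical of sparid mitogenomes (NAD2 1047, COI 1566, ATP6 684, ...); TN93
with base frequencies (A 0.28, C 0.29, G 0.16, T 0.27) and
transition/transversion ratios κ1 = 6 (purine), κ2 = 12 (pyrimidine),
reflecting the strong, pyrimidine-heavy transition bias of vertebrate
mtDNA; random 8-taxon trees with uniform branch lengths 0.02–0.08 expected
substitutions/site, giving panel divergences in the range observed among
confamilial fish mitogenomes (p ≈ 0.05–0.25). Substitutions use exact
per-site Gillespie simulation under the scaled TN93 generator, so realized
counts can be audited against the matrix-exponential expectation
(`expected_p_distance`, used by the calibration tests). Internal stop
codons are rejection-resampled by re-evolving the offending codon from its
parent state. Spacers evolve at 0.1× and are excluded from all statistics;
optional indels (off by default) are confined to spacers so gene
alignments stay codon-clean.

What the generator does **not** emulate: tRNA/rRNA/control regions,
annotation errors, rate variation *within* genes, selection, and real
indel processes in coding sequence. Passing tests on synthetic panels
therefore demonstrate the pipeline's internal correctness and calibration
against its own model — not that any particular real panel will reproduce a
given printed percentage, which also depends on the upstream aligner and
its gap parameters (a ±1-point sensitivity documented for the per-gene
percentages).

Fixture builders: `plant_diagnostic_region` engineers target-unique bases
at chosen gene offsets (erroring if a requested base collides with an
off-target base), and `plant_primer_sites` writes a literal primer pair
into the target's gene at a chosen spacing — both produce *synthetic*
ground truth for the design and screening stages, e.g. a known 290 bp
product.

## Problem sizes and reproducibility

The validation experiments use 8-taxon panels and 50 seeded replicates for
marker-ranking recovery (the fast gene at rate ×3 must rank first in
≥ 95 % of replicates), 10 replicates for the two-taxon model-calibration
check, and ~12 kb synthetic genomes — sizes chosen so the full suite runs
on a laptop-class single core in minutes while keeping Monte-Carlo error
well below the tested effect sizes. Every stochastic stage consumes an
explicit integer seed; re-running the pipeline with identical inputs and
configuration is bit-identical, and the output manifest records the
configuration hash and all thresholds.

## Known limitations

* Progressive MSA with two sequences ≥ 3 kb falls back to unit-cost
  alignment for guide distances; for divergences beyond ~30 % the affine
  aligner's defaults (and any single set of gap parameters) shift per-gene
  percentages by a point or two.
* The in-silico PCR model ignores primer–template indels, polymerase
  kinetics and amplification efficiency; it predicts binding, not Ct.
* TN93 saturation is reported as missing rather than being truncated;
  downstream consumers must handle NaN distances (the NJ stage refuses
  them).
* The nearest-neighbor Tm model targets short oligos (8–40 nt) at simple
  ionic conditions; no Mg2+ or dNTP corrections are applied.
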