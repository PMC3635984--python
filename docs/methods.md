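# Methods

This note documents the models, conventions and numerical choices behind
`natcons`, and what the synthetic benchmark does and does not demonstrate.

## Expression model and elementary transforms

All intensities are RMA-convention log2 values and are never re-logged.
Replicates are averaged by the arithmetic mean **on the log scale** (one
column per tissue afterwards); matrices lacking a configured shared tissue
are rejected at ingest rather than imputed.

Relative abundance divides each tissue's log intensity by the profile's sum;
it is defined only for strictly positive entries (guaranteed in the RMA
regime; violations raise). The abundance vector is non-negative and sums
to 1, so the Euclidean divergence between two abundance profiles lies in
[0, √2], reaching √2 only for expression confined to disjoint tissues.

The detectability filter keeps a cross-species pair when **any** of its 2·T
averaged intensities strictly exceeds the threshold (default 6.5, the
intensity at which detection-above-background p-values on these arrays fall
below 0.01). Reading the filter per pair rather than per probeset matches
the convention that either member's detection suffices; a per-member mode is
exposed (`mode="each"`). The threshold is applied after replicate averaging,
since the analysis matrices are averaged; it is configurable and can be
disabled.

## Divergence comparison and its null

The comparison restricts ortholog pairs by the expression filter, computes
each retained pair's divergence, builds **one permuted set of equal size
from the retained pairs** (species-A members keep their order; species-B
members are uniformly re-paired, fixed points allowed — excluding them would
bias the null at small n), and applies Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom, two-sided, reporting the direction
(orthologous < permuted) alongside. Filtering precedes permutation so both
sets draw on the same probeset universe and remain exchangeable under the
null. Degenerate inputs follow fixed conventions: two equal constant samples
give t = 0, p = 1; unequal constant samples give t = ±∞, p = 0.

**Calibration caveat.** Because the permuted set reuses the orthologous
set's profiles, the two divergence samples are positively dependent:
D(a, b) and D(a, b′) correlate at ≈ 0.25 when they share one profile, so
cov(mean_o, mean_p) ≈ 0.5·v/n and Var(mean_o − mean_p) ≈ v/n, half of what
the unpaired Welch test assumes. The test's true size at nominal 0.05 is
therefore ≈ 0.006 (measured: 1/200 rejections under a no-conservation
generator). The procedure is **conservative**: dependence can hide real
signal but cannot manufacture it, so the astronomically small p-values on
conserved data are trustworthy. Users wanting a resampling-based inference
can pass `n_null_sets > 1` (CLI `--n-null-sets`) to obtain a one-sided
permutation p-value over many permuted sets, or use the within-pair
tissue-label-shuffle null (`alternative_randomization`), which breaks
profile sharing per pair but tests a different (within-pair) hypothesis.

A Pearson-based divergence (1 − r of the raw log profiles, range [0, 2]) is
available as a robustness measure; it is undefined for constant profiles and
raises rather than returning NaN.

Cross-tissue correlation matrices (species-A tissue s vs species-B tissue t
over ortholog pairs) flag zero-variance tissues as undefined (NaN in that
row/column only). Cumulative distributions of both divergence sets are
emitted as ECDF tables; plotting is left to the user.

## Orthology

Gene-level orthologs come from a homology-group table (group id, species,
gene id) joined to per-species gene→probeset annotations; groups missing a
species are skipped, unannotated genes are warned about and skipped.

Exon-level orthology uses an in-package Needleman–Wunsch global aligner
(match +1, mismatch −1, linear gap −2 by default; configurable) rather than
a local-alignment heuristic: "global identity" is the fraction of identical
columns over **all** alignment columns, gaps included — the strictest
denominator. Ties between DP predecessors resolve diagonal > up > left, and
the two sequences are put in canonical (lexicographic) order before
aligning, which makes the identity deterministic and exactly symmetric. The
cutoff is identity > 0.80; among multiple candidates only the highest
identity survives, ties going to the lexicographically smallest identifier.
Best-hit is one-directional by default with an optional reciprocal-best
mode. A banded edit-distance prescreen (edlib) skips candidate pairs whose
unit-cost edit distance already exceeds `(1 − min_identity)·(|a| + |b|)`; by
that bound such pairs can never reach the cutoff, so the prescreen is
lossless and only saves time.

Probesets overlapped by annotated transcripts on **both** strands are
removed before divergence analysis (their signal is strand-ambiguous).
Coordinates are 0-based half-open throughout; book-ended intervals do not
overlap. The probeset's own strand is irrelevant to this filter.

## Tissue specificity

Three criteria on the averaged matrix, after dropping excluded
(non-orthologous, e.g. whole-embryo) tissues: top tissue strictly above the
6.5 threshold; z-score of the top value strictly above 2; top value at least
1.0 log2 above the runner-up (≥, following "at least"). The z-score uses the
mean and sample sd (ddof = 1) over **all** tissues including the candidate —
with T = 9 the attainable maximum is (T−1)/√T ≈ 2.67, so the z > 2 criterion
is demanding; an `exclude_self` variant is exposed. Constant profiles have
all z = 0 and are never called; a tie for the maximum gives margin 0 and is
never called. All cutoffs are parameters; the defaults are the analysis
convention, in log2 units.

## Novelty screening

"Perfect match" is an exact, full-length, contiguous substring match of the
query's **reverse complement** in either reference database — the arrays
report the strand opposite the annotated transcript, so known transcripts
appear as reverse complements (a forward-orientation match does not count; a
`both_strands` diagnostic mode exists). Matching uses an 11-mer seed index
with exact extension, equivalent to a full substring scan; `N` never matches
and queries containing `N` are flagged and skipped; queries shorter than the
word size fall back to a direct scan. Counts are reported in three rows:
absent from RefSeq-like, absent from EST-like, absent from both (novel).

## Sense–antisense coupling

Sense and antisense arrays are normalized separately, so absolute levels are
not comparable between protocols; the module reports only correlations: per
tissue, Pearson r between protocols across probesets; and across loci, the
correlation of sense-protocol vs antisense-protocol cross-species
divergence, joined on the shared probeset identifier (both protocols
interrogate the same exonic locus).

## The synthetic generator

Defaults emulate the study design: 3 species (human, mouse, rat) × 9 matched
tissues (brain, heart, kidney, liver, lung, spleen, ovary, testes, thymus)
× 2 technical replicates × 2 protocols; optional extra tissues (e.g. embryo)
for testing the exclusion step. Per ortholog group, each species' deviation
from the protocol mean is `alpha·b + (1−alpha)·u + ε` with shared latent `b`
(sd 1 log2), per-species latent `u`, and noise sd 0.5; conservation weight
defaults alpha_sense = 0.8 > alpha_antisense = 0.4, with a per-locus jitter
(sd 0.1) shared between strands so conservation is coupled across protocols.
Antisense values additionally share fraction rho = 0.5 of the standardized
sense deviation (per-tissue sense–antisense correlation ≈ rho) and sit 1
log2 lower on average (expressed means 8 and 7; background 6 ± 0.2, below
the 6.5 threshold; replicate noise sd 0.25; everything clipped to
[0.5, 15.5]). One root seed spawns independent child streams for sequences,
expression, spikes and novelty, so stages are individually reproducible and
outputs are byte-identical under a fixed seed.

Sequences: one random ancestor per ortholog group (150 bp default), mutated
per species at 5% per site (substitutions only, never to the same base), so
cross-species identity concentrates near (1−r)² ≈ 0.90 — above the 0.80
cutoff — while unpaired decoys sit at the ~0.25 random baseline. A fraction
of probesets (10%) are novel: absent from both reference databases; the rest
are embedded as exact reverse-complement substrings with random flanks into
the RefSeq-like database, the EST-like database, or both. 5% of probesets
get an opposite-strand overlapping transcript in the BED annotation; 10% of
unpaired probesets get a +3 log2 single-tissue spike over the sub-threshold
background.

**What passing on synthetic data does not show.** The generator is Gaussian
on the log scale with exchangeable tissues; real arrays have heavy-tailed
noise, correlated tissues, probe-level effects (GC content,
cross-hybridization), indel-containing exon alignments (the mutation model
is substitution-only), and reference databases with partial or redundant
records. Perfect precision/recall on orthology, novelty and
tissue-specificity reflects the planted-truth setting — signals are
unambiguous by construction — and should be read as correctness of the
implementations, not as expected performance on real data.

## Problem sizes and numerics

The benchmark sizes are chosen to make every Monte-Carlo check
statistically decisive at desk scale: 5,000 pairs for the headline
significance run, 200 replicates × 1,000 pairs for null calibration, 100
replicates for the sense-vs-antisense gap ordering, 10,000 random cases for
the metric axioms, 100 ortholog groups (plus 50 decoys) for orthology
recovery, 2,000 probesets (200 spiked) for tissue-specificity, 500 queries
for the novelty oracle. Abundance sums are checked to 1e-9; alignment
identities are exact rationals of column counts; Welch's test delegates to
`scipy.stats.ttest_ind(equal_var=False)` apart from the degenerate
conventions above; p-values below double-precision underflow are reported as
−log10 p capped at 300.

## Known limitations

- The aligner is O(nm) per pair with linear (not affine) gap costs;
  exon-sized sequences are the intended regime.
- One permuted set (as in the underlying design) rather than a full
  permutation distribution; the Welch p is conservative under dependence as
  analyzed above.
- The novelty screen is exact-match only by design; it cannot model
  near-perfect BLAST hits with trimmed flanks.
- Gene-level orthology trusts the homology table; no synteny or tree-based
  verification.
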