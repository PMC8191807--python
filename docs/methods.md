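# Methods

## Rate estimation from fluctuation assays

A fluctuation assay consists of C parallel cultures grown without
selection from a small inoculum to N viable cells each, then plated on
selective medium.  Mutations arise at rate μ per locus per division; a
mutation early in growth founds a large resistant clone, so the
selected-colony counts r₁..r_C follow the heavy-tailed Luria–Delbrück
distribution rather than a Poisson.

`lc_median_m` implements the method of the median: the expected number of
mutations per culture m is the unique positive root of

    r̃/m − ln(m) = 1.24,

with r̃ the median count.  The left side is strictly decreasing in m, so
the root is found by bracketed Brent iteration to relative tolerance
1e-12.  The estimator needs r̃ ≥ 1; a zero median carries no information
for it and the caller is directed to the P0 method,
m = −ln(fraction of cultures with zero mutants).  The rate is μ = m/N;
N is the final viable count per culture, and pooled assays use the median
N across cultures.

`FluctuationModel` / `FluctuationResults` follow the model-object
convention: the model holds the data (counts, N, a label), `fit()` selects
the method (`auto` uses the median method when r̃ ≥ 1, else P0) and
attaches a confidence interval; `summary()` renders the estimate.

**Confidence intervals.**  The total-rate CI is a nonparametric bootstrap
over cultures: 10 000 resamples (seeded; `n_boot=0` disables), percentile
interval, each resample re-estimated with the same median/P0 logic.  The
bootstrap statistic takes few distinct median values, so the Lea–Coulson
relation is solved once per distinct value.  Per-class CIs are a labelled
composite — total-rate CI bounds scaled by the Wilson interval on k/n —
because no exact small-sample interval exists for a product of a
Luria–Delbrück rate and a binomial fraction; treat them as indicative.

**Jackpot handling.**  None: the median is already robust to jackpot
cultures, and no outlier trimming or plating-efficiency / differential-
fitness correction is applied.  Maximum-likelihood (MSS) estimation is
deliberately out of scope.

## Per-class rate partitioning

With k of n sequenced mutants in a class, the class rate is μ·k/n.  When
k = 0 the class receives the single-event upper bound μ·(1/n), flagged as
a bound (`<` prefix in displays) — the rate the class would have had with
one observed event.  Observed-class rates sum to μ exactly before display
rounding; displays use 3 significant figures for rates and nearest-integer
rounding for fold changes and percentages, with raw ratios always emitted
alongside.  `fold_change` against a bounded baseline returns a bound in
the opposite direction.

`ma_rate` is the mutation-accumulation arithmetic: genome-wide rate =
mutations / (genome bp × divisions per line × number of lines).

## Sequence scanners

Coordinates are 1-based inclusive everywhere internally; BED-style input
is converted at the I/O boundary.  Ambiguity codes are rejected rather
than expanded — reporter genes are fully determined sequences.

**Direct repeats** (`scan_direct_repeats`, default min length 4): for
every offset d and every maximal run of positions x with
seq[x] = seq[x+d], one pair of length min(run, d) is reported at the left
end of the run.  The min(run, d) cap keeps the two copies non-overlapping
and collapses homopolymer/periodic runs to their single maximal tandem
pair, preventing the combinatorial blow-up of reporting every
sub-alignment.  Repeats are exact; separation is filterable.

**Quasi-palindromes** (`scan_quasipalindromes`, defaults min_arm 6,
max_loop 12, max_mismatch 2): for each placement of the inner boundary and
each loop length, arms grow outward symmetrically and the single largest
arm within the mismatch budget is reported.  The defaults are package
choices — no published arm/loop/mismatch definition exists for the
reporter-gene QP — and are exposed as configuration.  The scanner emits
equal-arm structures (substitution-type defects); *length-defect* QPs,
whose perfecting event is an insertion, are described in curated
registries (TSV of arm intervals and loop length) because arm-length
asymmetry is not recoverable from a symmetric scan.

## Variant calling and normalization

Mutant alleles are aligned globally to the reference under fixed scoring
(match +1, mismatch −2, gap open −5, gap extend −1; a gap of length L
scores −5 −(L−1)), with ties broken by the aligner's deterministic first
traceback so outputs are bit-identical across runs.  A length ratio above
2 is rejected as a wrong-gene input.  Maximal difference runs become
calls; calls separated by at most `merge_window` (default 10 bp, a package
decision — "complex mutation" has no standard operational definition)
merge into one complex call.

Indels are left-aligned (the VCF convention) and carry their full
`shift_range` of equivalent placements, because junction analysis must
consider every placement: `classify_variant` maximizes junction homology
over the range.  `normalize_indel` is idempotent, and applying extracted
calls to the reference reconstructs the mutant exactly (a tested
invariant).

## Classification

Precedence: (1) `QP_TEMPLATED` for an insertion or complex call that
perfects a registered QP — checked by applying the call to the QP
footprint and testing exact reverse-complement arm identity at fixed loop
length — so templated insertions are never double-counted as small
indels; (2) `SBS` with one of six complementary-collapsed types
(AT>TA, AT>GC, AT>CG, CG>GC, CG>AT, CG>TA); (3) deletions/insertions ≥ 5 bp
(`DEL_GE5`/`INS_GE5`; a 5 bp event is in this class, "< 5 bp" means
1–4 bp); (4) `INDEL_LT5`; (5) `COMPLEX`.  Junction homology ≥ 4 bp sets a
"flanked by direct repeats" flag but does not gate the size class, which
counts all ≥ 5 bp events.  Insertions equal to an adjacent reference
segment (either flank, any equivalent placement) are flagged duplications.
Region assignment uses the leftmost variant start; boundary-spanning
events are logged.

**Strand inference.**  The templating arm of a perfected QP is the arm the
variant did not touch.  Combined with the fork direction (origin side
relative to the gene) a configurable lookup names the initiating strand;
the default convention calls a right-arm-templated correction under a
rightward-moving fork a leading-strand-initiated switch.  The mapping is a
convention, exposed as configuration, and `unknown` fork direction yields
`unknown` strand.

## Statistics

Fisher exact is two-sided by the probability-mass method; chi-square is
the Pearson statistic without continuity correction (warning when an
expected cell is below 5); proportion CIs are Wilson score intervals
(Clopper–Pearson behind a flag).  `compare_spectra` collapses each class
against the rest into a 2×2 table and applies Benjamini–Hochberg
adjustment across classes because many per-class tests are run; raw
p-values are always reported, and odds ratios use the Haldane–Anscombe
0.5 correction when a zero cell exists.

## Synthetic data

**Cultures.**  The culture model is a deterministic doubling-generation
process: every cell divides each generation, new mutations per generation
are Poisson with mean (divisions × μ), and a mutant arising g doublings
before plating contributes a clone of 2^g colonies (a final partial
generation, when N/n₀ is not a power of two, divides only the cells
needed and its mutants stay single-cell clones).  Expected mutations per
culture are exactly μ(N − n₀) and P(count = 0) = exp(−m), both tested.
This is simpler than a continuous-time birth process; the discreteness
quantizes clone sizes to powers of two, which biases the
median-method estimate mildly low (the tested recovery band is ±25% on
the median over 200 assays at μ = 10⁻⁷, N = 2×10⁷, 20 cultures — the
assay geometry of a typical reporter-gene experiment).  What passing
recovery tests show is that the estimator pipeline is correctly wired and
calibrated to that band; they do not certify accuracy under real-culture
effects the generator omits (plating efficiency, fitness differences
between mutants, non-synchronous growth).

**Cohorts.**  `simulate_mutant_cohort` draws one event per mutant from a
weighted mixture: slippage deletions remove the inter-repeat segment plus
one repeat copy of an eligible scanned pair (copies ≥ 4 bp by default,
separation 1–50 bp); duplications tandem-copy the same geometry;
substitutions follow a configurable six-type spectrum; small indels are
1–4 bp; QP insertions insert the exact bases that perfect a registered
length-defect QP.  `synthetic_reporter` emulates an engineered GC-rich
construct: an 804 bp region at 63.8% GC and a 966 bp region at 39% GC,
with a planted 4 bp repeat pair separated by 19 bp (so the slippage
product is a 23 bp deletion) and a planted QP (8 bp arms, 3 bp loop, the
right arm missing an internal dinucleotide).  GC-dependence of slippage
weight is not modelled — the eligibility constraints are knobs, not
mechanistic claims.  All randomness flows from a single seed; identical
seeds give byte-identical cohorts.

## Segregant mapping

Parental-origin tracks are intersected per chromosome: candidate regions
are the maximal intervals every phenotype-positive segregant carries from
the required parent, optionally excluding segments also shared by every
phenotype-negative segregant.  Genotype gaps count as unknown, not as
sharing (conservative).  The operation is deterministic interval
arithmetic — no linkage or LOD computation — matching how a
single-locus trait is localized from a handful of segregants.

## Problem sizes and numerical choices

The test and acceptance runs use: 200 simulated assays × 20 cultures for
estimator recovery; 500-mutant cohorts for classifier recovery (≥ 95%
ground-truth class agreement required; ambiguous multi-call alignments
are counted as misses); 1000 random deletions for the junction oracle;
exhaustive Fisher enumeration for all tables with total ≤ 8 plus a
300-table seeded sample up to total 60; 10 segregants × 5 chromosomes at
20 kb marker resolution for interval recovery.  These sizes are the
package's choices for routine verification; all are parameters.

Root finding uses Brent with a doubling upper bracket; bootstrap
quantiles are percentile-type; display rounding never feeds back into
computation.  Degenerate inputs (all-zero assays, empty regions,
zero-margin tables, overlapping annotations) raise `ValueError` with the
offending quantity named.

## Known limitations

- Per-class CIs are a composite approximation (see above).
- The culture model's power-of-two clone sizes slightly fatten the
  discrete granularity of low counts; rate estimates inherit a small
  negative bias relative to the continuous model.
- The QP scanner does not discover length-defect QPs; they must be
  registered explicitly.
- Junction homology assumes exact repeat identity; mismatched
  ("degenerate") repeats are not scored.
- The alignment tie-break is the aligner's canonical traceback; co-optimal
  alignments with different gap placements are resolved deterministically
  but not configurably (left-normalization downstream removes most of the
  difference).
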