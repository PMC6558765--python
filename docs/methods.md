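# Methods

This note documents the models, algorithms, numerical choices, and
limitations behind `brcakit`.

## Mutation catalogs

Substitutions are classified by the pyrimidine of the mutated base pair and
its two flanking reference bases, giving 6 × 16 = 96 channels ordered
substitution-major (C>A, C>G, C>T, T>A, T>C, T>G), then 5′ flank, then 3′
flank, each alphabetically — the COSMIC convention. Purine-strand records
are reverse-complemented before lookup; the 192 strand representations
collapse 2-to-1 onto the 96 channels, and the test suite verifies this map
exhaustively. Records whose reference triplet contains an ambiguous base
(N) are skipped and counted (real assemblies contain gaps; treating them as
errors would make whole-genome runs brittle); records whose REF disagrees
with the reference triplet are rejected with a diagnostic, since they
indicate coordinate or assembly mismatches.

Sample-level filtering drops samples with total counts strictly below a
threshold (default 1,000), so a sample at exactly the threshold is kept.
Tumor mutational burden is a pure ratio, nonsynonymous count over coding
megabases; annotation of nonsynonymous status and the coding footprint are
taken as user-provided inputs, since burden is a summary statistic here, not
a method under study.

## Background-anchored sparse signatures

The model is M ≈ α₀β₀ + αβ with β₀ fixed. Fitting alternates:

1. **Exposure update** — exact nonnegative least squares per sample against
   the design [β₀; β] (scipy's active-set NNLS, with a shared-Gram fast path
   for rows whose unconstrained solution is already nonnegative).
2. **Signature update** — cyclic nonnegative coordinate descent on
   ‖W ⊙ (M − α₀β₀ − αβ)‖² + λΣ|β| with the closed-form soft-threshold step
   per (signature, channel), vectorized across channels (2 sweeps per outer
   iteration).
3. **Renormalization** — each signature row is rescaled to sum to 1 and the
   compensating factor absorbed into its exposure column (the product αβ,
   and hence the residual, is unchanged).

**Scaling.** The optimization runs on M divided by its mean per-sample
total. On raw counts (thousands of mutations per sample) a penalty weight
of order 0.1 is numerically inert, and worse, a spare component can drift
into a duplicate of the background and absorb its exposures, since
duplicating β₀ is residual-neutral. On the normalized scale the classical
λ grid (0.05–0.15) exerts real shrinkage and background duplication is
suppressed. Exposures are rescaled to mutation counts on output.

**Inactive components.** A row the LASSO shrinks entirely to zero stays
zero, with zero exposure, rather than being reseeded: reseeding re-opens
the background-duplication channel. Consumers should treat the model's
active components (`SignatureModel.active_components`) as the discovered
signatures; at large λ the effective number of signatures can be smaller
than the requested K.

**Monotonicity.** Steps 1 and 2 are exact descent on the penalized
objective; step 3 leaves the residual unchanged but rescales the L1 term,
introducing a per-iteration slack bounded by λ·K (in normalized units;
observed slack is ~10⁻⁵ relative). Convergence is declared when the
relative objective change falls below `tol` (default 10⁻⁵, capped at 200
outer iterations). Initialization is nonnegative double-SVD of the
background-subtracted catalog, with Dirichlet-random restarts (default 5;
best final objective kept).

**Bi-cross-validation.** Each repeat holds out a random ~10% × ~10%
row-by-column block; held-out cells get zero weight during fitting and are
predicted from the fitted factors. The grid records mean and Monte-Carlo
standard error of the held-out MSE per (K, λ). Selection uses the
one-standard-error rule — among cells within one SE of the minimum, the
smallest K and then the largest λ win. The rule matters: a surplus
signature changes held-out error by a noise-level amount (well under 1% in
simulations) while a missing one inflates it severalfold, so a strict
argmin would flip between K and K+1 on noise. Holdout fits use a reduced
iteration budget (30 outer iterations, tol 10⁻³, single start), which
leaves selection unchanged in simulations while keeping a 12-cell × 20-repeat
grid on a 100 × 96 catalog under a minute.

**Exposure refitting** for a fixed signature set is one NNLS pass; cohort
summaries of an exposure table are plain column means, and fractions are
per-sample exposures over row totals.

## SV filtering and classification

The six high-confidence clauses are conjunctive per-variant predicates, so
their order cannot change the survivor set; tallies report the first
failing clause in the documented order. Recurrence removal then drops
variants whose two breakends both match another tumor sample's variant
within ±10 bp (exact matching is configurable; the windowed default
reflects breakend jitter in assembly-based callers), or match any call from
an unmatched normal. Finally, variants with either breakend inside a
germline-CNV panel interval of the same variant class are removed
(class-agnostic overlap is configurable). "MAPQ of supporting reads" is
evaluated against the caller's record-level MAPQ annotation: the toolkit
consumes VCFs, not BAMs.

Orientation convention: a breakend is "+" if sequence left of its position
is retained in the derived allele, "−" otherwise. VCF bracket notation maps
as t[p[ → (+,−), t]p] → (+,+), ]p]t → (−,+), [p[t → (−,−). In coordinate
order, (+,−) is a deletion, (−,+) a tandem duplication, (+,+)/(−,−) an
inversion-type junction; events under 50 bp are indels and interchromosomal
junctions are translocations. Inversions are classified but reported
separately from the three headline classes, whose counts are the usual
cohort comparison.

Microhomology fractions count junction homology lengths inside an inclusive
1–10 bp window, per sample × class × size bin; empty cells are reported as
missing rather than zero so that downstream medians are not dragged toward
zero by samples with no events in a bin. Copy-number-corrected genome size
is Σ segment length × CN/2 — a diploid baseline with chrX included, which
matches a female-genome breast-cancer cohort.

## Breakpoint-enrichment scans

Bins are anchored at coordinate 0 per chromosome, 10 Mb wide with 5 Mb
step, and must fit entirely inside the chromosome; bins with > 25% overlap
with gap regions are excluded from testing, so the Bonferroni factor is the
number of *tested* regions. The bin count is convention-sensitive (the
treatment of chromosome ends is not standardized), so no exact bin count is
asserted anywhere.

Each variant contributes both of its breakend positions as independent
breakpoint events; both may fall in one region. Under the null, the count
in a region of effective length L is Poisson(d·L) with d = total
breakpoints / non-gap genome length (gap-region breakpoints are excluded
from the numerator as well). Copy-number correction replaces L by the
cohort mean of Σ overlap-length × CN/2, with uncovered bases contributing
at baseline ploidy — expected breakpoint counts scale with the DNA content
actually present in the cohort. Adjusted p-values are min(1, raw × number
of tests).

The package ships the published 11-gene worked-example table (gene body
length, pooled breakpoint count, reported adjusted p-values, plain and
CN-corrected) from a 46-tumor BRCA1/2-mutated cohort, together with a 1-D
integer-search calibrator that finds the single Bonferroni factor best
reproducing the reported values (minimax relative error). At the reported
density of 7.36 × 10⁻⁶ breakpoints/bp the calibrated factor is 19,112 —
consistent with a protein-coding gene count — and reproduces all 11
adjusted p-values within 1.2%.

Functional-region enrichment is the upper-tail hypergeometric probability
of the observed number of breakpoints inside an annotation, with the
population partitioned at 1-bp resolution; a binomial variant (success
probability = covered fraction) is provided and agrees within 10% whenever
the population is ≥ 10⁴ times the draw count. Replication-timing tracks are
cut into early/mid/late tertiles of equal covered bases (ties broken by
genomic order; by default higher timing values are "earlier", the Repli-seq
convention, with a flag to flip). Gene-set enrichment is upper-tail
hypergeometric on set overlap. Expression comparisons use the one-sided
Wilcoxon rank-sum test; for small tie-free samples the exact null
distribution is used, otherwise the normal approximation.

## Methylation and power

Per-sample methylation is the mean beta over non-missing probes of one
class; samples with > 50% missing probes in the class are flagged. Group
comparisons use the two-sided Wilcoxon rank-sum test (exact for small
tie-free samples). The power simulation fits per-group Gaussians (sample
mean, sd with ddof = 1; zero-variance groups are rejected as unusable for
simulation), then redraws both groups R = 10,000 times and applies the
rank test at α = 0.05; power is the rejection fraction with its binomial
Monte-Carlo standard error. The test inside the simulation is the Wilcoxon
rank-sum to match the group comparisons it is powering (a t-test option is
provided); "correct result" means rejection when the generating
distributions differ, and the rejection rate under equality is the type-I
error, which calibrates to [0.04, 0.06] at R = 10,000.

## Synthetic data

Every generator takes an explicit seed, is bit-reproducible, and returns a
truth record alongside the data.

- **Catalogs** draw per-sample exposures (background fraction uniform on
  0.3–0.6, remainder split over K sparse signatures by a Dirichlet), then
  channel counts by multinomial sampling at the stated mutations-per-sample
  (Poisson and deterministic-rounding modes are available). Default
  synthetic signatures load 8 random channels each with Dirichlet weights,
  giving the sparse, well-separated structure the method targets. The
  packaged default background is a smooth CpG-deamination-weighted
  spectrum — a synthetic stand-in for a germline mutation spectrum,
  adequate for simulation but not a substitute for an empirically estimated
  background in real analyses.
- **SV call sets** place clean calls uniformly over a 3-chromosome
  (50/40/30 Mb) toy genome, with class mixture, per-class log-normal size
  mixtures (bimodal deletions at ~30 bp and ~2 kb; 1–100 kb tandem
  duplications), per-class microhomology distributions concentrated on
  1–10 bp, and a 16% insertion fraction — the qualitative structure of
  BRCA1/2-mutated cohorts. A configurable number of calls fails exactly one
  filter clause each; recurrent pairs and germline-panel overlaps are
  planted in reserved genome areas that clean calls avoid, and distinct
  calls are kept > 64 bp apart so the windowed recurrence matcher cannot
  collide them — survivor counts are therefore exactly predictable from the
  truth record.
- **Copy-number profiles** tile the toy genome with integer-CN segments
  (default distribution centered on CN 2).
- **Methylation matrices** draw a per-sample level from its group Gaussian
  and add truncated-Gaussian probe noise; the Gaussian-on-beta-scale choice
  deliberately mirrors the power analysis's own model rather than a Beta
  distribution.

What the generators do *not* emulate: real hg19 sequence content, LD or
mutation hotspots, signature catalogs of real cohorts, probe-level
methylation structure (CpG islands, Infinium type-I/II bias), or caller
artifacts beyond the planted clause failures. Passing tests therefore
demonstrate the correctness and calibration of the statistics under their
own model assumptions, not performance on real cohorts.

## Problem sizes used in the checks

The acceptance checks run at the scale a single CPU handles in about a
minute: signature recovery and bi-CV selection on 100-sample × 2,000-mutation
catalogs (10 replicates of a 12-cell grid × 20 repeats), 200 null and 100
planted replicates of the bin scan on the toy genome at 2 × 10⁻⁶
breakpoints/bp, a ~280-call filter run, and 10,000-replicate power
simulations.

## Known limitations

- The sparse factorization is non-convex; different seeds can reach
  different local optima. Restarts mitigate but do not eliminate this.
- Bi-CV holdout blocks are uniform random; stratified holdouts for very
  unbalanced cohorts are not implemented.
- The recurrence filter is O(pairs within a coarse bucket); extremely deep
  multi-sample call sets with clustered breakpoints would need an interval
  index.
- CN-corrected effective lengths average over the cohort; per-sample
  enrichment tests are not provided.
- The published gene table is consumed as printed; its gene-model source
  (and hence body lengths such as TP53's) is not re-derivable, so those
  rows serve as arithmetic worked examples, not as an annotation fixture.
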