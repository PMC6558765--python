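# brcakit

Tools for comparative genomic analysis of BRCA1/2-mutated versus sporadic
breast tumors: background-anchored sparse mutational-signature extraction,
high-confidence somatic structural-variant (SV) filtering and breakend
classification, Poisson breakpoint-enrichment scans, methylation-array group
comparison with simulation-based power analysis, and synthetic-data
generators that make every stage testable without any external downloads.

The package is aimed at cancer-genomics analysts who consume the outputs of
standard callers (SNV tables, SvABA-style breakend VCFs, Control-FREEC-style
copy-number segments, 450K-style beta-value matrices) and want the cohort
statistics around them to be reproducible.

## The models

**Mutational signatures.** Single-base substitutions are tabulated into the
96 trinucleotide channels (pyrimidine-strand substitution × 5′/3′ flanks,
COSMIC ordering), giving a count matrix *M* (samples × 96). *M* is factorized
as

&nbsp;&nbsp;&nbsp;&nbsp;*M* ≈ α₀β₀ + αβ

where β₀ is a **fixed background signature** — the spectrum of replication
errors accrued during normal cell division, assumed present in every tumor —
α₀ its per-sample exposures (mutation counts), β the *K* discovered
signatures (rows on the 96-channel simplex) and α their exposures. β is
estimated under an L1 (LASSO) penalty so that discovered signatures are
sparse and well separated from the dense background. *K* and the penalty
weight λ are chosen by **repeated bi-cross-validation**: a random row-block ×
column-block of *M* is held out, the model is fitted to the remaining cells,
and the held-out block is scored by squared prediction error; selection uses
the one-standard-error rule (smallest *K*, largest λ within one Monte-Carlo
standard error of the grid minimum).

**Structural variants.** Breakend pairs ≥ 50 bp apart (and all
interchromosomal junctions) are SVs; smaller events are indels. Calls pass a
six-clause high-confidence filter — autosomes/chrX only, zero reads in the
matched normal, ≥ 10 tumor reads with ≥ 2 split reads for SVs, QUAL ≥ 30 and
MAPQ ≥ 30, no breakpoint in an assembly gap, both junctions assembled —
followed by removal of variants recurring across tumors or present in
unmatched normals, and of variants overlapping a germline-CNV panel.
Breakend orientation determines the class: (+,−) deletion, (−,+) tandem
duplication, (+,+)/(−,−) inversion, cross-chromosome translocation.
Microhomology (1–10 bp shared sequence at the junction) and untemplated
insertions are profiled per class and size range, and per-tumor genome size
is corrected for copy number as Σ segment-length × CN/2.

**Breakpoint enrichment.** Pooled cohort breakpoints are modeled as uniform
over the non-gap genome at density *d* (breakpoints/bp). For a region of
(copy-number-corrected) length *L*, the count is Poisson(*d·L*); enrichment
is the upper tail P(X ≥ k), Bonferroni-corrected by the number of regions
(10-Mb bins stepped by 5 Mb with gap-heavy bins dropped, or gene bodies).
Functional-region and gene-set enrichment use upper-tail hypergeometric
tests; expression of disrupted genes uses the one-sided Wilcoxon rank-sum
test.

**Methylation and power.** 450K-style beta values (0 = unmethylated,
1 = methylated) are averaged per sample within a probe class, groups are
compared by the two-sided Wilcoxon rank-sum test, and the power of a planned
comparison is estimated by fitting group Gaussians and redrawing both groups
10,000 times, counting rejections at α = 0.05.

## Worked example

```python
from brcakit import simulate
from brcakit.signatures import fit, bi_cross_validate, match_signatures
from brcakit.enrichment import (GENE_BREAKPOINT_EXAMPLES, REPORTED_BREAKPOINT_DENSITY,
                                calibrate_bonferroni_factor, poisson_region_test)

# simulate a cohort of 100 tumors, 2,000 mutations each, from 3 sparse
# signatures plus the packaged background, then select K and refit
cat, truth = simulate.simulate_catalog(
    simulate.CatalogSimSpec(n_samples=100, mutations_per_sample=2000, K=3, seed=1))
res = bi_cross_validate(cat, truth["beta0"], K_grid=[2, 3, 4, 5],
                        lambda_grid=[0.05, 0.10, 0.15], repeats=20, seed=1)
print(f"bi-CV chose K = {res.chosen_K}, lambda = {res.chosen_lambda}")
model = fit(cat, truth["beta0"], K=res.chosen_K, lam=res.chosen_lambda, seed=1)
for t, f, cos in match_signatures(truth["signatures"], model.beta):
    print(f"true signature {t} recovered by component {f}: cosine = {cos:.3f}")

# published breast-tumor gene worked examples: one shared gene-count
# Bonferroni factor reproduces the reported adjusted Poisson p-values
t = GENE_BREAKPOINT_EXAMPLES.set_index("gene")
sub = t.loc[["RB1", "TP53", "PTEN", "ETV6", "KLHL8", "ARGLU1"]]
n = calibrate_bonferroni_factor(sub["length"], sub["breakpoints"], sub["adjusted_p"],
                                REPORTED_BREAKPOINT_DENSITY)
print(f"calibrated gene-count Bonferroni factor: {n}")
raw, adj = poisson_region_test(17, 176159, REPORTED_BREAKPOINT_DENSITY, n)
print(f"RB1: raw p = {raw:.2e}, adjusted p = {adj:.2e}")
```

prints

```
bi-CV chose K = 3, lambda = 0.05
true signature 0 recovered by component 1: cosine = 1.000
true signature 1 recovered by component 2: cosine = 1.000
true signature 2 recovered by component 0: cosine = 1.000
calibrated gene-count Bonferroni factor: 19112
RB1: raw p = 6.85e-14, adjusted p = 1.31e-09
```

Bi-cross-validation recovers the planted number of signatures and each true
signature is matched essentially exactly. The enrichment arithmetic
reproduces the published RB1 result: 17 breakpoints in a 176,159-bp gene at
a cohort density of 7.36 × 10⁻⁶ breakpoints/bp give a Poisson upper tail of
6.85 × 10⁻¹⁴, and multiplying by the calibrated protein-coding gene count
(19,112) yields the reported adjusted p of 1.31 × 10⁻⁹.

A `brcakit` command-line interface wraps the same functions
(`brcakit simulate|catalog|signatures|sv|enrich|meth|run --help`).

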