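"""Poisson breakpoint-enrichment scans and set-enrichment tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brcakit import simulate
from brcakit.enrichment import (
    GENE_BREAKPOINT_EXAMPLES,
    REPORTED_BREAKPOINT_DENSITY,
    calibrate_bonferroni_factor,
    count_breakpoints_in_annotation,
    disrupted_gene_expression_test,
    gene_set_enrichment,
    make_bins,
    poisson_region_test,
    region_class_enrichment,
    replication_timing_tertiles,
    scan_bins,
    scan_genes,
)


# --- bins ------------------------------------------------------------------

def test_bins_on_toy_chromosome():
    bins = make_bins({"chr1": 23_000_000})
    assert len(bins) == 3
    assert list(bins["start"]) == [0, 5_000_000, 10_000_000]
    assert (bins["end"] - bins["start"] == 10_000_000).all()


def test_short_chromosome_gets_no_bins():
    assert len(make_bins({"chr1": 9_000_000})) == 0


def test_gap_heavy_bin_is_excluded():
    gaps = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [3_000_000]})
    bins = make_bins({"chr1": 23_000_000}, gap_regions=gaps)
    assert bool(bins.loc[0, "excluded"])  # 30% gap overlap > 25%
    assert not bins.loc[1:, "excluded"].any()


def test_bins_require_width_greater_than_step():
    with pytest.raises(ValueError):
        make_bins({"chr1": 23_000_000}, width=5_000_000, step=5_000_000)


# --- Poisson test ----------------------------------------------------------

def brute_force_poisson_upper_tail(k: int, lam: float) -> float:
    """Independent oracle: sum the Poisson pmf from k upward until terms
    underflow, in log space."""
    total = 0.0
    i = k
    while True:
        log_term = -lam + i * math.log(lam) - math.lgamma(i + 1)
        term = math.exp(log_term)
        total += term
        if term < total * 1e-18 and i > lam:
            return total
        i += 1


def test_zero_count_gives_unit_pvalue():
    raw, adj = poisson_region_test(0, 1_000, 1e-6, 100)
    assert raw == 1.0 and adj == 1.0


def test_poisson_tail_matches_brute_force_summation():
    lam = REPORTED_BREAKPOINT_DENSITY * 176_159
    oracle = brute_force_poisson_upper_tail(17, lam)
    raw, _ = poisson_region_test(17, 176_159, REPORTED_BREAKPOINT_DENSITY)
    assert raw == pytest.approx(oracle, rel=1e-10)
    assert raw == pytest.approx(6.9e-14, rel=0.02)


def test_published_gene_examples_reproduced_with_one_shared_factor():
    """A single Bonferroni factor reproduces all 11 published adjusted
    p-values simultaneously within 5% relative error."""
    t = GENE_BREAKPOINT_EXAMPLES
    n = calibrate_bonferroni_factor(
        t["length"], t["breakpoints"], t["adjusted_p"], REPORTED_BREAKPOINT_DENSITY
    )
    assert 18_000 <= n <= 20_000  # consistent with a protein-coding gene count
    for _, row in t.iterrows():
        _, adj = poisson_region_test(
            int(row["breakpoints"]), float(row["length"]), REPORTED_BREAKPOINT_DENSITY, n
        )
        assert adj == pytest.approx(row["adjusted_p"], rel=0.05), row["gene"]


def test_adjusted_pvalue_caps_at_one():
    _, adj = poisson_region_test(1, 100_000, REPORTED_BREAKPOINT_DENSITY, 19_000)
    assert adj == 1.0


def test_poisson_monotonicity_in_k_and_length():
    ps = [poisson_region_test(k, 100_000, 1e-5)[0] for k in range(0, 10)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    lams = [poisson_region_test(5, L, 1e-5)[0] for L in (50_000, 100_000, 200_000)]
    assert all(a <= b for a, b in zip(lams, lams[1:]))


def test_poisson_test_input_validation():
    with pytest.raises(ValueError):
        poisson_region_test(-1, 100, 1e-6)
    with pytest.raises(ValueError):
        poisson_region_test(1, 0, 1e-6)


# --- scans -----------------------------------------------------------------

def test_scan_with_no_breakpoints_in_bins_gives_unit_pvalues():
    bins = make_bins({"chr1": 23_000_000})
    bp = pd.DataFrame({"chrom": ["chr2"] * 5, "pos": [10, 20, 30, 40, 50]})
    res = scan_bins(bp, bins, density=1e-6)
    assert (res["breakpoints"] == 0).all()
    assert (res["p_raw"] == 1.0).all()
    assert not res["significant"].any()


def test_planted_bin_attains_minimum_adjusted_p():
    sizes = dict(simulate.TOY_CHROM_SIZES)
    planted = [("chr2", 10_000_000, 20_000_000, 10.0)]
    bp = simulate.simulate_breakpoints(sizes, density=2e-6, planted_regions=planted, seed=1)
    bins = make_bins(sizes)
    res = scan_bins(bp, bp_bins := bins, density=2e-6)
    best = res.iloc[res["p_adjusted"].values.argmin()]
    assert best["chrom"] == "chr2" and best["start"] == 10_000_000
    assert best["significant"]


def test_cn_correction_scales_effective_length():
    sizes = {"chr1": 23_000_000}
    bins = make_bins(sizes)
    bp = pd.DataFrame({"chrom": ["chr1"], "pos": [1_000_000]})
    whole_genome_cn4 = {
        "S1": pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [23_000_000], "cn": [4]})
    }
    plain = scan_bins(bp, bins, density=1e-6)
    corrected = scan_bins(bp, bins, cn_profiles=whole_genome_cn4, density=1e-6)
    np.testing.assert_allclose(
        corrected["effective_length"], 2 * plain["effective_length"]
    )
    # doubled expected length weakens enrichment
    assert (corrected["p_raw"] >= plain["p_raw"]).all()


def test_gene_scan_uses_gene_count_as_bonferroni_factor():
    genes = pd.DataFrame(
        {
            "gene": ["A", "B"],
            "chrom": ["chr1", "chr1"],
            "start": [0, 1_000_000],
            "end": [100_000, 1_200_000],
        }
    )
    bp = pd.DataFrame({"chrom": ["chr1"] * 6, "pos": [10, 20, 30, 40, 50, 60]})
    res = scan_genes(bp, genes, density=1e-6)
    raw, adj = poisson_region_test(6, 100_000, 1e-6, 2)
    assert res.loc[res["region"] == "A", "p_adjusted"].iloc[0] == pytest.approx(adj)
    assert res.loc[res["region"] == "B", "p_adjusted"].iloc[0] == 1.0  # k = 0 capped


def test_gene_scan_rejects_duplicates_and_degenerate_intervals():
    genes = pd.DataFrame(
        {"gene": ["A", "A"], "chrom": ["chr1"] * 2, "start": [0, 10], "end": [5, 20]}
    )
    with pytest.raises(ValueError):
        scan_genes(pd.DataFrame({"chrom": [], "pos": []}), genes)
    genes2 = pd.DataFrame({"gene": ["A"], "chrom": ["chr1"], "start": [10], "end": [10]})
    with pytest.raises(ValueError):
        scan_genes(pd.DataFrame({"chrom": [], "pos": []}), genes2)


# --- annotation enrichment -------------------------------------------------

def binomial_upper_tail(k, n, p):
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def test_region_class_enrichment_binomial_matches_exact_summation():
    oracle = binomial_upper_tail(5, 10, 0.1)
    p = region_class_enrichment(5, 10, 100, 1_000, method="binom")
    assert p == pytest.approx(oracle, rel=1e-12)
    assert p == pytest.approx(1.6e-3, rel=0.05)


def test_region_class_enrichment_edge_cases():
    assert region_class_enrichment(0, 10, 100, 1_000) == 1.0
    assert region_class_enrichment(10, 10, 1_000, 1_000) == 1.0  # annotation = genome
    with pytest.raises(ValueError):
        region_class_enrichment(1, 10, 2_000, 1_000)


def test_hypergeometric_and_binomial_agree_for_large_populations():
    for k, n in [(5, 20), (12, 40)]:
        ph = region_class_enrichment(k, n, 100_000, 1_000_000, method="hypergeom")
        pb = region_class_enrichment(k, n, 100_000, 1_000_000, method="binom")
        assert ph == pytest.approx(pb, rel=0.10)


def test_count_breakpoints_in_annotation():
    ann = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
    bp = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [101, 200, 250]})
    # 1-based pos 101 -> 0-based 100 inside; pos 200 -> 199 inside; 250 outside
    assert count_breakpoints_in_annotation(bp, ann) == 2


def hypergeom_upper_tail(overlap, universe, target, drawn):
    total = math.comb(universe, drawn)
    return sum(
        math.comb(target, i) * math.comb(universe - target, drawn - i)
        for i in range(overlap, min(target, drawn) + 1)
    ) / total


def test_gene_set_enrichment_matches_exact_enumeration():
    universe = {f"g{i}" for i in range(100)}
    target = {f"g{i}" for i in range(10)}
    disrupted = {f"g{i}" for i in range(6)} | {f"g{i}" for i in range(50, 64)}
    assert len(disrupted & target) == 6 and len(disrupted) == 20
    oracle = hypergeom_upper_tail(6, 100, 10, 20)
    p = gene_set_enrichment(disrupted, universe, target)
    assert p == pytest.approx(oracle, rel=1e-10)
    assert p == pytest.approx(4.0e-3, rel=0.15)


def test_gene_set_enrichment_edges():
    universe = {f"g{i}" for i in range(50)}
    target = {f"g{i}" for i in range(5)}
    assert gene_set_enrichment({"g40", "g41"}, universe, target) == 1.0
    p_extreme = gene_set_enrichment(target, universe, target)
    assert p_extreme == pytest.approx(1 / math.comb(50, 5), rel=1e-9)
    with pytest.raises(ValueError):
        gene_set_enrichment(set(), set(), set())


# --- replication timing ----------------------------------------------------

def test_tertiles_one_interval_each():
    track = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "start": [0, 100, 200],
            "end": [100, 200, 300],
            "timing": [1.0, 2.0, 3.0],
        }
    )
    out = replication_timing_tertiles(track)
    by_timing = out.set_index("timing")["category"]
    assert by_timing[3.0] == "early" and by_timing[2.0] == "mid" and by_timing[1.0] == "late"


def test_tertile_boundaries_are_coverage_quantiles():
    rng = np.random.default_rng(0)
    n = 300
    track = pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "start": np.arange(n) * 1000,
            "end": (np.arange(n) + 1) * 1000,
            "timing": np.linspace(0, 1, n) + rng.normal(0, 1e-6, n),
        }
    )
    out = replication_timing_tertiles(track)
    cov = out.groupby("category").apply(
        lambda g: (g["end"] - g["start"]).sum(), include_groups=False
    )
    assert cov.max() - cov.min() <= 1000  # equal thirds to interval granularity
    # highest timing values land in "early"
    assert out.loc[out["timing"].idxmax(), "category"] == "early"


def test_uniform_timing_ties_broken_by_genomic_order():
    track = pd.DataFrame(
        {
            "chrom": ["chr1"] * 6,
            "start": np.arange(6) * 10,
            "end": (np.arange(6) + 1) * 10,
            "timing": [0.5] * 6,
        }
    )
    out = replication_timing_tertiles(track, early_is_high=False)
    assert list(out["category"]) == ["early", "early", "mid", "mid", "late", "late"]


def test_empty_track_raises():
    with pytest.raises(ValueError):
        replication_timing_tertiles(pd.DataFrame())


# --- expression ------------------------------------------------------------

def test_expression_test_extreme_configuration_is_exact():
    expr = pd.Series(
        np.concatenate([np.arange(10, 20), np.arange(10)]),
        index=[f"g{i}" for i in range(20)],
        dtype=float,
    )
    disrupted = {f"g{i}" for i in range(10)}  # all higher-expressed
    _, p = disrupted_gene_expression_test(disrupted, expr)
    assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-9)


def test_expression_test_single_swap_increases_p():
    vals = np.concatenate([np.arange(10, 20), np.arange(10)]).astype(float)
    expr = pd.Series(vals, index=[f"g{i}" for i in range(20)])
    extreme = disrupted_gene_expression_test({f"g{i}" for i in range(10)}, expr)[1]
    swapped = disrupted_gene_expression_test(
        {f"g{i}" for i in range(9)} | {"g10"}, expr
    )[1]
    assert swapped > extreme


def test_expression_test_requires_both_groups():
    expr = pd.Series([1.0, 2.0], index=["a", "b"])
    with pytest.raises(ValueError):
        disrupted_gene_expression_test({"a", "b"}, expr)
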