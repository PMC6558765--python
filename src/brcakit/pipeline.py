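"""End-to-end orchestration and cohort-level group statistics.

``run_pipeline`` executes the configured stages — catalog construction and
signature refitting, SV filtering/classification, breakpoint-enrichment
scans, methylation summaries — on files produced by the simulators or by
upstream callers, writing every artifact plus a manifest of the parameters
and seeds used.  Re-running with the same inputs and seed is byte-identical.

``group_stats`` compares a per-sample statistic between named group pairs
with the two-sided Wilcoxon rank-sum test (uncorrected by default; raw
p-values are what cohort comparisons of this kind conventionally report).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import catalog as catalog_mod
from . import enrichment, methylation, signatures, sv

logger = logging.getLogger(__name__)

GROUP_VOCABULARY = ("BRCA1", "BRCA2", "sporadic-TN", "ER+", "HER2+", "normal")


def validate_sample_sheet(groups: pd.Series, vocabulary=GROUP_VOCABULARY) -> None:
    if groups.index.duplicated().any():
        raise ValueError("sample ids must be unique")
    unknown = sorted(set(groups) - set(vocabulary))
    if unknown:
        raise ValueError(f"unknown group label(s): {unknown}")


def group_stats(
    values: pd.Series,
    groups: pd.Series,
    comparisons: list[tuple[str, str]],
    adjust: str | None = None,
) -> pd.DataFrame:
    """Two-sided rank-sum p-values and medians for a list of group pairs."""
    rows = []
    for a, b in comparisons:
        va = values[groups[values.index] == a].dropna()
        vb = values[groups[values.index] == b].dropna()
        if len(va) < 2 or len(vb) < 2:
            raise ValueError(f"group {a if len(va) < 2 else b!r} too small for comparison")
        pooled = np.concatenate([va.to_numpy(), vb.to_numpy()])
        method = (
            "exact"
            if min(len(va), len(vb)) <= 25 and len(np.unique(pooled)) == len(pooled)
            else "asymptotic"
        )
        res = stats.mannwhitneyu(va, vb, alternative="two-sided", method=method)
        rows.append(
            {
                "group_a": a, "group_b": b, "n_a": len(va), "n_b": len(vb),
                "median_a": float(va.median()), "median_b": float(vb.median()),
                "direction": "a>b" if va.median() > vb.median() else (
                    "a<b" if va.median() < vb.median() else "a=b"
                ),
                "statistic": float(res.statistic), "p": float(res.pvalue),
            }
        )
    df = pd.DataFrame.from_records(rows)
    if adjust == "bonferroni" and len(df):
        df["p_adjusted"] = (df["p"] * len(df)).clip(upper=1.0)
    elif adjust not in (None, "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the configured stages and write tables plus a manifest.

    ``config`` keys (all optional; a stage runs when its inputs are given):

    - ``snv_table``, ``reference_fasta``: build and filter the 96-channel
      catalog; with ``signature_table`` also refit exposures.
    - ``sv_calls``: apply the high-confidence filter (with optional
      ``gap_bed``, ``dgv_bed``) and summarize classes.
    - ``breakpoint_table`` (or the filtered SV survivors), ``chrom_sizes``:
      bin and gene enrichment scans; optional ``cn_segments`` per sample.
    - ``beta_matrix``, ``probe_manifest``, ``sample_sheet``: methylation
      summaries and group comparison.
    - ``seed``: recorded in the manifest and passed to stochastic stages.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: str(v) for k, v in config.items()}, "outputs": []}
    seed = int(config.get("seed", 0))

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"].append(name)

    if "snv_table" in config:
        if "reference_fasta" not in config:
            raise FileNotFoundError("snv stage requires reference_fasta")
        import pyfaidx

        records = catalog_mod.read_snv_table(config["snv_table"])
        ref = pyfaidx.Fasta(str(config["reference_fasta"]))
        cat = catalog_mod.build_catalog(records, ref)
        cat = catalog_mod.filter_low_count_samples(
            cat, int(config.get("min_total_mutations", 1000))
        )
        catalog_mod.write_catalog(cat, outdir / "catalog.tsv")
        manifest["outputs"].append("catalog.tsv")
        if "signature_table" in config and len(cat):
            sig_df = pd.read_csv(config["signature_table"], sep="\t", index_col=0)
            beta0 = sig_df.loc["background"].to_numpy()
            fixed = sig_df.drop(index="background")
            summary = signatures.refit_exposures(
                cat, beta0, fixed.to_numpy(), names=list(fixed.index)
            )
            summary.exposures.to_csv(outdir / "exposures.tsv", sep="\t", index_label="sample")
            manifest["outputs"].append("exposures.tsv")

    survivors = None
    if "sv_calls" in config:
        calls = sv.read_call_table(config["sv_calls"])
        gap = pd.read_csv(config["gap_bed"], sep="\t", header=None) if "gap_bed" in config else None
        dgv = pd.read_csv(config["dgv_bed"], sep="\t", header=None) if "dgv_bed" in config else None
        report = sv.apply_high_confidence_filter(calls, dgv_panel=dgv, gap_regions=gap)
        survivors = report.survivors
        logger.info(
            "SV filter: %d/%d survivors; clause failures %s; recurrence %d; panel %d",
            report.n_survivors, report.n_input, report.clause_failures,
            report.recurrence_removed, report.dgv_removed,
        )
        sv.write_call_table(survivors, outdir / "sv_filtered.tsv")
        manifest["outputs"].append("sv_filtered.tsv")
        _write(sv.summarize_samples(survivors), "sv_summary.tsv")
        manifest["sv_filter"] = {
            "n_input": report.n_input,
            "n_survivors": report.n_survivors,
            "clause_failures": report.clause_failures,
            "recurrence_removed": report.recurrence_removed,
            "dgv_removed": report.dgv_removed,
        }

    bp = None
    if "breakpoint_table" in config:
        bp = pd.read_csv(config["breakpoint_table"], sep="\t")
    elif survivors is not None:
        bp = pd.DataFrame(
            [{"chrom": c, "pos": p} for call in survivors for c, p in call.breakpoints]
        )
    if bp is not None and "chrom_sizes" in config:
        sizes_df = pd.read_csv(config["chrom_sizes"], sep="\t", header=None)
        sizes = dict(zip(sizes_df[0].astype(str), sizes_df[1].astype(int)))
        gap = pd.read_csv(config["gap_bed"], sep="\t", header=None) if "gap_bed" in config else None
        bins = enrichment.make_bins(sizes, gap_regions=gap)
        cn_profiles = None
        if "cn_segments" in config:
            seg = sv.read_cn_segments(config["cn_segments"])
            if "sample" in seg.columns:
                cn_profiles = {s: g.drop(columns="sample") for s, g in seg.groupby("sample")}
            else:
                cn_profiles = {"cohort": seg}
        nongap = sum(sizes.values())
        if gap is not None:
            nongap -= int((gap[2] - gap[1]).sum())
        scan = enrichment.scan_bins(
            bp, bins, cn_profiles=cn_profiles,
            density=config.get("density"), nongap_genome_length=nongap,
        )
        _write(scan, "bin_enrichment.tsv")
        plotdata = scan.assign(midpoint=(scan["start"] + scan["end"]) // 2)[
            ["chrom", "midpoint", "p_adjusted"]
        ]
        _write(plotdata, "bin_enrichment_plotdata.tsv")

    if "beta_matrix" in config:
        beta = methylation.read_beta_matrix(config["beta_matrix"])
        probe_class = methylation.read_probe_manifest(config["probe_manifest"])
        groups = methylation.read_sample_sheet(config["sample_sheet"])
        validate_sample_sheet(groups)
        means = methylation.sample_mean_beta(beta, probe_class, "CpG")
        means_df = means.rename("mean_beta").rename_axis("sample").reset_index()
        _write(means_df, "methylation_means.tsv")
        pairs = config.get("comparisons")
        if pairs:
            _write(group_stats(means, groups, [tuple(p) for p in pairs]), "methylation_tests.tsv")

    manifest["seed"] = seed
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest_outputs = manifest["outputs"]
    logger.info("pipeline wrote %d artifacts to %s", len(manifest_outputs), outdir)
    return manifest
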