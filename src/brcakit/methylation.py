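"""Methylation-array summaries, group comparison, and power analysis.

Beta values (0 = fully unmethylated, 1 = fully methylated) from a 450K-style
array are aggregated to a per-sample mean within a probe class (CpG or CpA),
groups are compared with the two-sided Wilcoxon rank-sum test, and the power
of a planned comparison is estimated by Monte-Carlo simulation: fit Gaussians
to the observed groups, repeatedly redraw both groups from those Gaussians,
and report the fraction of replicates in which the test rejects at alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PROBE_CLASSES = ("CpG", "CpA")


def sample_mean_beta(
    beta: pd.DataFrame, probe_class: pd.Series, which: str = "CpG"
) -> pd.Series:
    """Per-sample mean beta over probes of one class (missing values excluded).

    ``beta`` is probes x samples; ``probe_class`` labels each probe.
    Samples with more than 50% missing probes in the class are flagged in
    the log but still summarized.
    """
    sel = probe_class.reindex(beta.index) == which
    if not sel.any():
        raise ValueError(f"no probes of class {which!r}")
    sub = beta.loc[sel]
    if ((sub < -1e-9) | (sub > 1 + 1e-9)).any().any():
        raise ValueError("beta values must lie in [0, 1]")
    missing_frac = sub.isna().mean(axis=0)
    flagged = missing_frac[missing_frac > 0.5]
    for s, f in flagged.items():
        logger.warning("sample %s has %.0f%% missing %s probes", s, 100 * f, which)
    return sub.mean(axis=0, skipna=True)


def group_compare(
    values: pd.Series, groups: pd.Series, pair: tuple[str, str]
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of one group pair.

    Returns the test statistic and p-value together with group medians and
    the direction of the difference.
    """
    a, b = pair
    va = values[groups[values.index] == a].dropna()
    vb = values[groups[values.index] == b].dropna()
    if len(va) < 2 or len(vb) < 2:
        raise ValueError(f"each group needs >= 2 samples ({a}: {len(va)}, {b}: {len(vb)})")
    res = stats.mannwhitneyu(va, vb, alternative="two-sided")
    return {
        "group_a": a,
        "group_b": b,
        "n_a": len(va),
        "n_b": len(vb),
        "median_a": float(va.median()),
        "median_b": float(vb.median()),
        "direction": "a>b" if va.median() > vb.median() else ("a<b" if va.median() < vb.median() else "a=b"),
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
    }


def estimate_group_gaussians(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group sample mean and standard deviation (ddof=1).

    Degenerate groups (sd == 0), unusable for simulation, raise a diagnostic.
    """
    rows = []
    for g, v in values.groupby(groups[values.index]):
        v = v.dropna()
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        sd = float(v.std(ddof=1))
        if sd <= 0:
            raise ValueError(f"group {g!r} has zero variance; cannot simulate from it")
        rows.append({"group": g, "mean": float(v.mean()), "sd": sd, "n": len(v)})
    return pd.DataFrame.from_records(rows).set_index("group")


@dataclass
class PowerSimConfig:
    """Two-group Gaussian power-simulation settings."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    replicates: int = 10_000
    alpha: float = 0.05
    test: str = "wilcoxon"  # or "ttest"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_a <= 0 or self.sd_b <= 0:
            raise ValueError("standard deviations must be > 0")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("group sizes must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.test not in ("wilcoxon", "ttest"):
            raise ValueError("test must be 'wilcoxon' or 'ttest'")


@dataclass
class PowerResult:
    power: float
    mc_standard_error: float
    replicates: int
    config: PowerSimConfig = field(repr=False)


def simulate_power(config: PowerSimConfig) -> PowerResult:
    """Monte-Carlo power of the two-group comparison.

    Each replicate draws both groups from their Gaussians and applies the
    configured two-sided test at ``alpha``; power is the rejection fraction.
    Bit-reproducible under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    R = config.replicates
    xa = rng.normal(config.mean_a, config.sd_a, size=(R, config.n_a))
    xb = rng.normal(config.mean_b, config.sd_b, size=(R, config.n_b))
    if config.test == "ttest":
        res = stats.ttest_ind(xa, xb, axis=1)
        pvals = res.pvalue
    else:
        res = stats.mannwhitneyu(xa, xb, axis=1, alternative="two-sided")
        pvals = res.pvalue
    rejections = int((pvals < config.alpha).sum())
    power = rejections / R
    se = float(np.sqrt(power * (1 - power) / R))
    return PowerResult(power=power, mc_standard_error=se, replicates=R, config=config)


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probes x samples beta-value matrix (TSV, probe ids in column 0)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_probe_manifest(path) -> pd.Series:
    """Read a probe manifest (probe id, class) into a Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_sample_sheet(path) -> pd.Series:
    """Read a sample sheet (sample id, group) into a Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]
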