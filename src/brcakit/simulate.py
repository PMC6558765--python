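"""Synthetic data generators for every pipeline input.

Each generator is deterministic under a fixed seed and returns a
machine-readable truth record alongside the data, so that downstream
recovery can be checked: mutation catalogs drawn from known signatures plus
a fixed background, SV call sets with planted per-clause filter failures and
per-region breakpoint enrichment, copy-number segment profiles, and
two-group truncated-Gaussian beta-value matrices.

The default toy genome has 3 chromosomes of 50/40/30 Mb — large enough for
10-Mb binning, small enough for seconds-scale runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import CHANNELS
from .signatures import default_background
from .sv import SVCall

logger = logging.getLogger(__name__)

TOY_CHROM_SIZES: dict[str, int] = {
    "chr1": 50_000_000,
    "chr2": 40_000_000,
    "chr3": 30_000_000,
}


# ---------------------------------------------------------------------------
# mutation catalogs
# ---------------------------------------------------------------------------

def default_signatures(K: int = 3, seed: int = 0, n_active: int = 8) -> np.ndarray:
    """K sparse synthetic signatures: each loads on ``n_active`` random
    channels with Dirichlet weights, rows summing to 1, disjointly seeded so
    signatures are well separated."""
    rng = np.random.default_rng(seed)
    sigs = np.zeros((K, 96))
    channels = rng.permutation(96)
    for k in range(K):
        active = channels[k * n_active : (k + 1) * n_active]
        sigs[k, active] = rng.dirichlet(np.ones(n_active) * 2.0)
    return sigs


@dataclass
class CatalogSimSpec:
    """Generative settings for a synthetic mutation catalog."""

    n_samples: int = 100
    mutations_per_sample: int = 2000
    K: int = 3
    background_fraction: tuple[float, float] = (0.3, 0.6)  # uniform range per sample
    noise: str = "multinomial"  # multinomial | poisson | none
    seed: int = 0
    signatures: np.ndarray | None = None   # (K, 96); generated when None
    beta0: np.ndarray | None = None        # (96,); packaged default when None

    def __post_init__(self) -> None:
        if self.mutations_per_sample < 1:
            raise ValueError("mutations_per_sample must be >= 1")
        if self.noise not in ("multinomial", "poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not 0 <= self.background_fraction[0] <= self.background_fraction[1] <= 1:
            raise ValueError("background_fraction must be an ordered pair in [0, 1]")


def simulate_catalog(spec: CatalogSimSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a samples x 96 catalog from alpha0 beta0 + alpha beta.

    Per sample the expected channel intensity is the exposure-weighted mixture
    of background and signatures; counts are drawn per the noise model
    (``none`` rounds the expectation deterministically).  The truth record
    carries the signatures, beta0, and exposure matrices.
    """
    rng = np.random.default_rng(spec.seed)
    beta0 = spec.beta0 if spec.beta0 is not None else default_background()
    beta0 = np.asarray(beta0, float)
    sigs = (
        np.asarray(spec.signatures, float)
        if spec.signatures is not None
        else default_signatures(spec.K, seed=spec.seed)
    )
    K = sigs.shape[0]
    if sigs.shape[1] != 96 or not np.allclose(sigs.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("signatures must be (K, 96) rows summing to 1")
    n, m = spec.n_samples, spec.mutations_per_sample
    bg_frac = rng.uniform(*spec.background_fraction, size=n)
    alpha0 = bg_frac * m
    sig_weights = rng.dirichlet(np.ones(K), size=n)
    alpha = (1 - bg_frac)[:, None] * m * sig_weights
    expected = np.outer(alpha0, beta0) + alpha @ sigs

    if spec.noise == "multinomial":
        counts = np.vstack(
            [rng.multinomial(m, expected[i] / expected[i].sum()) for i in range(n)]
        )
    elif spec.noise == "poisson":
        counts = rng.poisson(expected)
    else:
        counts = np.rint(expected).astype(np.int64)

    catalog = pd.DataFrame(
        counts,
        index=pd.Index([f"S{i:03d}" for i in range(n)], name="sample"),
        columns=list(CHANNELS),
    )
    truth = {
        "beta0": beta0,
        "signatures": sigs,
        "alpha0": alpha0,
        "alpha": alpha,
        "noise": spec.noise,
        "seed": spec.seed,
    }
    return catalog, truth


# ---------------------------------------------------------------------------
# breakpoints and SV call sets
# ---------------------------------------------------------------------------

def simulate_breakpoints(
    chrom_sizes: dict[str, int] | None = None,
    density: float = 2e-6,
    planted_regions: list[tuple[str, int, int, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson breakpoint positions: uniform at ``density`` per bp, with
    rate multiplied by the fold factor inside each planted (chrom, start,
    end, fold) region.  Returns a table (chrom, pos) with 1-based positions.
    """
    sizes = chrom_sizes or TOY_CHROM_SIZES
    rng = np.random.default_rng(seed)
    planted = planted_regions or []
    for chrom, start, end, fold in planted:
        if chrom not in sizes or start < 0 or end > sizes[chrom]:
            raise ValueError(f"planted region {chrom}:{start}-{end} outside the genome")
        if fold < 1:
            raise ValueError("fold enrichment must be >= 1")
    rows = []
    for chrom, size in sizes.items():
        n = rng.poisson(density * size)
        pos = rng.integers(1, size + 1, size=n)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
        for pchrom, start, end, fold in planted:
            if pchrom != chrom or fold <= 1:
                continue
            extra = rng.poisson(density * (fold - 1) * (end - start))
            epos = rng.integers(start + 1, end + 1, size=extra)
            rows.append(pd.DataFrame({"chrom": chrom, "pos": epos}))
    return pd.concat(rows, ignore_index=True).sort_values(["chrom", "pos"]).reset_index(drop=True)


@dataclass
class SVSimSpec:
    """Generative settings for a synthetic somatic SV/indel call set.

    ``clause_failures`` plants calls that fail exactly one filter clause
    each; ``n_recurrent_pairs`` plants identical variants in two tumor
    samples; ``n_dgv`` plants calls inside the emitted germline-CNV panel.
    Gap regions and the panel occupy reserved genome areas that clean calls
    avoid, so survivor counts are exactly predictable.
    """

    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(TOY_CHROM_SIZES))
    n_samples: int = 10
    n_pass: int = 200
    clause_failures: dict[str, int] = field(
        default_factory=lambda: {
            "chromosomes": 10, "normal_support": 10, "tumor_support": 10,
            "quality": 10, "gap_region": 10, "assembled": 10,
        }
    )
    n_recurrent_pairs: int = 5
    n_dgv: int = 8
    class_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "deletion": 0.35, "tandem_duplication": 0.25, "inversion": 0.05,
            "interchromosomal_translocation": 0.15, "small_indel": 0.20,
        }
    )
    # per-class log10-size mixture components: (weight, mean, sd)
    size_mixtures: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {
            "deletion": [(0.5, 1.5, 0.3), (0.5, 3.3, 0.4)],   # bimodal: ~30 bp and ~2 kb
            "tandem_duplication": [(1.0, 4.0, 0.4)],           # 1-100 kb
            "inversion": [(1.0, 4.0, 0.5)],
            "small_indel": [(1.0, 0.5, 0.3)],                  # < 50 bp
        }
    )
    # per-class microhomology length distribution over 0..12 bp
    microhomology_probs: dict[str, np.ndarray] = field(default_factory=dict)
    insertion_fraction: float = 0.16
    planted_regions: list[tuple[str, int, int, float]] = field(default_factory=list)
    baseline_density: float = 1e-6  # breakends per bp for clean calls
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mixture.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError("class mixture proportions must sum to 1")
        if not self.microhomology_probs:
            # default: deletions/dups/translocations mostly 1-10 bp, indels mostly none
            mh = np.zeros(13)
            mh[0] = 0.25
            mh[1:11] = 0.07
            mh[11:] = 0.025
            flat = np.zeros(13)
            flat[0] = 0.8
            flat[1:5] = 0.05
            self.microhomology_probs = {
                "deletion": mh / mh.sum(),
                "tandem_duplication": mh / mh.sum(),
                "interchromosomal_translocation": mh / mh.sum(),
                "inversion": mh / mh.sum(),
                "small_indel": flat / flat.sum(),
            }


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length)) if length > 0 else ""


def _orientations(rng: np.random.Generator, cls: str) -> tuple[str, str]:
    if cls in ("deletion", "small_indel"):
        return "+", "-"
    if cls == "tandem_duplication":
        return "-", "+"
    if cls == "inversion":
        return ("+", "+") if rng.random() < 0.5 else ("-", "-")
    return rng.choice(["+", "-"]), rng.choice(["+", "-"])


def simulate_sv_callset(spec: SVSimSpec) -> tuple[list[SVCall], dict]:
    """Generate a multi-sample somatic call set with planted structure.

    Returns (calls, truth).  The truth record contains the expected
    high-confidence survivor count, the per-clause planted failure counts,
    the gap-region and germline-CNV-panel BED tables the calls were planted
    against, the planted enrichment regions, and per-class generative
    parameters.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = dict(spec.chrom_sizes)
    chroms = list(sizes)
    samples = [f"T{i:02d}" for i in range(spec.n_samples)]

    # reserved areas: gaps in the last 2 Mb of the last chromosome, the
    # germline-CNV panel in the last 2 Mb of the first chromosome
    last, first = chroms[-1], chroms[0]
    gap_regions = pd.DataFrame(
        {"chrom": [last], "start": [sizes[last] - 2_000_000], "end": [sizes[last]]}
    )
    dgv_start = sizes[first] - 2_000_000
    dgv_panel = pd.DataFrame(
        {
            "chrom": [first] * 4,
            "start": [dgv_start + i * 500_000 for i in range(4)],
            "end": [dgv_start + (i + 1) * 500_000 for i in range(4)],
            "variant_class": ["deletion", "tandem_duplication", "deletion", "inversion"],
        }
    )
    reserved = {(last, sizes[last] - 2_000_000, sizes[last]), (first, dgv_start, sizes[first])}

    for chrom, start, end, fold in spec.planted_regions:
        if chrom not in sizes or start < 0 or end > sizes[chrom]:
            raise ValueError(f"planted region {chrom}:{start}-{end} outside the toy genome")

    def in_reserved(chrom: str, pos: int) -> bool:
        return any(c == chrom and s < pos <= e for c, s, e in reserved)

    fold_lookup = [
        (c, s, e, f) for c, s, e, f in spec.planted_regions if f > 1
    ]

    def sample_pos1() -> tuple[str, int]:
        # chromosome by length, position uniform, planted folds via rejection-free
        # mixture: with probability proportional to extra mass, draw inside a
        # planted region
        total_len = sum(sizes.values())
        extra = [(c, s, e, f) for c, s, e, f in fold_lookup]
        extra_mass = sum((f - 1) * (e - s) for _, s, e, f in extra)
        while True:
            u = rng.random() * (total_len + extra_mass)
            if u < total_len:
                chosen = None
                for c in chroms:
                    if u < sizes[c]:
                        chosen = c
                        break
                    u -= sizes[c]
                pos = int(u) + 1
                if chosen is None or in_reserved(chosen, pos):
                    continue
                return chosen, pos
            u -= total_len
            for c, s, e, f in extra:
                m = (f - 1) * (e - s)
                if u < m:
                    return c, s + 1 + int(u / (f - 1))
                u -= m

    classes = list(spec.class_mixture)
    probs = np.array([spec.class_mixture[c] for c in classes])

    def draw_size(cls: str) -> int:
        comps = spec.size_mixtures[cls]
        w = np.array([c[0] for c in comps])
        i = rng.choice(len(comps), p=w / w.sum())
        _, mu, sd = comps[i]
        size = int(round(10 ** rng.normal(mu, sd)))
        if cls == "small_indel":
            return int(np.clip(size, 1, 49))
        return max(50, size)

    used_positions: set[tuple[str, int]] = set()

    def _near_used(chrom: str, pos: int) -> bool:
        # 64-bp buckets with neighbor check keep distinct calls > 64 bp apart,
        # comfortably beyond the 10 bp recurrence-matching tolerance
        return any((chrom, pos // 64 + d) in used_positions for d in (-1, 0, 1))

    def make_call(
        sample: str,
        cls: str | None = None,
        pos1: tuple[str, int] | None = None,
        allow_reserved: bool = False,
    ) -> SVCall:
        cls = cls or classes[rng.choice(len(classes), p=probs)]
        for _ in range(100):
            c1, p1 = pos1 or sample_pos1()
            if cls == "interchromosomal_translocation":
                c2 = rng.choice([c for c in chroms if c != c1])
                p2 = int(rng.integers(1, sizes[c2] + 1))
                if in_reserved(c2, p2) and not allow_reserved:
                    continue
                size = None
            else:
                c2 = c1
                size = draw_size(cls)
                p2 = p1 + size
                if p2 > sizes[c2] or (in_reserved(c2, p2) and not allow_reserved):
                    continue
            if (_near_used(c1, p1) or _near_used(c2, p2)) and pos1 is None:
                continue
            used_positions.update([(c1, p1 // 64), (c2, p2 // 64)])
            o1, o2 = _orientations(rng, cls)
            mh_probs = spec.microhomology_probs[cls]
            mh_len = int(rng.choice(len(mh_probs), p=mh_probs))
            ins = _random_seq(rng, int(rng.integers(1, 20))) if (
                cls != "small_indel" and rng.random() < spec.insertion_fraction
            ) else ""
            support = 10 + int(rng.poisson(15))
            split = min(support, 2 + int(rng.poisson(5)))
            return SVCall(
                sample_id=sample,
                chrom1=c1, pos1=p1, orient1=o1,
                chrom2=c2, pos2=p2, orient2=o2,
                qual=30.0 + float(rng.exponential(40)),
                mapq=int(rng.integers(30, 61)),
                tumor_support=support, tumor_split=split, normal_support=0,
                homology_seq=_random_seq(rng, mh_len), insertion_seq=ins,
                junctions_assembled=(True, True),
            )
        raise RuntimeError("could not place a call; genome too crowded")

    calls: list[SVCall] = []
    for _ in range(spec.n_pass):
        calls.append(make_call(rng.choice(samples)))

    # per-clause planted failures (each fails exactly one clause)
    from dataclasses import replace as _replace

    for clause, n_fail in spec.clause_failures.items():
        for _ in range(n_fail):
            base = make_call(rng.choice(samples))
            if clause == "chromosomes":
                bad = _replace(base, chrom1="chrY", chrom2="chrY", pos2=base.pos1 + (base.size or 100))
            elif clause == "normal_support":
                bad = _replace(base, normal_support=1 + int(rng.integers(0, 5)))
            elif clause == "tumor_support":
                if base.is_sv and rng.random() < 0.5:
                    bad = _replace(base, tumor_split=int(rng.integers(0, 2)))
                else:
                    t = int(rng.integers(0, 10))
                    bad = _replace(base, tumor_support=t, tumor_split=min(t, base.tumor_split))
            elif clause == "quality":
                if rng.random() < 0.5:
                    bad = _replace(base, qual=float(rng.uniform(0, 29.5)))
                else:
                    bad = _replace(base, mapq=int(rng.integers(0, 30)))
            elif clause == "gap_region":
                gpos = int(rng.integers(sizes[last] - 2_000_000 + 1, sizes[last] - 100_000))
                bad = _replace(base, chrom1=last, pos1=gpos, chrom2=last, pos2=gpos + (base.size or 5000))
            elif clause == "assembled":
                bad = _replace(base, junctions_assembled=(True, False))
            else:
                raise ValueError(f"unknown clause {clause!r}")
            calls.append(bad)

    # recurrent variants: the same junction in two different tumors
    for _ in range(spec.n_recurrent_pairs):
        s1, s2 = rng.choice(samples, size=2, replace=False)
        a = make_call(s1)
        jitter = int(rng.integers(-5, 6))
        b = _replace(a, sample_id=s2, pos1=max(1, a.pos1 + jitter), pos2=max(1, a.pos2 + jitter))
        calls.extend([a, b])

    # calls overlapping the germline-CNV panel (class-matched)
    for _ in range(spec.n_dgv):
        row = dgv_panel.iloc[int(rng.integers(0, len(dgv_panel)))]
        cls = row["variant_class"]
        p1 = int(rng.integers(row["start"] + 1, row["end"] - 200_000))
        dgv_call = make_call(
            rng.choice(samples), cls=cls, pos1=(row["chrom"], p1), allow_reserved=True
        )
        calls.append(dgv_call)

    order = rng.permutation(len(calls))
    calls = [calls[i] for i in order]

    truth = {
        "expected_survivors": spec.n_pass,
        "clause_failures": dict(spec.clause_failures),
        "n_recurrent_removed": 2 * spec.n_recurrent_pairs,
        "n_dgv_removed": spec.n_dgv,
        "gap_regions": gap_regions,
        "dgv_panel": dgv_panel,
        "planted_regions": list(spec.planted_regions),
        "class_mixture": dict(spec.class_mixture),
        "insertion_fraction": spec.insertion_fraction,
        "seed": spec.seed,
    }
    return calls, truth


# ---------------------------------------------------------------------------
# copy-number profiles
# ---------------------------------------------------------------------------

def simulate_cn_profile(
    chrom_sizes: dict[str, int] | None = None,
    n_segments: int = 20,
    cn_values: tuple[int, ...] = (0, 1, 2, 3, 4),
    cn_probs: tuple[float, ...] = (0.02, 0.13, 0.6, 0.15, 0.1),
    seed: int = 0,
) -> pd.DataFrame:
    """Non-overlapping integer-CN segments tiling the toy genome."""
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    sizes = chrom_sizes or TOY_CHROM_SIZES
    rng = np.random.default_rng(seed)
    total = sum(sizes.values())
    rows = []
    for chrom, size in sizes.items():
        k = max(1, int(round(n_segments * size / total)))
        cuts = np.sort(rng.choice(np.arange(1, size), size=k - 1, replace=False)) if k > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [size]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            cn = int(rng.choice(cn_values, p=cn_probs))
            rows.append({"chrom": chrom, "start": int(s), "end": int(e), "copy_number": cn})
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# methylation matrices
# ---------------------------------------------------------------------------

@dataclass
class MethSimSpec:
    """Two-or-more-group truncated-Gaussian beta-value matrix settings.

    ``groups`` maps label -> (mean, sd, n) on the beta scale; the sd is the
    across-sample spread of the per-sample methylation level.  ``probe_sd``
    is additional probe-level noise around each sample's level.
    """

    groups: dict[str, tuple[float, float, int]] = field(
        default_factory=lambda: {
            "BRCA1": (0.35, 0.05, 20),
            "sporadic-TN": (0.40, 0.05, 20),
        }
    )
    n_probes: dict[str, int] = field(default_factory=lambda: {"CpG": 300, "CpA": 50})
    probe_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for g, (m, s, n) in self.groups.items():
            if not 0 < m < 1:
                raise ValueError(f"group {g!r}: mean must be in (0, 1)")
            if s <= 0:
                raise ValueError(f"group {g!r}: sd must be > 0")
            if n < 2:
                raise ValueError(f"group {g!r}: n must be >= 2")


def simulate_methylation(spec: MethSimSpec) -> tuple[pd.DataFrame, pd.Series, pd.Series, dict]:
    """Draw a probes x samples beta matrix with group structure.

    Per sample, a methylation level is drawn from its group Gaussian; per
    probe, beta = level + Gaussian probe noise, truncated to [0, 1].
    Returns (beta, probe_class, groups, truth).
    """
    rng = np.random.default_rng(spec.seed)
    probe_ids, probe_cls = [], []
    for cls, n in spec.n_probes.items():
        probe_ids += [f"{cls.lower()}_{i:05d}" for i in range(n)]
        probe_cls += [cls] * n
    probe_class = pd.Series(probe_cls, index=probe_ids, name="probe_class")

    cols, labels, levels = [], [], []
    for g, (mean, sd, n) in spec.groups.items():
        for i in range(n):
            cols.append(f"{g}_{i:03d}")
            labels.append(g)
            levels.append(rng.normal(mean, sd))
    levels = np.clip(np.asarray(levels), 0.0, 1.0)
    noise = rng.normal(0.0, spec.probe_sd, size=(len(probe_ids), len(cols)))
    beta = np.clip(levels[None, :] + noise, 0.0, 1.0)
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=cols)
    groups = pd.Series(labels, index=cols, name="group")
    truth = {"sample_levels": dict(zip(cols, levels)), "spec_groups": dict(spec.groups), "seed": spec.seed}
    return beta_df, probe_class, groups, truth
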