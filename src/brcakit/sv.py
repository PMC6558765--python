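"""Somatic structural-variant and indel toolkit.

Consumes assembly-based somatic breakend calls (SvABA-style VCFs or long
tables), applies a six-clause high-confidence filter followed by
cross-sample recurrence and germline-CNV-panel removal, classifies calls
into indels and SV types from breakend geometry, and summarizes sizes,
breakpoint microhomology, untemplated insertions, and copy-number-corrected
genome size.

Variants spanning >= 50 bp, and all interchromosomal junctions, are
structural variants; smaller intrachromosomal variants are indels.

Breakend orientation convention: each breakend carries ``+`` if the sequence
to the LEFT of its position is retained in the derived allele (the junction
continues rightward into the partner), ``-`` if the sequence to the RIGHT is
retained.  With the two breakends in coordinate order on one chromosome:
(+,-) is a deletion, (-,+) a tandem duplication, (+,+) or (-,-) an
inversion-type junction.  VCF BND bracket notation maps onto this as

    t[p[  ->  (+,-)      t]p]  ->  (+,+)
    ]p]t  ->  (-,+)      [p[t  ->  (-,-)

where the left column is the orientation of the record's own breakend and
the right column that of its mate.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SV_MIN_SIZE = 50
ALLOWED_CHROMS = tuple(f"chr{c}" for c in list(range(1, 23)) + ["X"])

VARIANT_CLASSES = (
    "small_indel",
    "deletion",
    "tandem_duplication",
    "inversion",
    "interchromosomal_translocation",
)


def normalize_chrom(name: str) -> str:
    """Normalize chromosome names to chr-prefixed hg19 style."""
    name = str(name)
    if name.upper() in {"MT", "CHRMT"}:
        return "chrM"
    if not name.lower().startswith("chr"):
        return f"chr{name}"
    return "chr" + name[3:]


@dataclass
class SVCall:
    """One somatic breakend pair (or indel) with caller annotations."""

    sample_id: str
    chrom1: str
    pos1: int
    orient1: str | None
    chrom2: str
    pos2: int
    orient2: str | None
    qual: float = 0.0
    mapq: int = 0
    tumor_support: int = 0
    tumor_split: int = 0
    normal_support: int = 0
    homology_seq: str = ""
    insertion_seq: str = ""
    junctions_assembled: tuple[bool, bool] = (True, True)
    in_gap: tuple[bool, bool] = (False, False)
    call_id: str = ""

    def __post_init__(self) -> None:
        self.chrom1 = normalize_chrom(self.chrom1)
        self.chrom2 = normalize_chrom(self.chrom2)
        if self.pos1 < 1 or self.pos2 < 1:
            raise ValueError("positions must be >= 1")
        if self.tumor_split > self.tumor_support:
            raise ValueError("tumor_split cannot exceed tumor_support")

    @property
    def interchromosomal(self) -> bool:
        return self.chrom1 != self.chrom2

    @property
    def size(self) -> int | None:
        """|pos2 - pos1| for intrachromosomal pairs; None across chromosomes."""
        if self.interchromosomal:
            return None
        return abs(self.pos2 - self.pos1)

    @property
    def is_sv(self) -> bool:
        return self.interchromosomal or (self.size is not None and self.size >= SV_MIN_SIZE)

    @property
    def breakpoints(self) -> list[tuple[str, int]]:
        return [(self.chrom1, self.pos1), (self.chrom2, self.pos2)]


def classify_variant(call: SVCall) -> str:
    """Assign one of the variant classes from breakend geometry.

    Raises ValueError (flagging the call unclassifiable) when an
    intrachromosomal SV lacks orientations.
    """
    if call.interchromosomal:
        return "interchromosomal_translocation"
    size = call.size
    if size is not None and size < SV_MIN_SIZE:
        return "small_indel"
    if call.orient1 is None or call.orient2 is None:
        raise ValueError(f"unclassifiable intrachromosomal SV without orientations: {call}")
    # orientations in coordinate order
    if call.pos1 <= call.pos2:
        o = (call.orient1, call.orient2)
    else:
        o = (call.orient2, call.orient1)
    if o == ("+", "-"):
        return "deletion"
    if o == ("-", "+"):
        return "tandem_duplication"
    return "inversion"


# ---------------------------------------------------------------------------
# high-confidence filter cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Thresholds for the six-clause high-confidence filter."""

    allowed_chroms: tuple[str, ...] = ALLOWED_CHROMS
    max_normal_support: int = 0
    min_tumor_support: int = 10
    min_split_reads: int = 2        # SVs only
    min_qual: float = 30.0
    min_mapq: int = 30
    recurrence_tolerance: int = 10  # bp on each breakend; 0 = exact matching
    dgv_class_aware: bool = True

CLAUSES = (
    "chromosomes",        # both breakpoints on chr1-22 or chrX
    "normal_support",     # zero supporting reads in the matched normal
    "tumor_support",      # >= 10 tumor reads, >= 2 split reads for SVs
    "quality",            # QUAL >= 30 and supporting-read MAPQ >= 30
    "gap_region",         # neither breakpoint in a gap region
    "assembled",          # both junctions assembled
)


@dataclass
class FilterReport:
    """Outcome of the filter cascade."""

    survivors: list[SVCall]
    clause_failures: dict[str, int]
    recurrence_removed: int
    dgv_removed: int
    malformed: int
    n_input: int

    @property
    def n_survivors(self) -> int:
        return len(self.survivors)


def _intervals_by_chrom(bed: pd.DataFrame | None) -> dict[str, np.ndarray]:
    """Index BED-style intervals (chrom, start, end; 0-based half-open)."""
    out: dict[str, np.ndarray] = {}
    if bed is None or len(bed) == 0:
        return out
    for chrom, grp in bed.groupby(bed.columns[0]):
        arr = grp.iloc[:, 1:3].to_numpy(dtype=np.int64)
        out[normalize_chrom(chrom)] = arr[np.argsort(arr[:, 0])]
    return out


def _point_in_intervals(idx: dict[str, np.ndarray], chrom: str, pos1based: int) -> bool:
    arr = idx.get(normalize_chrom(chrom))
    if arr is None:
        return False
    p = pos1based - 1  # to 0-based
    return bool(((arr[:, 0] <= p) & (arr[:, 1] > p)).any())


def _passes_clauses(call: SVCall, cfg: FilterConfig, gap_idx) -> str | None:
    """Return the name of the first failing clause, or None if all pass.

    The six clauses are conjunctive per-variant predicates, so the survivor
    set is invariant to the order in which they are checked.
    """
    if call.chrom1 not in cfg.allowed_chroms or call.chrom2 not in cfg.allowed_chroms:
        return "chromosomes"
    if call.normal_support > cfg.max_normal_support:
        return "normal_support"
    if call.tumor_support < cfg.min_tumor_support or (
        call.is_sv and call.tumor_split < cfg.min_split_reads
    ):
        return "tumor_support"
    if call.qual < cfg.min_qual or call.mapq < cfg.min_mapq:
        return "quality"
    in_gap = call.in_gap
    if gap_idx:
        in_gap = (
            in_gap[0] or _point_in_intervals(gap_idx, call.chrom1, call.pos1),
            in_gap[1] or _point_in_intervals(gap_idx, call.chrom2, call.pos2),
        )
    if in_gap[0] or in_gap[1]:
        return "gap_region"
    if not (call.junctions_assembled[0] and call.junctions_assembled[1]):
        return "assembled"
    return None


def _breakend_key(chrom: str, pos: int, tol: int) -> tuple:
    if tol <= 0:
        return (chrom, pos)
    return (chrom, pos // (2 * tol + 1))


def _recurrence_groups(calls: Sequence[SVCall], tol: int) -> list[set[int]]:
    """Group call indices whose both breakends match within +/- tol bp."""
    groups: list[set[int]] = []
    parent = list(range(len(calls)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    buckets: dict[tuple, list[int]] = defaultdict(list)
    for i, c in enumerate(calls):
        bp = tuple(sorted(c.breakpoints))
        # coarse bucket on first breakend only; verify both ends pairwise
        buckets[(bp[0][0], bp[0][1] // max(1, tol * 4) if tol > 0 else bp[0][1])].append(i)
        if tol > 0:
            buckets[(bp[0][0], bp[0][1] // (tol * 4) + 1)].append(i)
    for members in buckets.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                ci, cj = calls[i], calls[j]
                bi = sorted(ci.breakpoints)
                bj = sorted(cj.breakpoints)
                if all(
                    x[0] == y[0] and abs(x[1] - y[1]) <= tol for x, y in zip(bi, bj)
                ):
                    union(i, j)
    merged: dict[int, set[int]] = defaultdict(set)
    for i in range(len(calls)):
        merged[find(i)].add(i)
    return [g for g in merged.values() if len(g) > 1]


def apply_high_confidence_filter(
    calls: Iterable[SVCall],
    unmatched_normal_calls: Iterable[SVCall] | None = None,
    dgv_panel: pd.DataFrame | None = None,
    gap_regions: pd.DataFrame | None = None,
    config: FilterConfig | None = None,
) -> FilterReport:
    """Apply the high-confidence somatic filter cascade.

    First the six per-variant clauses (chromosome set, zero normal support,
    tumor support / split reads, QUAL and MAPQ, gap regions, junction
    assembly); then removal of variants recurring across tumor samples or
    matching any call from an unmatched normal; then removal of variants
    overlapping a germline-CNV panel (DGV-style BED with an optional fourth
    column naming the variant class).
    """
    cfg = config or FilterConfig()
    gap_idx = _intervals_by_chrom(gap_regions)
    clause_failures = Counter({c: 0 for c in CLAUSES})
    malformed = 0
    passed: list[SVCall] = []
    n_input = 0
    for call in calls:
        n_input += 1
        if not isinstance(call, SVCall):
            malformed += 1
            logger.warning("skipping malformed record: %r", call)
            continue
        failing = _passes_clauses(call, cfg, gap_idx)
        if failing is None:
            passed.append(call)
        else:
            clause_failures[failing] += 1

    # recurrence: same variant in >1 tumor sample (windowed breakpoint match)
    tol = cfg.recurrence_tolerance
    removed_rec: set[int] = set()
    for group in _recurrence_groups(passed, tol):
        samples = {passed[i].sample_id for i in group}
        if len(samples) > 1:
            removed_rec.update(group)
    # ... or present in any unmatched normal
    if unmatched_normal_calls:
        normals = [c for c in unmatched_normal_calls if isinstance(c, SVCall)]
        for i, c in enumerate(passed):
            if i in removed_rec:
                continue
            bi = sorted(c.breakpoints)
            for nc in normals:
                bn = sorted(nc.breakpoints)
                if all(x[0] == y[0] and abs(x[1] - y[1]) <= tol for x, y in zip(bi, bn)):
                    removed_rec.add(i)
                    break
    after_rec = [c for i, c in enumerate(passed) if i not in removed_rec]

    # DGV-style panel overlap: either breakpoint inside a panel interval,
    # optionally requiring the same variant class
    dgv_removed = 0
    survivors: list[SVCall] = []
    if dgv_panel is not None and len(dgv_panel):
        has_class = dgv_panel.shape[1] >= 4
        if cfg.dgv_class_aware and has_class:
            class_idx = {
                cls: _intervals_by_chrom(grp.iloc[:, :3])
                for cls, grp in dgv_panel.groupby(dgv_panel.columns[3])
            }
        else:
            class_idx = {None: _intervals_by_chrom(dgv_panel.iloc[:, :3])}
        for c in after_rec:
            try:
                cls = classify_variant(c)
            except ValueError:
                cls = None
            idx = class_idx.get(cls if (cfg.dgv_class_aware and has_class) else None, {})
            hit = any(_point_in_intervals(idx, ch, p) for ch, p in c.breakpoints)
            if hit:
                dgv_removed += 1
            else:
                survivors.append(c)
    else:
        survivors = after_rec

    return FilterReport(
        survivors=survivors,
        clause_failures=dict(clause_failures),
        recurrence_removed=len(removed_rec),
        dgv_removed=dgv_removed,
        malformed=malformed,
        n_input=n_input,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

DEFAULT_SIZE_BINS = ((5, 100), (100, 10_000), (10_000, 100_000), (100_000, 10_000_000))


def microhomology_fraction(
    calls: Iterable[SVCall],
    size_bins: Sequence[tuple[int, int]] = DEFAULT_SIZE_BINS,
    mh_range: tuple[int, int] = (1, 10),
) -> pd.DataFrame:
    """Fraction of calls with breakpoint microhomology in ``mh_range`` (bp,
    both endpoints inclusive), per sample, variant class, and size bin.

    Interchromosomal translocations have no size and are pooled in a single
    "all" size bin.  Cells with no calls are absent from the result (missing,
    not zero).
    """
    lo_mh, hi_mh = mh_range
    cells: dict[tuple, list[int]] = defaultdict(list)
    for c in calls:
        cls = classify_variant(c)
        mh = len(c.homology_seq or "")
        if c.interchromosomal:
            cells[(c.sample_id, cls, "all")].append(mh)
            continue
        size = c.size
        for lo, hi in size_bins:
            if lo <= size < hi:
                cells[(c.sample_id, cls, f"[{lo},{hi})")].append(mh)
                break
    records = [
        {
            "sample": s,
            "variant_class": cls,
            "size_bin": b,
            "n": len(v),
            "microhomology_fraction": float(np.mean([lo_mh <= x <= hi_mh for x in v])),
        }
        for (s, cls, b), v in sorted(cells.items())
    ]
    return pd.DataFrame.from_records(
        records, columns=["sample", "variant_class", "size_bin", "n", "microhomology_fraction"]
    )


def size_distribution(
    calls: Iterable[SVCall], variant_class: str, log_bins: np.ndarray | None = None
) -> pd.DataFrame:
    """Histogram of sizes for an intrachromosomal variant class.

    ``log_bins`` are bin edges (default: 30 log-spaced bins from 1 bp to
    10 Mb).  Returns counts and densities (densities sum to 1 when any call
    falls in range).
    """
    if variant_class == "interchromosomal_translocation":
        raise ValueError("translocations have no size")
    if log_bins is None:
        log_bins = np.logspace(0, 7, 30)
    sizes = [c.size for c in calls if classify_variant(c) == variant_class]
    counts, edges = np.histogram(sizes, bins=log_bins)
    total = counts.sum()
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "count": counts,
            "density": counts / total if total else np.zeros_like(counts, dtype=float),
        }
    )


def insertion_fraction(calls: Sequence[SVCall]) -> float:
    """Fraction of SVs carrying a nonempty untemplated insertion; NaN if no SVs."""
    svs = [c for c in calls if c.is_sv]
    if not svs:
        return float("nan")
    return sum(bool(c.insertion_seq) for c in svs) / len(svs)


def corrected_genome_size(cn_profile: pd.DataFrame, baseline_ploidy: int = 2) -> float:
    """Copy-number-corrected genome size for one sample.

    Sum over segments of length x (copy_number / baseline_ploidy).  The
    profile is a table (chrom, start, end, copy_number) with 0-based
    half-open segments.
    """
    cn = cn_profile.iloc[:, 3].to_numpy(dtype=float)
    if (cn < 0).any():
        raise ValueError("copy numbers must be >= 0")
    lengths = (cn_profile.iloc[:, 2] - cn_profile.iloc[:, 1]).to_numpy(dtype=float)
    return float((lengths * cn / baseline_ploidy).sum())


def summarize_samples(calls: Sequence[SVCall]) -> pd.DataFrame:
    """Per-sample counts by variant class plus SV insertion fraction."""
    rows: dict[str, Counter] = defaultdict(Counter)
    for c in calls:
        rows[c.sample_id][classify_variant(c)] += 1
    records = []
    for sample in sorted(rows):
        rec = {"sample": sample}
        rec.update({cls: rows[sample].get(cls, 0) for cls in VARIANT_CLASSES})
        rec["insertion_fraction"] = insertion_fraction(
            [c for c in calls if c.sample_id == sample]
        )
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# I/O: call tables and breakend VCFs
# ---------------------------------------------------------------------------

_CALL_COLUMNS = [
    "sample", "chrom1", "pos1", "orient1", "chrom2", "pos2", "orient2",
    "qual", "mapq", "tumor_support", "tumor_split", "normal_support",
    "homology_seq", "insertion_seq", "assembled1", "assembled2",
]


def calls_to_table(calls: Iterable[SVCall]) -> pd.DataFrame:
    records = []
    for c in calls:
        records.append(
            {
                "sample": c.sample_id,
                "chrom1": c.chrom1, "pos1": c.pos1, "orient1": c.orient1 or "",
                "chrom2": c.chrom2, "pos2": c.pos2, "orient2": c.orient2 or "",
                "qual": c.qual, "mapq": c.mapq,
                "tumor_support": c.tumor_support, "tumor_split": c.tumor_split,
                "normal_support": c.normal_support,
                "homology_seq": c.homology_seq, "insertion_seq": c.insertion_seq,
                "assembled1": int(c.junctions_assembled[0]),
                "assembled2": int(c.junctions_assembled[1]),
            }
        )
    return pd.DataFrame.from_records(records, columns=_CALL_COLUMNS)


def table_to_calls(df: pd.DataFrame) -> list[SVCall]:
    calls = []
    for _, r in df.iterrows():
        calls.append(
            SVCall(
                sample_id=str(r["sample"]),
                chrom1=str(r["chrom1"]), pos1=int(r["pos1"]),
                orient1=str(r["orient1"]) if str(r["orient1"]) in "+-" else None,
                chrom2=str(r["chrom2"]), pos2=int(r["pos2"]),
                orient2=str(r["orient2"]) if str(r["orient2"]) in "+-" else None,
                qual=float(r["qual"]), mapq=int(r["mapq"]),
                tumor_support=int(r["tumor_support"]), tumor_split=int(r["tumor_split"]),
                normal_support=int(r["normal_support"]),
                homology_seq="" if pd.isna(r["homology_seq"]) else str(r["homology_seq"]),
                insertion_seq="" if pd.isna(r["insertion_seq"]) else str(r["insertion_seq"]),
                junctions_assembled=(bool(int(r["assembled1"])), bool(int(r["assembled2"]))),
            )
        )
    return calls


def write_call_table(calls: Iterable[SVCall], path) -> None:
    calls_to_table(calls).to_csv(path, sep="\t", index=False)


def read_call_table(path) -> list[SVCall]:
    return table_to_calls(pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[]))


# breakend orientation <-> VCF bracket notation (see module docstring)
def _alt_string(call: SVCall) -> str:
    ins = call.insertion_seq or ""
    t = "N" + ins
    mate = f"{call.chrom2}:{call.pos2}"
    if call.orient1 == "+" and call.orient2 == "-":
        return f"{t}[{mate}["
    if call.orient1 == "+" and call.orient2 == "+":
        return f"{t}]{mate}]"
    if call.orient1 == "-" and call.orient2 == "+":
        return f"]{mate}]{t}"
    return f"[{mate}[{t}"


def _parse_alt(alt: str) -> tuple[str, int, str, str, str]:
    """Parse a BND ALT into (mate_chrom, mate_pos, orient_self, orient_mate, inserted)."""
    if "[" in alt:
        bracket = "["
        mate_orient = "-"
    elif "]" in alt:
        bracket = "]"
        mate_orient = "+"
    else:
        raise ValueError(f"not a breakend ALT: {alt!r}")
    left, mate, right = alt.split(bracket)
    self_orient = "+" if left else "-"
    t = left or right
    chrom, pos = mate.rsplit(":", 1)
    inserted = t[1:] if self_orient == "+" else t[:-1]
    return chrom, int(pos), self_orient, mate_orient, inserted


_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
    '##INFO=<ID=MAPQ,Number=1,Type=Integer,Description="Minimum MAPQ of supporting reads">',
    '##INFO=<ID=HOMSEQ,Number=1,Type=String,Description="Microhomology sequence at the junction">',
    '##INFO=<ID=INSERTION,Number=1,Type=String,Description="Untemplated insertion at the junction">',
    '##INFO=<ID=TUMALT,Number=1,Type=Integer,Description="Supporting reads in the tumor">',
    '##INFO=<ID=TUMSPLIT,Number=1,Type=Integer,Description="Split reads in the tumor">',
    '##INFO=<ID=NORMALT,Number=1,Type=Integer,Description="Supporting reads in the matched normal">',
    '##INFO=<ID=ASSEMBLED,Number=1,Type=Integer,Description="Number of assembled junctions (0-2)">',
    '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">',
]


def write_sv_vcf(calls: Sequence[SVCall], path, chrom_sizes: dict[str, int] | None = None) -> None:
    """Write calls as a VCF 4.2 file of paired breakend (BND) records."""
    import pysam

    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    chroms = chrom_sizes or {}
    seen = {c for call in calls for c in (call.chrom1, call.chrom2)}
    for c in sorted(seen):
        header.contigs.add(c, length=chroms.get(c))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, call in enumerate(calls):
            if call.orient1 is None or call.orient2 is None:
                logger.warning("skipping call without orientations in VCF output")
                continue
            for end in (0, 1):
                rec = vf.new_record()
                rec.contig = call.chrom1 if end == 0 else call.chrom2
                rec.start = (call.pos1 if end == 0 else call.pos2) - 1
                rec.ref = "N"
                mate = replace(
                    call,
                    chrom1=call.chrom2, pos1=call.pos2, orient1=call.orient2,
                    chrom2=call.chrom1, pos2=call.pos1, orient2=call.orient1,
                )
                rec.alts = (_alt_string(call if end == 0 else mate),)
                rec.id = f"bnd_{i}_{end + 1}"
                rec.qual = call.qual
                rec.info["SVTYPE"] = "BND"
                rec.info["MATEID"] = f"bnd_{i}_{2 - end}"
                rec.info["MAPQ"] = call.mapq
                if call.homology_seq:
                    rec.info["HOMSEQ"] = call.homology_seq
                if call.insertion_seq:
                    rec.info["INSERTION"] = call.insertion_seq
                rec.info["TUMALT"] = call.tumor_support
                rec.info["TUMSPLIT"] = call.tumor_split
                rec.info["NORMALT"] = call.normal_support
                rec.info["ASSEMBLED"] = int(call.junctions_assembled[0]) + int(
                    call.junctions_assembled[1]
                )
                rec.info["SAMPLE"] = call.sample_id
                vf.write(rec)


def read_sv_vcf(path, default_sample: str = "sample") -> list[SVCall]:
    """Read paired BND records into SVCalls (one call per mate pair)."""
    import pysam

    calls = []
    seen_pairs = set()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            mate_id = rec.info.get("MATEID")
            if mate_id is not None and rec.id is not None:
                pair = tuple(sorted([rec.id, str(mate_id)]))
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
            chrom2, pos2, o1, o2, ins = _parse_alt(rec.alts[0])
            assembled = int(rec.info.get("ASSEMBLED", 2))
            calls.append(
                SVCall(
                    sample_id=str(rec.info.get("SAMPLE", default_sample)),
                    chrom1=rec.contig, pos1=rec.pos, orient1=o1,
                    chrom2=chrom2, pos2=pos2, orient2=o2,
                    qual=float(rec.qual if rec.qual is not None else 0.0),
                    mapq=int(rec.info.get("MAPQ", 0)),
                    tumor_support=int(rec.info.get("TUMALT", 0)),
                    tumor_split=int(rec.info.get("TUMSPLIT", 0)),
                    normal_support=int(rec.info.get("NORMALT", 0)),
                    homology_seq=str(rec.info.get("HOMSEQ", "") or ""),
                    insertion_seq=ins or str(rec.info.get("INSERTION", "") or ""),
                    junctions_assembled=(assembled >= 1, assembled >= 2),
                    call_id=str(rec.id or ""),
                )
            )
    return calls


def read_cn_segments(path) -> pd.DataFrame:
    """Read copy-number segments (chrom, start, end, copy_number[, sample])."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return df
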