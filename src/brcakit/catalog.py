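"""96-channel somatic mutation catalogs.

Single-base substitutions are classified into 96 channels by the pyrimidine
of the mutated base pair and its two flanking bases.  Channel order is
substitution-major (C>A, C>G, C>T, T>A, T>C, T>G), then 5' flank, then 3'
flank, each in A, C, G, T order — the COSMIC convention.  Mutations reported
on the purine strand are reverse-complemented onto the pyrimidine strand
before lookup.

A catalog is a pandas DataFrame: rows = samples, columns = the 96 channel
labels, entries = nonnegative mutation counts (the count matrix M with
M[i, j] = number of mutations of category j in sample i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def channel_labels() -> list[str]:
    """The 96 channel labels, e.g. ``A[C>A]A`` ... ``T[T>G]T``, in fixed order."""
    labels = []
    for sub in SUBSTITUTIONS:
        for f5 in BASES:
            for f3 in BASES:
                labels.append(f"{f5}[{sub}]{f3}")
    return labels


CHANNELS: tuple[str, ...] = tuple(channel_labels())
_CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}


class ContextMismatchError(ValueError):
    """The reference triplet does not match the record's REF allele."""


class AmbiguousContextError(ValueError):
    """The reference triplet contains a non-ACGT base (e.g. N)."""


@dataclass(frozen=True)
class SNVRecord:
    """One somatic single-nucleotide variant call.

    ``pos`` is 1-based (VCF convention) and must be >= 2 so that a 5' flank
    exists in the reference.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single A/C/G/T bases, got {self.ref}>{self.alt}")
        if self.pos < 2:
            raise ValueError(f"pos must be >= 2 (5' flank required), got {self.pos}")


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def classify_snv(ref: str, alt: str, context: str) -> int:
    """Classify one substitution into its channel index (0..95).

    Parameters
    ----------
    ref, alt
        Single-base reference and alternate alleles on the reported strand.
    context
        The 3-base reference triplet centered on the mutated position, on the
        same strand as ``ref``.

    Raises
    ------
    AmbiguousContextError
        If the context contains a base outside A/C/G/T.
    ContextMismatchError
        If the middle base of the context differs from ``ref``.
    """
    context = context.upper()
    ref = ref.upper()
    alt = alt.upper()
    if len(context) != 3:
        raise ValueError(f"context must be 3 bases, got {context!r}")
    if any(b not in BASES for b in context) or alt not in BASES:
        raise AmbiguousContextError(f"ambiguous base in context {context!r} or alt {alt!r}")
    if context[1] != ref:
        raise ContextMismatchError(
            f"context middle base {context[1]!r} does not match ref {ref!r}"
        )
    if ref in "AG":  # purine strand: collapse onto the pyrimidine strand
        context = reverse_complement(context)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return _CHANNEL_INDEX[label]


def _fetch_context(reference, chrom: str, pos: int) -> str:
    """Reference triplet centered on 1-based ``pos``.

    ``reference`` may be a pyfaidx.Fasta (or anything sliceable per-chromosome
    with 0-based coordinates) or a plain mapping of chromosome -> sequence
    string.
    """
    seq = reference[chrom]
    frag = seq[pos - 2 : pos + 1]
    return str(frag).upper()


def build_catalog(records: Iterable[SNVRecord], reference) -> pd.DataFrame:
    """Build the samples x 96 mutation count matrix from SNV records.

    Records whose context contains an ambiguous base are skipped (counted and
    logged); records whose REF disagrees with the reference triplet are
    rejected with a diagnostic (counted and logged).  The catalog total equals
    the number of successfully classified records.
    """
    counts: dict[str, np.ndarray] = {}
    order: list[str] = []
    n_skipped = 0
    n_rejected = 0
    n_classified = 0
    for rec in records:
        try:
            ctx = _fetch_context(reference, rec.chrom, rec.pos)
        except KeyError as exc:
            raise KeyError(f"chromosome {rec.chrom!r} not in reference") from exc
        try:
            j = classify_snv(rec.ref, rec.alt, ctx)
        except AmbiguousContextError:
            n_skipped += 1
            continue
        except ContextMismatchError as exc:
            logger.warning("rejected %s:%d in %s: %s", rec.chrom, rec.pos, rec.sample_id, exc)
            n_rejected += 1
            continue
        if rec.sample_id not in counts:
            counts[rec.sample_id] = np.zeros(96, dtype=np.int64)
            order.append(rec.sample_id)
        counts[rec.sample_id][j] += 1
        n_classified += 1
    if n_skipped:
        logger.info("skipped %d records with ambiguous context bases", n_skipped)
    if not counts:
        logger.warning("no classifiable records; returning empty catalog")
        return pd.DataFrame(columns=list(CHANNELS), dtype=np.int64)
    mat = np.vstack([counts[s] for s in order])
    return pd.DataFrame(mat, index=pd.Index(order, name="sample"), columns=list(CHANNELS))


def read_snv_table(path) -> list[SNVRecord]:
    """Read a tab-separated SNV table with columns sample, chrom, pos, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df.columns = [c.lower() for c in df.columns]
    return [
        SNVRecord(str(r["sample"]), str(r["chrom"]), int(r["pos"]), str(r["ref"]), str(r["alt"]))
        for _, r in df.iterrows()
    ]


def write_catalog(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index_label="sample")


def read_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    if list(df.columns) != list(CHANNELS):
        raise ValueError("catalog columns do not match the 96 channel labels")
    return df


def filter_low_count_samples(catalog: pd.DataFrame, min_total: int = 1000) -> pd.DataFrame:
    """Drop samples with total mutation count strictly below ``min_total``.

    A sample with exactly ``min_total`` mutations is retained.  Row order is
    preserved and the operation is idempotent.
    """
    totals = catalog.sum(axis=1)
    kept = catalog.loc[totals >= min_total]
    if len(kept) == 0 and len(catalog) > 0:
        logger.warning("all %d samples fall below min_total=%d", len(catalog), min_total)
    return kept


def tumor_mutational_burden(nonsynonymous_count: int, coding_megabases: float) -> float:
    """Nonsynonymous mutations per megabase of coding sequence."""
    if coding_megabases <= 0:
        raise ValueError(f"coding_megabases must be > 0, got {coding_megabases}")
    if nonsynonymous_count < 0:
        raise ValueError("nonsynonymous_count must be >= 0")
    return nonsynonymous_count / coding_megabases
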