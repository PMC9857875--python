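"""Read assignment and normalization for 5'-tRF quantification.

Reads are assigned to candidate 5'-tRFs by exact full-length sequence
identity.  Because the candidate set is sequence-deduplicated, the
assignment is a hash lookup and each read maps to at most one candidate —
under a zero-mismatch full-read constraint this is equivalent to running
an aligner against the candidate FASTA, and it is exactly testable.

The "total mapped reads" RPM denominator counts reads that match anywhere
(exact substring of either strand) in the mature + pre-tRNA sequence sets;
a library-size denominator (all reads) is available via
``denominator="library"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .reference import TRFReference, reverse_complement

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclass
class SampleLibrary:
    """Per-sample read accounting."""

    sample_id: str
    total_mapped_reads: int
    assigned_reads: int
    n_reads: int = 0
    n_skipped_non_acgt: int = 0

    def __post_init__(self) -> None:
        if self.assigned_reads > self.total_mapped_reads:
            raise ValueError("assigned_reads cannot exceed total_mapped_reads")


def assign_reads(
    reads: list[str],
    reference: TRFReference,
    sample_id: str = "sample",
    denominator: str = "trna",
) -> tuple[dict[str, int], SampleLibrary]:
    """Count reads per candidate 5'-tRF by exact full-length match.

    A read increments candidate ``c`` iff its sequence equals
    ``c.sequence`` exactly.  ``total_mapped_reads`` counts reads that match
    the tRNA sequence space (candidate hits, or exact substring of a
    mature/pre-tRNA sequence on either strand); with
    ``denominator="library"`` every valid read counts.
    Non-ACGT reads are skipped with a logged count.
    """
    if not reference.candidates:
        raise ValueError("empty reference")
    if denominator not in ("trna", "library"):
        raise ValueError("denominator must be 'trna' or 'library'")

    # tRNA sequence space for the denominator; concatenation with a
    # separator keeps substring checks linear over a single haystack.
    pool = list(reference.mature_sequences.values()) + list(
        reference.pre_trna_sequences.values()
    )
    haystack = "#".join(pool)
    haystack_rc = reverse_complement(haystack.replace("#", "N")).replace("N", "#")

    counts: dict[str, int] = {c.trf_id: 0 for c in reference.candidates}
    by_seq = {c.sequence: c.trf_id for c in reference.candidates}
    assigned = 0
    mapped = 0
    skipped = 0
    n_valid = 0
    for read in reads:
        read = read.upper()
        if not read or set(read) - _ACGT:
            skipped += 1
            continue
        n_valid += 1
        trf_id = by_seq.get(read)
        if trf_id is not None:
            counts[trf_id] += 1
            assigned += 1
            mapped += 1
        elif read in haystack or read in haystack_rc:
            mapped += 1
    if skipped:
        logger.warning("%s: skipped %d non-ACGT reads", sample_id, skipped)
    total = n_valid if denominator == "library" else mapped
    return counts, SampleLibrary(
        sample_id=sample_id,
        total_mapped_reads=total,
        assigned_reads=assigned,
        n_reads=len(reads),
        n_skipped_non_acgt=skipped,
    )


def rpm_normalize(
    counts: pd.DataFrame, libraries: dict[str, SampleLibrary]
) -> ExpressionMatrix:
    """Reads-per-million of total mapped reads, per sample.

    ``counts`` is features x samples raw counts; every sample must have a
    positive total-mapped denominator.
    """
    totals = []
    for sample in counts.columns:
        lib = libraries[sample]
        if lib.total_mapped_reads <= 0:
            raise ValueError(f"sample {sample!r} has zero total mapped reads")
        totals.append(lib.total_mapped_reads)
    rpm = counts.astype(float) * 1e6 / np.asarray(totals, dtype=float)
    return ExpressionMatrix(rpm, scale="RPM")


def filter_detected(
    matrix: ExpressionMatrix, quantile: float = 0.90, threshold: float = 1.0
) -> ExpressionMatrix:
    """Keep features whose q-th quantile across samples is >= threshold.

    This is the robust-detection filter: features with 90th-quantile
    RPM < 1 are removed.  The boundary is inclusive (quantile exactly at
    the threshold is retained) and the quantile interpolates linearly
    between order statistics.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    q = matrix.data.quantile(quantile, axis=1, interpolation="linear")
    keep = q[q >= threshold].index
    return ExpressionMatrix(matrix.data.loc[keep], matrix.scale)


def log2_uq_normalize(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(v + pseudocount), then upper-quantile normalize across samples.

    Per sample the 75th percentile of the log2 values (over retained
    features) is subtracted and the across-sample mean of those upper
    quartiles added back, equalizing per-sample upper quartiles while
    preserving the overall location.
    """
    if matrix.scale not in ("RPM", "RPKM"):
        raise ValueError(f"expected an RPM/RPKM matrix, got scale {matrix.scale!r}")
    logged = np.log2(matrix.data + pseudocount)
    uq = logged.quantile(0.75, axis=0)
    if (uq <= 0).any():
        bad = list(uq.index[uq <= 0])
        raise ValueError(f"degenerate samples with non-positive upper quartile: {bad}")
    out = logged - uq + uq.mean()
    return ExpressionMatrix(out, scale="log2-UQ")


def uq_then_log2_normalize(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Alternative order: upper-quantile scale on RPM, then log2(v+1)."""
    if matrix.scale not in ("RPM", "RPKM"):
        raise ValueError(f"expected an RPM/RPKM matrix, got scale {matrix.scale!r}")
    uq = matrix.data.quantile(0.75, axis=0)
    if (uq <= 0).any():
        bad = list(uq.index[uq <= 0])
        raise ValueError(f"degenerate samples with non-positive upper quartile: {bad}")
    scaled = matrix.data / uq * uq.mean()
    return ExpressionMatrix(np.log2(scaled + pseudocount), scale="log2-UQ")


def quantify_cohort(
    reads_by_sample: dict[str, list[str]],
    reference: TRFReference,
    denominator: str = "trna",
) -> tuple[pd.DataFrame, dict[str, SampleLibrary]]:
    """Assign reads for every sample and stack the per-candidate counts."""
    libs: dict[str, SampleLibrary] = {}
    cols: dict[str, dict[str, int]] = {}
    for sample, reads in reads_by_sample.items():
        counts, lib = assign_reads(reads, reference, sample_id=sample, denominator=denominator)
        cols[sample] = counts
        libs[sample] = lib
    counts_df = pd.DataFrame(cols)
    counts_df.index.name = "trf_id"
    return counts_df, libs
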