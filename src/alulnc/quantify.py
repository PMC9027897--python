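"""Per-insertion fragment counting, median-of-ratios normalization, the
expression filter cascade, and the read-coverage drop score at putative
TSSs.

The counting unit is the sequenced fragment (mate pairs merged to one
template span): a fragment increments every insertion interval it
overlaps by at least one base, so counts over overlapping intervals are
not additive, but are conserved on disjoint interval sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .discovery import IntervalIndex
from .genome_io import AlignedFragment, GenomicInterval

logger = logging.getLogger(__name__)

NO_SIGNAL = math.inf


@dataclass
class CountMatrix:
    """Non-negative integer counts, insertions x samples."""

    row_ids: list[str]
    col_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"count shape {self.counts.shape} inconsistent with "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} cols"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("duplicate column ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_ids, columns=self.col_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="insertion_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset_rows(self, row_ids: Sequence[str]) -> "CountMatrix":
        pos = {rid: i for i, rid in enumerate(self.row_ids)}
        idx = [pos[rid] for rid in row_ids]
        return CountMatrix(list(row_ids), list(self.col_ids), self.counts[idx, :])


@dataclass
class SampleSheet:
    """Sample id -> condition, with the derived healthy-vs-inflammation
    binary grouping (every non-healthy condition pools into inflammation)."""

    conditions: dict[str, str]
    healthy_label: str = "healthy"

    def condition(self, sample_id: str) -> str:
        return self.conditions[sample_id]

    def binary_groups(self, col_ids: Sequence[str]) -> np.ndarray:
        """Boolean mask over columns: True = inflammation, False = healthy."""
        missing = [c for c in col_ids if c not in self.conditions]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")
        mask = np.array([self.conditions[c] != self.healthy_label for c in col_ids])
        if mask.all() or (~mask).all():
            raise ValueError("both healthy and inflammation groups must be non-empty")
        return mask

    @classmethod
    def from_tsv(cls, path, healthy_label: str = "healthy") -> "SampleSheet":
        conditions: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sample, _, condition = line.partition("\t")
                if not condition:
                    raise ValueError(f"sample sheet line without condition: {line!r}")
                conditions[sample] = condition
        return cls(conditions, healthy_label)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for sample, condition in self.conditions.items():
                fh.write(f"{sample}\t{condition}\n")


def count_fragments(
    fragments: Iterable[AlignedFragment],
    insertions: Sequence[tuple[str, GenomicInterval]],
    strand_mode: str = "both",
) -> np.ndarray:
    """Count fragments over insertion intervals (one sample's column).

    A fragment increments every interval its span overlaps by >= 1 bp.
    ``strand_mode``: both ignores strand; sense requires the fragment
    strand to match the insertion strand; antisense requires a mismatch.
    """
    if strand_mode not in ("both", "sense", "antisense"):
        raise ValueError(f"invalid strand_mode {strand_mode!r}")
    index = IntervalIndex(
        (interval, (i, interval)) for i, (_, interval) in enumerate(insertions)
    )
    counts = np.zeros(len(insertions), dtype=np.int64)
    for frag in fragments:
        for _, (i, interval) in index.query(frag.chrom, frag.span.start, frag.span.end):
            if strand_mode == "sense" and frag.strand != interval.strand:
                continue
            if strand_mode == "antisense" and frag.strand == interval.strand:
                continue
            counts[i] += 1
    return counts


def build_count_matrix(
    sample_fragments: dict[str, list[AlignedFragment]],
    insertions: Sequence[tuple[str, GenomicInterval]],
    strand_mode: str = "both",
) -> CountMatrix:
    col_ids = list(sample_fragments)
    columns = [
        count_fragments(sample_fragments[s], insertions, strand_mode) for s in col_ids
    ]
    counts = (
        np.column_stack(columns)
        if columns
        else np.zeros((len(insertions), 0), dtype=np.int64)
    )
    return CountMatrix([rid for rid, _ in insertions], col_ids, counts)


def size_factors(matrix: CountMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    For rows with a positive geometric mean g_i, factor_j is the median
    over those rows of count_ij / g_i. Requires at least one row with
    all-positive counts.
    """
    counts = matrix.counts.astype(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no row with all-positive counts; consider adding a pseudocount"
        )
    ref = counts[positive, :]
    log_geo_mean = np.log(ref).mean(axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geo_mean[:, None], axis=0))
    return factors


def normalize(matrix: CountMatrix, factors: np.ndarray) -> np.ndarray:
    """Divide each column by its size factor."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (len(matrix.col_ids),) or np.any(factors <= 0):
        raise ValueError("need one positive factor per sample")
    return matrix.counts / factors[None, :]


def filter_min_expression(
    matrix: CountMatrix, min_count: int = 400, min_samples: int = 1
) -> list[str]:
    """Rows with >= min_count raw reads (inclusive) in >= min_samples
    samples — the 'coverage of at least 400 in one or more participants'
    prefilter."""
    keep = (matrix.counts >= min_count).sum(axis=1) >= min_samples
    kept = [rid for rid, k in zip(matrix.row_ids, keep) if k]
    if not kept:
        logger.warning("expression prefilter removed every row")
    return kept


def fold_changes(
    normalized: np.ndarray,
    inflammation_mask: np.ndarray,
    pseudocount: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row fold change between inflammation and healthy group means of
    normalized values, with a pseudocount guarding empty rows.

    Returns (fc, up_in_inflammation): fc >= 1 with the direction reported
    separately, so both up- and down-regulated rows pass one threshold.
    """
    mean_infl = normalized[:, inflammation_mask].mean(axis=1) + pseudocount
    mean_healthy = normalized[:, ~inflammation_mask].mean(axis=1) + pseudocount
    ratio = mean_infl / mean_healthy
    fc = np.maximum(ratio, 1.0 / ratio)
    return fc, ratio >= 1.0


def filter_robust(
    matrix: CountMatrix,
    fc: np.ndarray,
    robust_count: int = 1000,
    fc_threshold: float = 1.3,
) -> list[str]:
    """The robust-candidate filter: max raw count strictly > robust_count
    in at least one sample, and fold change >= fc_threshold (inclusive)."""
    if len(fc) != len(matrix.row_ids):
        raise ValueError("fold changes must align with matrix rows")
    keep = (matrix.counts.max(axis=1) > robust_count) & (fc >= fc_threshold)
    return [rid for rid, k in zip(matrix.row_ids, keep) if k]


def _mean_coverage(
    fragments: Iterable[AlignedFragment], chrom: str, start: int, end: int
) -> float:
    """Mean per-base read depth over [start, end)."""
    depth = np.zeros(end - start, dtype=np.int64)
    for frag in fragments:
        if frag.chrom != chrom:
            continue
        lo, hi = max(frag.span.start, start), min(frag.span.end, end)
        if lo < hi:
            depth[lo - start : hi - start] += 1
    return float(depth.mean())


def tss_coverage_drop(
    fragments: Sequence[AlignedFragment],
    chrom: str,
    tss_pos: int,
    gene_strand: str,
    window: int = 200,
) -> float:
    """Coverage-drop ratio at a putative internal TSS.

    Mean per-base coverage in the ``window`` nt immediately 5' of the TSS
    (transcription direction) divided by the mean immediately 3' of it. A
    small ratio (an abrupt rise in coverage at the TSS) is the signature
    of a transcript initiating there rather than reading through. Zero
    downstream coverage returns the +inf sentinel NO_SIGNAL.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if gene_strand == "+":
        up = (max(0, tss_pos - window), tss_pos)
        down = (tss_pos, tss_pos + window)
    elif gene_strand == "-":
        up = (tss_pos + 1, tss_pos + 1 + window)
        down = (max(0, tss_pos + 1 - window), tss_pos + 1)
    else:
        raise ValueError(f"gene strand must be + or -, got {gene_strand!r}")
    mean_up = _mean_coverage(fragments, chrom, *up)
    mean_down = _mean_coverage(fragments, chrom, *down)
    if mean_down == 0.0:
        return NO_SIGNAL
    return mean_up / mean_down
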