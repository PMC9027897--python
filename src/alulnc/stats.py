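"""Differential-expression statistics and sample clustering.

The test is a two-sided two-sample t-test on normalized values between
the healthy and inflammation groups — Welch (unequal-variance) by
default, since the two groups differ in size and count data are
heteroscedastic; a pooled-variance option is available. P-values are
adjusted with the Benjamini-Hochberg step-up procedure and called
significant strictly below alpha (default 0.001). Sample structure is
checked with Ward-linkage hierarchical clustering on Euclidean
distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .quantify import CountMatrix, SampleSheet, fold_changes


@dataclass
class DeResult:
    insertion_id: str
    fold_change: float
    up_in: str  # "inflammation" or "healthy"
    p: float
    p_adj: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        if self.fold_change < 1.0:
            raise ValueError("fold_change must be >= 1 (direction is in up_in)")


def welch_ttest(values: Sequence[float], groups: Sequence[bool], pooled: bool = False) -> float:
    """Two-sided two-sample t-test p-value between the two label groups.

    Welch-Satterthwaite degrees of freedom by default; ``pooled=True``
    switches to the equal-variance Student test.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=bool)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    a, b = values[groups], values[~groups]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        # degenerate: no variance anywhere; identical means are a perfect null
        return 1.0 if a.mean() == b.mean() else 0.0
    result = sps.ttest_ind(a, b, equal_var=pooled)
    return float(result.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * n / j, capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def differential_expression(
    matrix: CountMatrix,
    normalized: np.ndarray,
    sheet: SampleSheet,
    pooled: bool = False,
    pseudocount: float = 1.0,
) -> list[DeResult]:
    """Per-insertion fold change and (BH-adjusted) t-test p-value on
    normalized values, healthy vs inflammation."""
    mask = sheet.binary_groups(matrix.col_ids)
    fc, up = fold_changes(normalized, mask, pseudocount)
    pvals = [welch_ttest(normalized[i, :], mask, pooled) for i in range(len(matrix.row_ids))]
    padj = bh_adjust(pvals)
    return [
        DeResult(rid, float(fc[i]), "inflammation" if up[i] else "healthy",
                 float(pvals[i]), float(padj[i]))
        for i, rid in enumerate(matrix.row_ids)
    ]


def call_significant(results: Sequence[DeResult], alpha: float = 0.001) -> list[DeResult]:
    """Rows with adjusted p strictly below alpha."""
    return [r for r in results if r.p_adj < alpha]


def write_de_tsv(path, results: Sequence[DeResult], alpha: float = 0.001) -> None:
    with open(path, "w") as fh:
        fh.write("insertion_id\tfold_change\tup_in\tp\tp_adj\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.insertion_id}\t{r.fold_change:.6g}\t{r.up_in}\t"
                f"{r.p:.6g}\t{r.p_adj:.6g}\t{str(r.p_adj < alpha).lower()}\n"
            )


@dataclass
class Dendrogram:
    """Ward-linkage merge tree over samples (scipy linkage matrix plus the
    sample ids in input order)."""

    linkage: np.ndarray
    leaf_ids: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.leaf_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def root_split(self) -> tuple[set[str], set[str]]:
        """The two sample sets produced by cutting below the root merge."""
        assignment = hierarchy.fcluster(self.linkage, t=2, criterion="maxclust")
        left = {sid for sid, c in zip(self.leaf_ids, assignment) if c == 1}
        right = set(self.leaf_ids) - left
        return left, right

    def to_newick(self) -> str:
        """Newick string with sample ids as leaves and merge heights as
        branch lengths."""
        n = len(self.leaf_ids)

        def node(idx: int, parent_height: float) -> str:
            if idx < n:
                return f"{self.leaf_ids[idx]}:{parent_height:.6g}"
            row = self.linkage[idx - n]
            height = row[2]
            children = ",".join(node(int(c), height) for c in row[:2])
            return f"({children}):{parent_height - height:.6g}"

        root = self.linkage[-1]
        height = root[2]
        children = ",".join(node(int(c), height) for c in root[:2])
        return f"({children});"


def hierarchical_cluster(normalized: np.ndarray, sample_ids: Sequence[str]) -> Dendrogram:
    """Ward-linkage agglomerative clustering of samples on Euclidean
    distances over the (insertions x samples) normalized matrix.

    Deterministic for a given input order; equal-distance merges follow
    scipy's nearest-neighbor-chain order.
    """
    if len(sample_ids) < 2:
        raise ValueError("need >= 2 samples to cluster")
    X = np.asarray(normalized, dtype=float).T  # samples in rows
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="ward")
    return Dendrogram(Z, list(sample_ids))


def separation_score(dendrogram: Dendrogram, labels: dict[str, str]) -> float:
    """Best-matching accuracy between the two root branches and a binary
    labelling of the samples; 1.0 means the root cut separates the two
    conditions exactly, 0.5 is chance."""
    left, right = dendrogram.root_split()
    values = sorted({labels[sid] for sid in dendrogram.leaf_ids})
    if len(values) != 2:
        raise ValueError("separation_score needs exactly two distinct labels")
    a = values[0]
    n = len(dendrogram.leaf_ids)
    match = sum(1 for s in left if labels[s] == a) + sum(1 for s in right if labels[s] != a)
    return max(match, n - match) / n
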