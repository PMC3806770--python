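"""Expression-matrix preparation: log2 transform, z-scoring, Wilcoxon filtering.

The committed pipeline order is transform -> filter -> normalize.  Variables
are whatever the current orientation makes columns: expression levels across
probes when clustering samples, expression levels across samples when
clustering probes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "ExpressionMatrix",
    "log2_transform",
    "normalize",
    "wilcoxon_filter",
    "preprocess_pipeline",
]

#: both groups at or below this size use the exact rank-sum null distribution
EXACT_WILCOXON_MAX_N = 15


@dataclass
class ExpressionMatrix:
    """A labelled observations x variables matrix.

    ``orientation`` records what the rows are ("samples" or "probes"); the
    matrix is always stored with observations as rows, and :meth:`transposed`
    flips which axis plays that role.
    """

    values: np.ndarray
    row_ids: list
    col_ids: list
    orientation: str = "samples"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.row_ids = list(self.row_ids)
        self.col_ids = list(self.col_ids)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} row ids x {len(self.col_ids)} column ids"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   orientation: str = "samples") -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns),
                   orientation)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids,
                            columns=self.col_ids)

    def transposed(self) -> "ExpressionMatrix":
        flipped = {"samples": "probes", "probes": "samples"}.get(
            self.orientation, self.orientation)
        return ExpressionMatrix(self.values.T, self.col_ids, self.row_ids,
                                flipped)


def log2_transform(M: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise base-2 logarithm; every entry must be strictly positive."""
    bad = np.argwhere(~(M.values > 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"log2 transform requires positive entries; found "
            f"{M.values[i, j]!r} at row {M.row_ids[i]!r}, "
            f"column {M.col_ids[j]!r}"
        )
    return replace(M, values=np.log2(M.values))


def normalize(M: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each variable (column) to mean 0, variance 1 (n-1 denominator)."""
    if M.values.shape[0] < 2:
        raise ValueError("normalization needs at least two observations")
    sd = M.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [M.col_ids[j] for j in zero]
        raise ValueError(
            f"zero-variance columns cannot be normalized; drop them first: "
            f"{names}"
        )
    values = (M.values - M.values.mean(axis=0)) / sd
    return replace(M, values=values)


def normalize_array(X: np.ndarray) -> np.ndarray:
    """Column z-scoring for bare arrays (used by the synthetic generators)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column")
    return (X - X.mean(axis=0)) / sd


def wilcoxon_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for one variable.

    Uses the exact null distribution when both groups have at most
    ``EXACT_WILCOXON_MAX_N`` members and the data are tie-free; otherwise the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    small = max(len(x), len(y)) <= EXACT_WILCOXON_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided",
                              method=method).pvalue)


def wilcoxon_filter(
    M: ExpressionMatrix,
    groups: Sequence,
    alpha_level: float = 0.001,
) -> ExpressionMatrix:
    """Keep variables that differ between two groups of observations.

    ``groups`` labels each row; exactly two distinct non-empty labels are
    required (pool classes beforehand for multi-class designs, e.g. normal
    versus all cancer subtypes).  A variable is retained when its two-sided
    rank-sum p-value is below ``alpha_level``.
    """
    groups = np.asarray(groups)
    if len(groups) != M.shape[0]:
        raise ValueError("group labels must match the number of observations")
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(
            f"expected exactly two groups, got {len(levels)}: {list(levels)}"
        )
    mask_a = groups == levels[0]
    mask_b = groups == levels[1]
    keep = [
        j for j in range(M.shape[1])
        if wilcoxon_rank_sum_p(M.values[mask_a, j], M.values[mask_b, j])
        < alpha_level
    ]
    return ExpressionMatrix(M.values[:, keep], M.row_ids,
                            [M.col_ids[j] for j in keep], M.orientation)


def preprocess_pipeline(
    M: ExpressionMatrix,
    log2: bool = True,
    groups: Sequence | None = None,
    alpha_level: float = 0.001,
) -> ExpressionMatrix:
    """Standard preparation in fixed order: log2 -> Wilcoxon filter -> z-score."""
    if log2:
        M = log2_transform(M)
    if groups is not None:
        M = wilcoxon_filter(M, groups, alpha_level)
        if M.shape[1] == 0:
            raise ValueError("no variables survived the Wilcoxon filter")
    return normalize(M)
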