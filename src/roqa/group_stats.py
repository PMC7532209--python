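"""Robust two-group comparison of particle shape measures.

Shape-record distributions are skewed (volume high-pass filters and ratio
measures confined to (0, 1] bound them), so comparisons use medians and the
semi-interquartile range (SIQR) instead of means, with the two-sided
Wilcoxon–Mann–Whitney rank-sum test for significance. Because p values can
be tiny while distributions still overlap heavily at large n, a comparison
is additionally flagged *well resolved* only when the median difference
exceeds the average SIQR of the two groups. Raw p values are reported; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "siqr",
    "rank_sum_test",
    "compare_groups",
    "DEFAULT_MEASURES",
    "EXACT_TEST_MAX_N",
]

#: Largest min(n_x, n_y) for which the exact (enumeration) null is used
#: when the pooled sample is tie-free.
EXACT_TEST_MAX_N = 25

#: Measures compared by default (record-table column names).
DEFAULT_MEASURES = [
    "voxel_volume_um3",
    "mean_intensity",
    "diameter_longest_um",
    "diameter_medium_um",
    "diameter_shortest_um",
    "flatness",
    "elongation",
    "sphericity",
]


@dataclass
class GroupComparison:
    measure: str
    median_a: float
    median_b: float
    siqr_a: float
    siqr_b: float
    p_value: float
    n_a: int
    n_b: int

    @property
    def median_difference(self) -> float:
        return self.median_b - self.median_a

    @property
    def average_siqr(self) -> float:
        return 0.5 * (self.siqr_a + self.siqr_b)

    @property
    def well_resolved(self) -> bool:
        """True when |median difference| exceeds the average SIQR."""
        return abs(self.median_difference) > self.average_siqr

    def as_dict(self) -> dict:
        return {
            "measure": self.measure,
            "median_a": self.median_a,
            "median_b": self.median_b,
            "siqr_a": self.siqr_a,
            "siqr_b": self.siqr_b,
            "median_difference": self.median_difference,
            "average_siqr": self.average_siqr,
            "p_value": self.p_value,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "well_resolved": self.well_resolved,
        }


def siqr(values) -> float:
    """Semi-interquartile range (Q3 − Q1)/2 with linear-interpolation
    (type-7) quantiles."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("SIQR needs at least 2 values")
    q1, q3 = np.percentile(values, [25, 75])  # numpy default = type 7
    return float(q3 - q1) / 2.0


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon–Mann–Whitney p value.

    Uses the exact permutation null when both samples are small
    (min(n) <= 25) and the pooled data is tie-free; otherwise the normal
    approximation with tie and continuity corrections. Identical constant
    samples give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= EXACT_TEST_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def compare_groups(a, b, measures=None) -> list[GroupComparison]:
    """Compare two groups of shape records on each measure.

    `a` and `b` are record tables (DataFrames or lists of ShapeRecord).
    Rows with a missing value for a measure are excluded pairwise for that
    measure only, mirroring per-measure bookkeeping of failed mesh volumes.
    """
    df_a = _as_frame(a)
    df_b = _as_frame(b)
    measures = list(measures) if measures is not None else DEFAULT_MEASURES
    out = []
    for m in measures:
        xa = df_a[m].dropna().to_numpy(dtype=float) if m in df_a else np.array([])
        xb = df_b[m].dropna().to_numpy(dtype=float) if m in df_b else np.array([])
        if xa.size < 2 or xb.size < 2:
            raise ValueError(f"measure {m!r}: need >= 2 non-missing values per group")
        out.append(
            GroupComparison(
                measure=m,
                median_a=float(np.median(xa)),
                median_b=float(np.median(xb)),
                siqr_a=siqr(xa),
                siqr_b=siqr(xb),
                p_value=rank_sum_test(xa, xb),
                n_a=int(xa.size),
                n_b=int(xb.size),
            )
        )
    return out


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.as_dict() for r in records])
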