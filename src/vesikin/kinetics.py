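"""Time-course assembly, peak location, and nonparametric testing.

The statistical battery mirrors common practice for small-n assay data:
Mann-Whitney U for two groups (exact when feasible), Kruskal-Wallis with
Dunn's post hoc for three or more independent groups, and Friedman with
Dunn's post hoc for matched (repeated-measures) designs.  Dunn's z-tests
are computed on pooled ranks (Kruskal-Wallis form, with tie correction) or
within-block ranks (Friedman form); pairwise p-values are adjusted by a
configurable method, Holm by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .stoichiometry import fold_ratio

__all__ = [
    "COMPARTMENTS",
    "TimeCourse",
    "TestResult",
    "PairwiseComparison",
    "PeakResult",
    "find_peak",
    "compartment_contrast",
    "mann_whitney",
    "kruskal_dunn",
    "friedman_dunn",
    "significance_stars",
]

COMPARTMENTS = frozenset({"medium", "cell", "EV", "lysate", "supernatant"})

_REQUIRED_COLUMNS = ("timepoint_h", "compartment", "replicate", "value", "unit")


class TimeCourse:
    """Per-timepoint, per-compartment replicate measurements.

    Wraps a DataFrame with columns timepoint_h, compartment, replicate,
    value, unit.  Units must be consistent within a compartment and
    timepoints non-negative.
    """

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"time course is missing columns: {missing}")
        if (df["timepoint_h"] < 0).any():
            raise ValueError("timepoints must be non-negative")
        bad = set(df["compartment"]) - COMPARTMENTS
        if bad:
            raise ValueError(f"unknown compartments: {sorted(bad)}")
        per_comp_units = df.groupby("compartment")["unit"].nunique()
        mixed = per_comp_units[per_comp_units > 1]
        if not mixed.empty:
            raise ValueError(f"mixed units within compartments: {list(mixed.index)}")
        self.records = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, rows: Sequence[tuple]) -> "TimeCourse":
        return cls(pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)))

    @classmethod
    def from_csv(cls, path) -> "TimeCourse":
        return cls(pd.read_csv(path))

    def compartment_means(self, compartment: str) -> pd.Series:
        """Replicate means per timepoint for one compartment, sorted by time."""
        sub = self.records[self.records["compartment"] == compartment]
        if sub.empty:
            raise ValueError(f"no records for compartment {compartment!r}")
        return sub.groupby("timepoint_h")["value"].mean().sort_index()

    def values_at(self, compartment: str, timepoint_h: float) -> np.ndarray:
        sub = self.records[
            (self.records["compartment"] == compartment)
            & (np.isclose(self.records["timepoint_h"], timepoint_h))
        ]
        if sub.empty:
            raise ValueError(f"no records for {compartment!r} at {timepoint_h} h")
        return sub["value"].to_numpy()


class PeakResult(NamedTuple):
    timepoint_h: float
    mean_value: float
    tied: bool


def find_peak(tc: TimeCourse, compartment: str) -> PeakResult:
    """Timepoint with the highest replicate mean for a compartment.

    Ties are broken toward the earlier timepoint and flagged.
    """
    means = tc.compartment_means(compartment)
    if len(means) < 2:
        raise ValueError(f"need at least 2 timepoints for {compartment!r}, got {len(means)}")
    top = means.max()
    at_top = means[np.isclose(means, top, rtol=1e-12, atol=0.0)]
    return PeakResult(
        timepoint_h=float(at_top.index[0]), mean_value=float(top), tied=len(at_top) > 1
    )


def compartment_contrast(
    tc: TimeCourse, a: str, b: str, timepoint_h: float
) -> float:
    """Fold ratio of per-timepoint means between two compartments."""
    mean_a = float(np.mean(tc.values_at(a, timepoint_h)))
    mean_b = float(np.mean(tc.values_at(b, timepoint_h)))
    return fold_ratio(mean_a, mean_b)


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: int
    group_b: int
    statistic: float
    p_value: float
    p_adjusted: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    comparisons: tuple[PairwiseComparison, ...] | None = None


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact U distribution when the smaller sample has n <= 8 and the
    pooled data are tie-free; otherwise the normal approximation with tie
    correction (and continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(x.size, y.size) <= 8 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"mann-whitney-{method}",
    )


def _adjust(p_values: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p_values
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"adjust must be 'holm', 'bonferroni' or 'none', got {method!r}")
    return multipletests(p_values, method=method)[1]


def _dunn_kruskal(groups: list[np.ndarray], adjust: str) -> tuple[PairwiseComparison, ...]:
    # Dunn's z on pooled ranks with tie correction
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    raw = []
    pairs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            raw.append(min(1.0, 2.0 * stats.norm.sf(abs(z))))
            pairs.append((i, j, z))
    adjusted = _adjust(np.asarray(raw), adjust)
    return tuple(
        PairwiseComparison(i, j, float(z), float(p), float(pa))
        for (i, j, z), p, pa in zip(pairs, raw, adjusted)
    )


def kruskal_dunn(groups: Sequence[Sequence[float]], adjust: str = "holm") -> TestResult:
    """Kruskal-Wallis H test with Dunn's pairwise post hoc.

    Requires at least three groups (use :func:`mann_whitney` for two).
    The omnibus H carries scipy's tie correction; Dunn z-statistics are
    computed on the pooled ranks and adjusted by ``adjust``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError(
            f"kruskal_dunn needs at least 3 groups (got {len(arrays)}); "
            "use mann_whitney for two groups"
        )
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    if np.unique(np.concatenate(arrays)).size == 1:
        # degenerate: a constant pooled sample carries no evidence
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    comparisons = _dunn_kruskal(arrays, adjust)
    return TestResult(
        statistic=float(h), p_value=float(p), method="kruskal-wallis", comparisons=comparisons
    )


def friedman_dunn(blocks, adjust: str = "holm") -> TestResult:
    """Friedman test on a complete block design with Dunn's post hoc.

    ``blocks`` is an (n_blocks x k_treatments) matrix of matched
    measurements; missing cells are an error (no imputation).  Dunn's
    z-statistics compare treatment mean within-block ranks with standard
    error sqrt(k(k+1)/(6 n)).
    """
    mat = np.asarray(blocks, dtype=float)
    if mat.ndim != 2:
        raise ValueError("blocks must be a 2-D matrix (blocks x treatments)")
    n_blocks, k = mat.shape
    if k < 3:
        raise ValueError(f"need at least 3 treatments, got {k}")
    if np.isnan(mat).any():
        raise ValueError("missing cells are not allowed in a complete block design")
    if np.all(mat == mat[:, [0]]):
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.friedmanchisquare(*mat.T)
    within_ranks = np.apply_along_axis(stats.rankdata, 1, mat)
    mean_ranks = within_ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n_blocks))
    raw, pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            raw.append(min(1.0, 2.0 * stats.norm.sf(abs(z))))
            pairs.append((i, j, z))
    adjusted = _adjust(np.asarray(raw), adjust)
    comparisons = tuple(
        PairwiseComparison(i, j, float(z), float(p_), float(pa))
        for (i, j, z), p_, pa in zip(pairs, raw, adjusted)
    )
    return TestResult(
        statistic=float(chi2), p_value=float(p), method="friedman", comparisons=comparisons
    )


def significance_stars(p: float) -> str:
    """Display band for a p-value (****, ***, **, *, or ns)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < threshold:
            return stars
    return "ns"
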