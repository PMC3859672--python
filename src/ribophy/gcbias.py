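"""GC-content bias analytics.

rRNA genes sit under strong structural constraint, so their GC content varies
far less than genomic GC content does.  The diagnostics here quantify that:
per-sequence GC fractions, ordinary least-squares regression of rRNA GC on
genomic GC (an unconstrained locus tracks the genome with slope near 1; a
constrained one shows a strongly attenuated slope), Wilcoxon rank-sum
comparisons between clades, and Tukey box summaries per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RegressionResult",
    "RankSumResult",
    "BoxStats",
    "gc_fraction",
    "fit_gc_regression",
    "rank_sum_test",
    "summarize_groups",
]

_UNAMBIGUOUS = set("ACGT")


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); gaps, ``?`` and ambiguity codes are excluded entirely."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    total = sum(1 for c in seq if c in _UNAMBIGUOUS)
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    gc = sum(1 for c in seq if c in "GC")
    return gc / total


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    stderr: float
    n: int


def fit_gc_regression(pairs) -> RegressionResult:
    """OLS of rRNA GC (y) on genomic GC (x) over ``(x, y)`` pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (genomic_gc, rrna_gc) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("genomic GC values are constant; slope undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        stderr=float(fit.stderr),
        n=arr.shape[0],
    )


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank-sum W of the first sample
    p_value: float
    method: str  # "exact" | "normal_approx"


def rank_sum_test(a, b, exact_max: int = 12) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    The exact null distribution is used when both samples have at most
    ``exact_max`` observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  The statistic
    reported is W, the rank sum of the first sample.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact_ok = max(a.size, b.size) <= exact_max and not has_ties
    if exact_ok:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal_approx"
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank-sum W
    return RankSumResult(statistic=w, p_value=float(min(res.pvalue, 1.0)), method=method)


@dataclass(frozen=True)
class BoxStats:
    """Tukey box-plot summary: quartiles, 1.5*IQR whiskers, outliers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    n: int


def _box(values: np.ndarray) -> BoxStats:
    # linear-interpolation (type-7) quartiles, stated in the docs so numbers
    # are reproducible across toolchains
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = tuple(float(v) for v in values[(values < lo_fence) | (values > hi_fence)])
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
        n=values.size,
    )


def summarize_groups(values: dict[str, list[float]]) -> dict[str, BoxStats]:
    """Per-group Tukey box statistics (e.g. GC fractions per clade)."""
    out: dict[str, BoxStats] = {}
    for group, vals in values.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {group!r} has no values")
        out[group] = _box(arr)
    return out
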