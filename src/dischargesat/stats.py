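"""Nonparametric test battery and percentile summaries.

The comparisons the analysis pipeline needs: Fisher's exact test for 2x2
tables (response rates, sex), the Mann-Whitney-Wilcoxon rank-sum test for
independent groups (scores, age, stay duration, ordinal education), the
Wilcoxon signed-rank test for paired per-patient differences (item-vs-item
ordering), a Bonferroni-adjusted significance threshold, and Table-style
percentile summaries.

Exact paths
-----------
* Fisher: two-sided p as the sum of hypergeometric probabilities no larger
  than that of the observed table (the R convention).
* Mann-Whitney: for combined n at or below ``exact_threshold`` (default
  20), full permutation enumeration of all C(m+n, m) group allocations of
  the pooled midranks -- valid with ties; p is the fraction of allocations
  whose U deviates from mn/2 at least as much as the observed U.
* Signed-rank: zeros dropped (reduced-sample method); for remaining n at
  or below ``exact_threshold`` (default 15), enumeration of all 2^n sign
  assignments of the midranks of |d|.

Beyond the thresholds, normal approximations with tie-corrected variance
and a 0.5 continuity correction are used::

    MWW:  z = (U - mn/2 -+ 1/2) / sqrt(mn/12 * ((N+1) - sum(t^3-t)/(N(N-1))))
    WSR:  z = (W - n(n+1)/4 -+ 1/2) / sqrt(n(n+1)(2n+1)/24 - sum(t^3-t)/48)

where the ``t`` are tie-group sizes of the pooled sample (MWW) or of |d|
(WSR), and the continuity correction shrinks the deviation toward zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import sqrt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm, rankdata

__all__ = [
    "TestResult",
    "PercentileTable",
    "ComparisonReport",
    "ItemOrderingReport",
    "fisher_exact",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "bonferroni_threshold",
    "percentile_table",
    "compare_arms",
    "compare_items_within",
    "DEFAULT_COMPARISONS",
    "PERCENTILE_LEVELS",
]

MANN_WHITNEY_EXACT_MAX_N = 20  # combined sample size for full enumeration
SIGNED_RANK_EXACT_MAX_N = 15  # nonzero differences for 2^n enumeration
PERCENTILE_LEVELS = (5, 10, 25, 50, 75, 90, 95)
DEFAULT_COMPARISONS = (("telephone", "internet"), ("telephone", "noneligible"))

_REL_EPS = 1e-9  # tolerance when comparing enumerated probabilities/deviations


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    method: str  # exact_enumeration | normal_approx_ties | degenerate
    n_per_group: tuple[int, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The p-value sums, over all tables with the observed margins, the
    hypergeometric probabilities not exceeding that of the observed table.
    The statistic is the sample odds ratio ``ad/bc``.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("counts must be integers")
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    N = a + b + c + d
    K = a + b  # first row margin
    n1 = a + c  # first column margin
    if N == 0:
        return TestResult("fisher_exact", float("nan"), 1.0, "degenerate", (0, 0), True)
    k_min = max(0, n1 - (N - K))
    k_max = min(K, n1)
    support = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(support, N, K, n1)
    p_obs = pmf[a - k_min]
    p = float(pmf[pmf <= p_obs * (1 + _REL_EPS)].sum())
    odds = a * d / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return TestResult(
        "fisher_exact", odds, min(p, 1.0), "exact_enumeration", (a + b, c + d)
    )


# ---------------------------------------------------------------------------
# Mann-Whitney-Wilcoxon rank-sum test
# ---------------------------------------------------------------------------


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Midranks times two -> exact integers even with ties."""
    return np.rint(2 * rankdata(values)).astype(np.int64)


def mann_whitney(
    x: Iterable[float],
    y: Iterable[float],
    exact_threshold: int = MANN_WHITNEY_EXACT_MAX_N,
) -> TestResult:
    """Two-sided Mann-Whitney-Wilcoxon test for two independent samples.

    Exact permutation enumeration when ``len(x) + len(y) <= exact_threshold``
    (correct under ties); otherwise normal approximation with tie-corrected
    variance and continuity correction.  The statistic is U of the first
    sample.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks2 = _doubled_midranks(pooled)  # doubled to stay integral under ties
    u2_obs = int(ranks2[:m].sum()) - m * (m + 1)  # 2*U1
    mu2 = m * n  # 2 * (mn/2)
    if m + n <= exact_threshold:
        dev_obs = abs(u2_obs - mu2)
        count = 0
        total = 0
        for combo in itertools.combinations(ranks2.tolist(), m):
            total += 1
            if abs(sum(combo) - m * (m + 1) - mu2) >= dev_obs:
                count += 1
        return TestResult(
            "mann_whitney", u2_obs / 2, count / total, "exact_enumeration", (m, n)
        )
    N = m + n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:  # all observations identical
        return TestResult("mann_whitney", u2_obs / 2, 1.0, "degenerate", (m, n), True)
    dev = abs(u2_obs - mu2) / 2.0
    z = max(dev - 0.5, 0.0) / sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return TestResult("mann_whitney", u2_obs / 2, p, "normal_approx_ties", (m, n))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(
    diffs: Iterable[float],
    exact_threshold: int = SIGNED_RANK_EXACT_MAX_N,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (reduced-sample method).  If everything is
    zero the result is flagged degenerate with p = 1.  The statistic is W+,
    the sum of the midranks of |d| over positive differences.
    """
    d = np.asarray(list(diffs), dtype=float)
    if len(d) == 0:
        raise ValueError("need at least one paired difference")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, "degenerate", (0,), True)
    ranks2 = _doubled_midranks(np.abs(d))
    w2_obs = int(ranks2[d > 0].sum())  # 2*W+
    total2 = int(ranks2.sum())  # = 2 * n(n+1)/2; E[2W+] is half of this
    if n <= exact_threshold:
        masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        w2_all = masks @ ranks2
        dev_obs = abs(w2_obs - total2 / 2)
        p = float(np.mean(np.abs(w2_all - total2 / 2) >= dev_obs - _REL_EPS))
        return TestResult(
            "wilcoxon_signed_rank", w2_obs / 2, p, "exact_enumeration", (n,)
        )
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        return TestResult("wilcoxon_signed_rank", w2_obs / 2, 1.0, "degenerate", (n,), True)
    dev = abs(w2_obs - total2 / 2) / 2.0
    z = max(dev - 0.5, 0.0) / sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return TestResult("wilcoxon_signed_rank", w2_obs / 2, p, "normal_approx_ties", (n,))


# ---------------------------------------------------------------------------
# Bonferroni and percentile tables
# ---------------------------------------------------------------------------


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Adjusted per-comparison significance level alpha / k."""
    if k < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / k


@dataclass(frozen=True)
class PercentileTable:
    """Quantiles of one group's score distribution at fixed levels."""

    group: str
    levels: tuple[int, ...]
    values: tuple[float, ...]  # exact quantiles
    n: int

    @property
    def rounded(self) -> tuple[float, ...]:
        from .report import round_half_up

        return tuple(round_half_up(v, 2) for v in self.values)

    def __post_init__(self) -> None:
        if any(b < a - 1e-12 for a, b in zip(self.values, self.values[1:])):
            raise ValueError("percentile values must be non-decreasing")


def percentile_table(
    scores: Iterable[float],
    group: str = "all",
    levels: Sequence[int] = PERCENTILE_LEVELS,
    method: str = "linear",
) -> PercentileTable:
    """Quantiles at the given percentile levels.

    The default ``method="linear"`` interpolates order statistics at
    position ``h = (n - 1) p + 1`` -- the convention that yields non-lattice
    values like 0.43 from lattice-valued scores.  Any numpy quantile method
    name may be passed instead.
    """
    arr = np.asarray([s for s in scores if s is not None], dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("cannot build a percentile table from an empty sample")
    qs = np.quantile(arr, [lv / 100 for lv in levels], method=method)
    return PercentileTable(group, tuple(int(lv) for lv in levels), tuple(map(float, qs)), arr.size)


# ---------------------------------------------------------------------------
# Arm comparisons
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ("total", "logistics", "continuity", "impressions")


@dataclass
class ComparisonReport:
    """Rank-test comparisons of score distributions between arms.

    ``tests`` holds one entry per (score, comparison) pair; ``percentiles``
    maps score -> group -> :class:`PercentileTable` (including "all").
    """

    alpha: float
    adjusted_alpha: float
    comparisons: tuple[tuple[str, str], ...]
    tests: list[dict] = field(default_factory=list)
    percentiles: dict[str, dict[str, PercentileTable]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "adjusted_alpha": self.adjusted_alpha,
            "comparisons": [list(c) for c in self.comparisons],
            "tests": [
                {
                    **{k: v for k, v in t.items() if k != "result"},
                    "statistic": t["result"].statistic,
                    "p_value": t["result"].p_value,
                    "method": t["result"].method,
                    "n_per_group": list(t["result"].n_per_group),
                }
                for t in self.tests
            ],
            "percentiles": {
                score: {
                    g: {"levels": list(pt.levels), "values": list(pt.rounded), "n": pt.n}
                    for g, pt in groups.items()
                }
                for score, groups in self.percentiles.items()
            },
        }

    def percentile_frame(self) -> pd.DataFrame:
        """Percentile tables as a tidy frame (one row per score x group)."""
        rows = []
        for score, groups in self.percentiles.items():
            for g, pt in groups.items():
                row = {"score": score, "group": g, "n": pt.n}
                row.update({f"p{lv}": v for lv, v in zip(pt.levels, pt.rounded)})
                rows.append(row)
        return pd.DataFrame(rows)


def compare_arms(
    scores: pd.DataFrame,
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
    alpha: float = 0.05,
    quantile_method: str = "linear",
    score_columns: Sequence[str] = SCORE_COLUMNS,
) -> ComparisonReport:
    """Mann-Whitney comparisons of the total and subscores between arms.

    ``scores`` must carry an ``arm`` column and the score columns; undefined
    scores (NaN/None) are dropped per column.  Significance is judged at the
    Bonferroni-adjusted level ``alpha / len(comparisons)``.
    """
    available = sorted(set(scores["arm"].dropna()))
    for a, b in comparisons:
        for g in (a, b):
            if g not in available:
                raise ValueError(f"arm {g!r} absent; available arms: {available}")
    adjusted = bonferroni_threshold(alpha, len(comparisons))
    report = ComparisonReport(alpha, adjusted, tuple(tuple(c) for c in comparisons))
    for col in score_columns:
        values = {
            g: scores.loc[scores["arm"] == g, col].dropna().to_numpy(dtype=float)
            for g in available
        }
        for a, b in comparisons:
            if len(values[a]) < 2 or len(values[b]) < 2:
                raise ValueError(
                    f"need >= 2 defined {col!r} scores per arm for {a} vs {b}"
                )
            res = mann_whitney(values[a], values[b])
            report.tests.append(
                {
                    "score": col,
                    "group_a": a,
                    "group_b": b,
                    "result": res,
                    "significant": bool(res.p_value <= adjusted),
                }
            )
        tables = {"all": percentile_table(scores[col].dropna(), "all", method=quantile_method)}
        for g in available:
            if len(values[g]):
                tables[g] = percentile_table(values[g], g, method=quantile_method)
        report.percentiles[col] = tables
    return report


# ---------------------------------------------------------------------------
# Within-patient item ordering
# ---------------------------------------------------------------------------


@dataclass
class ItemOrderingReport:
    """Paired signed-rank comparisons between item subscores.

    One entry per pair, with the direction of the difference: ``+1`` when
    the first-named item scores higher, ``-1`` when lower, ``0`` when the
    paired differences are centred on zero.
    """

    pairs: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pairs": [
                {
                    "pair": p["pair"],
                    "median_difference": p["median_difference"],
                    "direction": p["direction"],
                    "statistic": p["result"].statistic,
                    "p_value": p["result"].p_value,
                    "method": p["result"].method,
                    "degenerate": p["result"].degenerate,
                }
                for p in self.pairs
            ]
        }


def compare_items_within(
    scores: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = (("logistics", "continuity"), ("impressions", "logistics")),
) -> ItemOrderingReport:
    """Signed-rank tests on paired per-patient subscore differences.

    Defaults compare logistics minus continuity (item 1 - item 2) and
    impressions minus logistics (item 3 - item 1).  Only patients with all
    subscores defined are used.
    """
    usable = scores.dropna(subset=["logistics", "continuity", "impressions"])
    if len(usable) < 2:
        raise ValueError("need at least 2 patients with all three subscores defined")
    report = ItemOrderingReport()
    for first, second in pairs:
        d = (usable[first] - usable[second]).to_numpy(dtype=float)
        res = wilcoxon_signed_rank(d)
        med = float(np.median(d))
        direction = int(np.sign(med)) if med != 0 else int(np.sign(np.mean(d)))
        report.pairs.append(
            {
                "pair": f"{first}-{second}",
                "median_difference": med,
                "direction": direction,
                "result": res,
            }
        )
    return report
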