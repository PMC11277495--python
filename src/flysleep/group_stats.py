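"""Group-comparison statistics for per-fly sleep and rhythm parameters.

The battery mirrors standard chronobiology practice: descriptive summaries
as mean ± SD and median [min–max]; a chi-square test (no continuity
correction by default) on rhythmic/arrhythmic counts; Kruskal–Wallis with
Dunn's pairwise post hoc (family-wise adjusted) across genotypes within a
sex; Mann–Whitney between sexes of one genotype; Shapiro–Wilk and
Lilliefors-corrected Kolmogorov–Smirnov as an advisory normality screen
(the comparisons are nonparametric regardless).  Significance is p ≤ 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import scipy.stats as st
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize",
    "rhythmicity_frequency_test",
    "multi_group_compare",
    "dunn_posthoc",
    "two_group_compare",
    "normality_screen",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    genotype: str
    sex: str
    parameter: str
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    note: str = ""

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return bool(p <= ALPHA) if np.isfinite(p) else False


def summarize(
    values: Sequence[float], genotype: str, sex: str, parameter: str
) -> GroupSummary:
    """Exact order statistics and moments of one group's per-fly values.

    NaNs (e.g. bout length for flies that never slept in a phase) are
    dropped; ``n`` counts the contributing flies.  SD is the sample SD and
    is NaN for a single value.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("no finite values to summarize")
    return GroupSummary(
        genotype,
        sex,
        parameter,
        len(v),
        float(np.mean(v)),
        float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
        float(np.median(v)),
        float(np.min(v)),
        float(np.max(v)),
    )


def rhythmicity_frequency_test(
    counts: np.ndarray | Sequence[Sequence[int]],
    groups: tuple[str, ...] = (),
    yates: bool = False,
) -> ComparisonResult:
    """Chi-square test on a rhythmic/arrhythmic contingency table.

    ``counts`` is a 2×k table (rows: rhythmic, arrhythmic; columns: groups).
    The default is the uncorrected chi-square, matching common statistics
    packages; set ``yates=True`` for the continuity-corrected 2×2 variant.
    """
    table = np.asarray(counts)
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    stat, p, _, _ = st.chi2_contingency(table, correction=yates)
    return ComparisonResult("chi-square", tuple(groups), float(stat), float(p))


def dunn_posthoc(
    values_by_group: Mapping[str, Sequence[float]],
) -> list[ComparisonResult]:
    """Dunn's (1964) pairwise rank z-tests after Kruskal–Wallis.

    All groups are pooled and midranked once; for groups i, j the statistic
    is z = (R̄_i − R̄_j) / sqrt(S² (1/n_i + 1/n_j)) with the tie-corrected
    variance S² = N(N+1)/12 − Σ(t³ − t)/(12(N−1)).  Two-sided p-values are
    adjusted family-wise over all k(k−1)/2 pairwise contrasts of one
    parameter (Bonferroni-type, capped at 1).
    """
    names = list(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in names]
    n = np.array([len(s) for s in samples])
    if len(names) < 2 or (n < 2).any():
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(samples)
    N = len(pooled)
    ranks = st.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    s2 = N * (N + 1) / 12.0 - (tie_counts**3 - tie_counts).sum() / (
        12.0 * (N - 1)
    )
    offsets = np.concatenate(([0], np.cumsum(n)))
    mean_ranks = np.array(
        [ranks[offsets[i] : offsets[i + 1]].mean() for i in range(len(names))]
    )
    m = len(names) * (len(names) - 1) // 2
    out = []
    for i, j in combinations(range(len(names)), 2):
        se = np.sqrt(s2 * (1.0 / n[i] + 1.0 / n[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * st.norm.sf(abs(z))
        out.append(
            ComparisonResult(
                "Dunn",
                (names[i], names[j]),
                float(z),
                float(p),
                p_adjusted=float(min(1.0, p * m)),
            )
        )
    return out


def multi_group_compare(
    values_by_group: Mapping[str, Sequence[float]],
) -> list[ComparisonResult]:
    """Kruskal–Wallis omnibus followed by Dunn's pairwise contrasts."""
    names = list(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(names) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    try:
        h, p = st.kruskal(*samples)
    except ValueError:  # all values identical
        h, p = 0.0, 1.0
    omnibus = ComparisonResult("Kruskal-Wallis", tuple(names), float(h), float(p))
    return [omnibus] + dunn_posthoc(values_by_group)


def two_group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    groups: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sided Mann–Whitney U between two groups.

    Exact enumeration is used when the smaller sample has ≤ 8 values and
    there are no cross-sample ties; otherwise the midrank normal
    approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        "Mann-Whitney", groups, float(res.statistic), float(res.pvalue),
        note=method,
    )


def normality_screen(
    values: Sequence[float], group: str = ""
) -> list[ComparisonResult]:
    """Shapiro–Wilk and Lilliefors-corrected KS normality tests.

    Advisory only — downstream comparisons are nonparametric regardless of
    the outcome.  A constant sample is degenerate (normality undefined) and
    is returned flagged with NaN statistics.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need >= 3 values")
    if np.ptp(v) == 0:
        nan = float("nan")
        return [
            ComparisonResult(t, (group,), nan, nan, note="degenerate: constant sample")
            for t in ("Shapiro-Wilk", "Kolmogorov-Smirnov")
        ]
    sw_stat, sw_p = st.shapiro(v)
    ks_stat, ks_p = lilliefors(v, dist="norm")
    return [
        ComparisonResult("Shapiro-Wilk", (group,), float(sw_stat), float(sw_p)),
        ComparisonResult(
            "Kolmogorov-Smirnov", (group,), float(ks_stat), float(ks_p),
            note="Lilliefors-corrected",
        ),
    ]
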