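"""Group comparison layer: Levene, one-way ANOVA + Scheffe, Kruskal-Wallis +
Bonferroni, and a routing report.

The routing rule is explicit: if Levene's test (center = mean) rejects
homogeneity at alpha = 0.05, or a Shapiro-Wilk normality pre-check fails in
any group, the metric is compared with Kruskal-Wallis and Bonferroni-
corrected pairwise rank tests; otherwise with one-way ANOVA and Scheffe
post-hoc contrasts.  The route taken is recorded in the report and can be
overridden.

Base tests come from scipy.stats; the Scheffe pairwise adjustment is
computed from its definition: for groups i, j with means m_i, m_j,

    F_ij = (m_i - m_j)^2 / (MSE * (1/n_i + 1/n_j)),
    p_ij = P[F(k-1, N-k) >= F_ij / (k-1)].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats

__all__ = [
    "GroupTable",
    "TestReport",
    "PairwiseResult",
    "levene",
    "anova_scheffe",
    "kruskal_bonferroni",
    "compare_groups",
    "group_summary",
]


@dataclass(frozen=True)
class GroupTable:
    """Per-subject metric values keyed by group label."""

    groups: dict[str, np.ndarray]
    metric: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for label, values in self.groups.items():
            arr = np.asarray(values, dtype=float).ravel()
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"group {label!r} contains non-finite values")
            clean[str(label)] = arr
        if len(clean) < 2:
            raise ValueError("need at least 2 groups")
        object.__setattr__(self, "groups", clean)

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, float]] | Mapping[str, Sequence[float]], metric: str = ""
    ) -> "GroupTable":
        if isinstance(records, Mapping):
            return cls({k: np.asarray(v, float) for k, v in records.items()}, metric)
        groups: dict[str, list[float]] = {}
        for label, value in records:
            groups.setdefault(label, []).append(float(value))
        return cls({k: np.asarray(v) for k, v in groups.items()}, metric)

    def require_min_n(self, n: int) -> None:
        for label, values in self.groups.items():
            if values.size < n:
                raise ValueError(f"group {label!r} has {values.size} < {n} values")

    @property
    def labels(self) -> list[str]:
        return list(self.groups)


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_adjusted: float
    method: str


@dataclass(frozen=True)
class TestReport:
    test: str
    statistic: float
    df: tuple[float, float] | None
    p_value: float
    pairwise: tuple[PairwiseResult, ...] = field(default_factory=tuple)


def levene(table: GroupTable) -> TestReport:
    """Levene's test of homogeneity of variances (center = mean)."""
    table.require_min_n(2)
    samples = list(table.groups.values())
    # n=2 groups have identical absolute deviations; scipy's W is then 0/0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = sstats.levene(*samples, center="mean")
    k = len(samples)
    n_total = sum(s.size for s in samples)
    return TestReport(test="levene", statistic=float(stat), df=(k - 1, n_total - k), p_value=float(p))


def anova_scheffe(table: GroupTable) -> TestReport:
    """One-way ANOVA with Scheffe post-hoc pairwise contrasts.

    The degenerate case (all values identical everywhere) reports F = 0 and
    p = 1 rather than NaN.
    """
    table.require_min_n(2)
    labels = table.labels
    samples = [table.groups[g] for g in labels]
    k = len(samples)
    n_total = sum(s.size for s in samples)
    df_between, df_within = k - 1, n_total - k

    grand = np.concatenate(samples).mean()
    ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)

    if ss_within == 0 and ss_between == 0:
        f_stat, p = 0.0, 1.0
        mse = 0.0
    else:
        mse = ss_within / df_within
        if mse == 0:
            f_stat, p = float("inf"), 0.0
        else:
            f_stat = (ss_between / df_between) / mse
            p = float(sstats.f.sf(f_stat, df_between, df_within))

    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = samples[i], samples[j]
            if mse == 0:
                fij = 0.0 if a.mean() == b.mean() else float("inf")
            else:
                fij = (a.mean() - b.mean()) ** 2 / (mse * (1 / a.size + 1 / b.size))
            p_adj = float(sstats.f.sf(fij / df_between, df_between, df_within))
            pairwise.append(
                PairwiseResult((labels[i], labels[j]), float(fij), p_adj, "scheffe")
            )
    return TestReport(
        test="anova",
        statistic=float(f_stat),
        df=(df_between, df_within),
        p_value=float(p),
        pairwise=tuple(pairwise),
    )


def kruskal_bonferroni(table: GroupTable) -> TestReport:
    """Kruskal-Wallis (tie-corrected) with Bonferroni-adjusted pairwise
    Mann-Whitney tests; adjusted p = min(1, m * p_raw), m = k(k-1)/2."""
    table.require_min_n(2)
    labels = table.labels
    samples = [table.groups[g] for g in labels]
    k = len(samples)
    all_equal = all(np.array_equal(s, samples[0]) for s in samples)
    if all_equal and np.all(samples[0] == samples[0][0]):
        h, p = 0.0, 1.0
    else:
        try:
            h, p = sstats.kruskal(*samples)
        except ValueError:  # all values identical across groups
            h, p = 0.0, 1.0
    m = k * (k - 1) // 2
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = samples[i], samples[j]
            if np.all(a == a[0]) and np.array_equal(np.unique(a), np.unique(b)):
                u, p_raw = float(a.size * b.size / 2), 1.0
            else:
                u, p_raw = sstats.mannwhitneyu(a, b, alternative="two-sided")
            pairwise.append(
                PairwiseResult(
                    (labels[i], labels[j]), float(u), min(1.0, m * float(p_raw)), "bonferroni"
                )
            )
    return TestReport(
        test="kruskal",
        statistic=float(h),
        df=(k - 1, float("nan")),
        p_value=float(p),
        pairwise=tuple(pairwise),
    )


def compare_groups(
    table: GroupTable,
    alpha_route: float = 0.05,
    route: str | None = None,
) -> dict:
    """Route a metric to ANOVA/Scheffe or Kruskal-Wallis/Bonferroni.

    ``route`` in {'anova', 'kruskal'} overrides the automatic rule.  Returns
    a dict with the levene report, normality p-values, the route taken and
    the omnibus report.
    """
    lev = levene(table)
    normality = {}
    for label, values in table.groups.items():
        if values.size >= 3 and np.ptp(values) > 0:
            normality[label] = float(sstats.shapiro(values).pvalue)
        else:
            normality[label] = float("nan")
    nonnormal = any(p < alpha_route for p in normality.values() if np.isfinite(p))
    if route is None:
        route = "kruskal" if (lev.p_value < alpha_route or nonnormal) else "anova"
    report = kruskal_bonferroni(table) if route == "kruskal" else anova_scheffe(table)
    return {
        "metric": table.metric,
        "levene": lev,
        "normality_p": normality,
        "route": route,
        "omnibus": report,
    }


def group_summary(table: GroupTable) -> dict[str, tuple[float, float, int]]:
    """Per-group (mean, SEM, n)."""
    out = {}
    for label, values in table.groups.items():
        sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
        out[label] = (float(values.mean()), sem, int(values.size))
    return out
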