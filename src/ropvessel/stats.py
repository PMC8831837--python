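"""Cohort statistics: one-way ANOVA, Tukey HSD, Pearson correlation.

These are the analyses relating the temporal vessel measurements
(TAA/TVA/TAW/TVW) to ROP stage: a one-way ANOVA across the four stage
groups, Tukey's multiple-comparison test between stage pairs (the
Tukey-Kramer standard error handles the unequal group sizes), and
Pearson correlations between measurement pairs with t-based two-sided
p-values. The ANOVA and Tukey test are also computable directly from
published per-group summary statistics (n, mean, SD), which is exact:
the classic sum-of-squares decomposition is a function of those
summaries only.

Significance is assessed at alpha = 0.05 throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientGroupsError, InvalidInputError, UndefinedCorrelationError

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "TukeyResult",
    "TukeyPair",
    "CorrelationResult",
    "summarize_groups",
    "anova_oneway",
    "anova_from_summary",
    "tukey_hsd",
    "tukey_from_summary",
    "pearson",
    "correlation_pvalue",
    "shapiro_report",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Per-group summary row (the published-table representation)."""

    label: str
    n: int
    mean: float
    sd: float
    median: float | None = None
    min: float | None = None
    max: float | None = None

    def __post_init__(self):
        if self.n < 2:
            raise InvalidInputError("group summary requires n >= 2")
        if self.sd < 0:
            raise InvalidInputError("sd must be >= 0")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float = float("nan")


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float      # mean_a - mean_b
    q: float              # studentized range statistic
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class TukeyResult:
    pairs: tuple

    def significant_pairs(self) -> set:
        return {frozenset((p.group_a, p.group_b)) for p in self.pairs if p.significant}

    def pair(self, a: str, b: str) -> TukeyPair:
        for p in self.pairs:
            if {p.group_a, p.group_b} == {a, b}:
                return p
        raise KeyError((a, b))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t: float
    p: float


def _validate_groups(groups) -> list[np.ndarray]:
    if len(groups) < 2:
        raise InsufficientGroupsError("need at least 2 groups")
    out = []
    for g in groups:
        arr = np.asarray(g, dtype=float).ravel()
        if arr.size < 2:
            raise InvalidInputError("every group needs n >= 2")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("group values must be finite")
        out.append(arr)
    return out


def summarize_groups(groups, labels=None) -> list[GroupSummary]:
    """Compute (n, mean, sd, median, min, max) summaries of raw groups."""
    arrs = _validate_groups(groups)
    labels = labels or [f"group{i}" for i in range(len(arrs))]
    return [
        GroupSummary(
            label=str(lab), n=len(a), mean=float(a.mean()),
            sd=float(a.std(ddof=1)), median=float(np.median(a)),
            min=float(a.min()), max=float(a.max()),
        )
        for lab, a in zip(labels, arrs)
    ]


def anova_from_summary(summaries) -> AnovaResult:
    """One-way ANOVA from per-group (n, mean, sd) summaries.

    SS_between = sum n_i (mean_i - grand_mean)^2,
    SS_within  = sum (n_i - 1) sd_i^2; F on (k-1, N-k) df. Identical to
    the raw-data ANOVA when the summaries are computed from the raw data.
    """
    if len(summaries) < 2:
        raise InsufficientGroupsError("need at least 2 group summaries")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries], dtype=float)
    sds = np.array([s.sd for s in summaries], dtype=float)
    N = ns.sum()
    k = len(summaries)
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_between = k - 1
    df_within = int(N - k)
    ms_within = ss_within / df_within
    if ms_within == 0:
        F = 0.0 if ss_between == 0 else float("inf")
    else:
        F = (ss_between / df_between) / ms_within
    p = float(sps.f.sf(F, df_between, df_within)) if math.isfinite(F) else 0.0
    if F == 0.0:
        p = 1.0
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within,
                       p=p, ms_within=ms_within)


def anova_oneway(groups) -> AnovaResult:
    """Classic one-way ANOVA on raw value vectors (>= 2 groups, each
    n >= 2), via the exact summary-statistic decomposition."""
    arrs = _validate_groups(groups)
    return anova_from_summary(summarize_groups(arrs))


def tukey_from_summary(summaries) -> TukeyResult:
    """Tukey HSD multiple comparisons from group summaries.

    Uses the studentized range distribution with the Tukey-Kramer
    standard error ``sqrt(MS_within / 2 * (1/n_i + 1/n_j))`` for unequal
    group sizes.
    """
    anova = anova_from_summary(summaries)
    k = len(summaries)
    pairs = []
    for a, b in itertools.combinations(summaries, 2):
        se = math.sqrt(anova.ms_within / 2.0 * (1.0 / a.n + 1.0 / b.n))
        diff = a.mean - b.mean
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else float("inf"))
        p_adj = float(sps.studentized_range.sf(q, k, anova.df_within)) if math.isfinite(q) else 0.0
        p_adj = min(max(p_adj, 0.0), 1.0)
        pairs.append(TukeyPair(group_a=a.label, group_b=b.label, mean_diff=diff,
                               q=q, p_adj=p_adj, significant=p_adj < ALPHA))
    return TukeyResult(pairs=tuple(pairs))


def tukey_hsd(groups, labels=None) -> TukeyResult:
    """Tukey HSD on raw groups (list of value vectors)."""
    return tukey_from_summary(summarize_groups(groups, labels))


def correlation_pvalue(r: float, n: int) -> tuple[float, float]:
    """Two-sided p-value of a Pearson r at sample size n.

    Uses ``t = r sqrt(n-2) / sqrt(1-r^2)`` on n-2 degrees of freedom;
    applicable to published correlation coefficients. Returns (t, p).
    """
    if n < 3:
        raise InvalidInputError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise InvalidInputError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return math.copysign(float("inf"), r), 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return t, min(p, 1.0)


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation with t-based two-sided p-value."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InvalidInputError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise InvalidInputError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    t, p = correlation_pvalue(r, n)
    return CorrelationResult(r=r, n=n, t=t, p=p)


def shapiro_report(groups, labels=None) -> list[dict]:
    """Optional normality report (Shapiro-Wilk per group); informational
    only, never a gate."""
    arrs = _validate_groups(groups)
    labels = labels or [f"group{i}" for i in range(len(arrs))]
    out = []
    for lab, a in zip(labels, arrs):
        if len(a) < 3:
            out.append({"label": lab, "W": float("nan"), "p": float("nan")})
            continue
        W, p = sps.shapiro(a)
        out.append({"label": str(lab), "W": float(W), "p": float(p)})
    return out
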