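"""Group-level summaries and hypothesis tests for cohort feature tables.

Summaries are reported as mean +/- SEM.  Group comparisons use the
non-parametric Kruskal-Wallis test with Dunn's post hoc z-tests
(Bonferroni-adjusted over the requested comparisons) or paired/unpaired
two-tailed Student's t-tests.  Incidence percentages and fold-ratios are
rounded half-up at presentation precision only; internal values stay
unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IntegrityError, StatisticsError


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def mean_sem(values) -> tuple[float, float, int]:
    """Mean, SEM (sample sd over sqrt(n)) and n of a sample."""
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise StatisticsError("empty sample")
    if a.size < 2:
        raise StatisticsError("SEM undefined for n < 2")
    return float(a.mean()), float(a.std(ddof=1) / np.sqrt(a.size)), int(a.size)


@dataclass(frozen=True)
class IncidenceCount:
    """An affected/total count pair (e.g. hearts developing 2:1 AV block)."""

    numerator: int
    denominator: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise StatisticsError("denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise StatisticsError("numerator must lie in [0, denominator]")

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent_unrounded(self) -> float:
        return 100.0 * self.fraction


def incidence_percent(count: IncidenceCount) -> float:
    """Incidence as a percentage, rounded half-up to one decimal."""
    return _round_half_up(count.percent_unrounded, 1)


def fold_ratio(a: IncidenceCount, b: IncidenceCount) -> float:
    """Ratio of two incidences (a over b), from the unrounded percentages,
    rounded half-up to one decimal."""
    if b.numerator == 0:
        raise StatisticsError("reference incidence is zero")
    return _round_half_up(a.percent_unrounded / b.percent_unrounded, 1)


@dataclass
class TestResult:
    """Result of a hypothesis test, with optional post hoc comparisons as
    ``(pair, z, raw_p, adjusted_p)`` tuples."""

    name: str
    statistic: float
    pvalue: float
    posthoc: list[tuple[tuple[str, str], float, float, float]] = field(
        default_factory=list
    )
    alpha: float = 0.05


def kruskal_dunn(
    groups: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]] | None = None,
) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test with Dunn's post hoc z-tests.

    ``comparisons`` selects the pairs for Dunn's tests; adjusted p-values
    use Bonferroni correction over that set.  With exactly two groups the
    H test reduces to the two-sided rank-sum test (H = z^2).
    """
    names = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in names]
    if len(samples) < 2:
        raise StatisticsError("need at least 2 groups")
    if any(s.size < 2 for s in samples):
        raise StatisticsError("every group needs n >= 2")

    if np.ptp(np.concatenate(samples)) == 0:
        # all values identical: H = 0, p = 1 (scipy raises on zero variance)
        return TestResult("kruskal-wallis", 0.0, 1.0)
    H, p = stats.kruskal(*samples)

    result = TestResult("kruskal-wallis", float(H), float(p))
    if comparisons:
        pooled = np.concatenate(samples)
        ranks = stats.rankdata(pooled)
        N = pooled.size
        idx = np.cumsum([0] + [s.size for s in samples])
        mean_ranks = {
            k: ranks[idx[i] : idx[i + 1]].mean() for i, k in enumerate(names)
        }
        sizes = {k: s.size for k, s in zip(names, samples)}
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / (12.0 * (N - 1))
        var0 = N * (N + 1) / 12.0 - tie_term
        m = len(comparisons)
        for a, b in comparisons:
            if a not in sizes or b not in sizes:
                raise StatisticsError(f"unknown group in comparison ({a}, {b})")
            se = np.sqrt(var0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            raw = 2.0 * stats.norm.sf(abs(z))
            result.posthoc.append(((a, b), float(z), float(raw), min(1.0, m * raw)))
    return result


def t_test(x, y, paired: bool = False, welch: bool = False) -> TestResult:
    """Two-tailed Student's t-test (paired or unpaired).

    The unpaired test uses pooled variance by default (``welch=True``
    switches to Welch's unequal-variance form).  A paired test on
    identical samples (all differences zero, t undefined) reports p = 1
    by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise StatisticsError("need n >= 2 per sample")
    if paired:
        if x.size != y.size:
            raise StatisticsError("paired test needs equal lengths")
        d = x - y
        if np.all(d == d[0]) and d[0] == 0:
            return TestResult("paired t-test", 0.0, 1.0)
        t, p = stats.ttest_rel(x, y)
        name = "paired t-test"
    else:
        t, p = stats.ttest_ind(x, y, equal_var=not welch)
        name = "welch t-test" if welch else "unpaired t-test"
    if np.isnan(p):
        t, p = 0.0, 1.0
    return TestResult(name, float(t), float(p))


@dataclass(frozen=True)
class CohortRecord:
    """One individual's value for one feature within a study group."""

    group: str
    feature: str
    value: float
    individual: str
    clutch: str = "1"
    chamber: str = ""
    modality: str = ""

    @property
    def feature_key(self) -> str:
        parts = [p for p in (self.feature, self.chamber, self.modality) if p]
        return " / ".join(parts)


def build_cohort_table(records: list[CohortRecord]) -> pd.DataFrame:
    """Summarize cohort records into a group x feature grid.

    Returns a DataFrame indexed by feature key with one column block per
    group holding ``mean``, ``sem``, ``n`` (individuals) and ``N``
    (clutches).  A feature missing for a group yields NaN cells.  Use
    :func:`format_cohort_table` for a printable mean +/- SEM grid.
    """
    if not records:
        raise StatisticsError("no records")
    seen = set()
    for r in records:
        key = (r.group, r.feature_key, r.individual)
        if key in seen:
            raise IntegrityError(f"duplicate entry for {key}")
        seen.add(key)
    df = pd.DataFrame(
        {
            "group": [r.group for r in records],
            "feature": [r.feature_key for r in records],
            "value": [r.value for r in records],
            "clutch": [r.clutch for r in records],
        }
    )
    rows = {}
    for (feat, grp), sub in df.groupby(["feature", "group"], sort=False):
        v = sub["value"].to_numpy()
        sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
        rows[(feat, grp)] = {
            "mean": v.mean(),
            "sem": sem,
            "n": v.size,
            "N": sub["clutch"].nunique(),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["feature", "group"])
    return out.unstack("group")


def format_cohort_table(grid: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Render a numeric cohort grid as ``mean +/- SEM`` strings."""
    groups = grid["mean"].columns
    data = {}
    for g in groups:
        col = []
        for feat in grid.index:
            m = grid[("mean", g)].get(feat, np.nan)
            s = grid[("sem", g)].get(feat, np.nan)
            col.append("" if pd.isna(m) else f"{m:.{decimals}f} ± {s:.{decimals}f}")
        data[g] = col
    return pd.DataFrame(data, index=grid.index)


__all__ = [
    "mean_sem",
    "IncidenceCount",
    "incidence_percent",
    "fold_ratio",
    "TestResult",
    "kruskal_dunn",
    "t_test",
    "CohortRecord",
    "build_cohort_table",
    "format_cohort_table",
]
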