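"""Cohort statistics: group comparison, Pearson correlations, chi-square.

Implements the statistical battery of a case-control ALPS study — pooled
(Student) independent-sample t tests on continuous variables, Pearson
correlations between the ALPS index and clinical covariates, and a Pearson
chi-square on 2x2 categorical tables — operating on raw samples or, where
only printed summary statistics are available, directly on mean/SD/n. All
p-values are two-tailed; no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Subject
from .errors import StatsError

logger = logging.getLogger(__name__)

#: smallest reportable two-tailed p (perfect correlation); keeps p in (0, 1]
MIN_P = 5e-324


@dataclass(frozen=True)
class GroupComparisonResult:
    """Pooled-variance two-sample t test. ``t`` is signed as
    (mean_b - mean_a) / SE, df = n_a + n_b - 2."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its t statistic
    ``t = r * sqrt((n - 2) / (1 - r^2))`` and two-tailed p."""

    r: float
    n: int
    t: float
    p: float


@dataclass(frozen=True)
class ContingencyResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""

    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    df: int
    p: float


def t_test_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
) -> GroupComparisonResult:
    """Student pooled-variance t test from sufficient statistics (mean, SD, n
    per group) — reproduces published p-values from printed summary rows."""
    if n_a < 2 or n_b < 2:
        raise StatsError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise StatsError("negative standard deviation")
    if sd_a == 0 and sd_b == 0 and mean_a != mean_b:
        raise StatsError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind_from_stats(
        mean_b, sd_b, n_b, mean_a, sd_a, n_a, equal_var=True
    )
    return GroupComparisonResult(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b,
        t=float(t), df=n_a + n_b - 2, p=float(max(p, MIN_P)),
    )


def t_test_raw(
    values_a: Sequence[float], values_b: Sequence[float]
) -> GroupComparisonResult:
    """Student pooled-variance t test on raw samples; identical to
    :func:`t_test_summary` fed the samples' own sufficient statistics."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("need n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() != b.mean():
        raise StatsError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(b, a, equal_var=True)
    return GroupComparisonResult(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=a.size,
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=b.size,
        t=float(t), df=a.size + b.size - 2, p=float(max(p, MIN_P)),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-tailed p from the t distribution.

    A perfect correlation (|r| = 1) has an unbounded t; its p is reported
    as the smallest positive float so p stays in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise StatsError("need n >= 3 for a correlation")
    if x.std() == 0 or y.std() == 0:
        raise StatsError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    n = x.size
    if abs(r) >= 1.0:
        return CorrelationResult(r=r, n=n, t=float(np.copysign(np.inf, r)), p=MIN_P)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return CorrelationResult(r=r, n=n, t=float(t), p=float(max(res.pvalue, MIN_P)))


def chi_square_2x2(
    counts: Sequence[Sequence[int]],
) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table (df = 1, no continuity correction)."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise StatsError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise StatsError("negative count")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise StatsError("zero marginal: chi-square undefined")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return ContingencyResult(
        table=tuple(tuple(int(v) for v in row) for row in table),
        chi2=float(chi2), df=int(df), p=float(max(p, MIN_P)),
    )


@dataclass
class CohortReport:
    """Structured results battery for a measured cohort."""

    group_test: GroupComparisonResult
    correlations: dict[str, CorrelationResult] = field(default_factory=dict)
    value_used: str = "alps_measured"

    def to_dataframe(self) -> pd.DataFrame:
        g = self.group_test
        rows = [{
            "analysis": "ALPS CAE vs HC (t test)",
            "estimate": g.mean_b - g.mean_a,
            "statistic": g.t, "df": g.df, "n": g.n_a + g.n_b, "p": g.p,
        }]
        for name, c in self.correlations.items():
            rows.append({
                "analysis": f"Pearson r: {name}",
                "estimate": c.r, "statistic": c.t, "df": c.n - 2,
                "n": c.n, "p": c.p,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        g = self.group_test
        lines = [
            f"ALPS index ({self.value_used}): "
            f"CAE {g.mean_a:.2f} +/- {g.sd_a:.2f} (n={g.n_a}) vs "
            f"HC {g.mean_b:.2f} +/- {g.sd_b:.2f} (n={g.n_b}); "
            f"t({g.df}) = {g.t:.2f}, p = {g.p:.3g}",
        ]
        for name, c in self.correlations.items():
            lines.append(f"{name}: r = {c.r:.3f} (n = {c.n}), p = {c.p:.3g}")
        return "\n".join(lines)


def _subject_values(subjects: list[Subject], use: str) -> np.ndarray:
    return np.array([getattr(s, use) for s in subjects], dtype=float)


def analyze_cohort(
    subjects: list[Subject], use: Optional[str] = None
) -> CohortReport:
    """Run the full results battery on a cohort.

    Compares ALPS between groups (pooled t test) and correlates ALPS with
    age in both groups and with disease duration and seizure frequency in
    the patient group. ``use`` selects ``"alps_measured"`` (default when
    every subject has one) or ``"alps_true"``. A correlation whose
    covariate is missing is skipped with a logged warning.
    """
    cae = [s for s in subjects if s.group == "CAE"]
    hc = [s for s in subjects if s.group == "HC"]
    if not cae or not hc:
        raise StatsError("cohort must contain both CAE and HC subjects")
    if use is None:
        use = ("alps_measured"
               if all(s.alps_measured is not None for s in subjects)
               else "alps_true")
    if any(getattr(s, use) is None for s in subjects):
        raise StatsError(f"{use} missing for some subjects")
    alps_cae = _subject_values(cae, use)
    alps_hc = _subject_values(hc, use)
    report = CohortReport(
        group_test=t_test_raw(alps_cae, alps_hc), value_used=use
    )
    specs = [
        ("ALPS vs age (CAE)", cae, "age"),
        ("ALPS vs duration (CAE)", cae, "duration"),
        ("ALPS vs frequency (CAE)", cae, "frequency"),
        ("ALPS vs age (HC)", hc, "age"),
    ]
    for name, group, attr in specs:
        covariate = [getattr(s, attr) for s in group]
        if any(v is None for v in covariate):
            logger.warning("skipping %s: covariate %s missing", name, attr)
            continue
        report.correlations[name] = pearson(
            _subject_values(group, use), np.asarray(covariate, dtype=float)
        )
    return report
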