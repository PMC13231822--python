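"""Univariate screening: chi-square, t and Mann-Whitney tests, sample size.

Conventions follow the source analysis: Pearson chi-square without
continuity correction, pooled-variance t by default (Welch by flag),
tie-corrected normal approximation for Mann-Whitney, two-sided p-values
throughout, and a single-proportion sample-size formula with ceiling
applied at each step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import Cohort

logger = logging.getLogger(__name__)


class DegenerateTableError(ValueError):
    """Contingency table has a zero row or column total (or negative counts)."""


class DegenerateSampleError(ValueError):
    """Sample has too few observations or zero variance for the test."""


@dataclass
class ContingencyTable:
    """Observed r x c counts with expected counts and the chi-square test."""

    variable: str
    row_labels: tuple[str, ...]
    counts: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float


@dataclass
class TwoSampleResult:
    """A two-sample location test: t (pooled/Welch) or Mann-Whitney z."""

    statistic: float
    p: float
    method: str
    df: float | None = None
    u: float | None = None


@dataclass
class SampleSizeSpec:
    """Inputs of the single-proportion sample-size formula."""

    pi: float
    alpha: float = 0.05
    delta: float = 0.05
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.delta <= 0.0:
            raise ValueError("delta must be > 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class ScreenResult:
    variable: str
    test: str
    statistic: float
    df: float | None
    p: float
    selected: bool


def pearson_chi2(
    counts, variable: str = "", row_labels: tuple[str, ...] | None = None
) -> ContingencyTable:
    """Uncorrected Pearson chi-square test of an r x c contingency table.

    ``expected[i, j] = row_i * col_j / N``; ``chi2 = sum (O - E)^2 / E``;
    ``df = (r - 1)(c - 1)``; p from the chi-square survival function.
    No continuity correction is applied for any table size.
    """
    observed = np.asarray(counts, dtype=float)
    if observed.ndim != 2 or observed.shape[0] < 2 or observed.shape[1] < 2:
        raise DegenerateTableError("need at least a 2 x 2 table")
    if np.any(observed < 0):
        raise DegenerateTableError("negative counts")
    n = observed.sum()
    if n <= 0:
        raise DegenerateTableError("empty table")
    rows = observed.sum(axis=1)
    cols = observed.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DegenerateTableError("zero row or column total")
    expected = np.outer(rows, cols) / n
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    labels = row_labels or tuple(str(i) for i in range(observed.shape[0]))
    return ContingencyTable(variable, tuple(labels), observed, expected, chi2, df, p)


def two_sample_t(
    x=None,
    y=None,
    variant: str = "pooled",
    summary: tuple[tuple[float, float, int], tuple[float, float, int]] | None = None,
) -> TwoSampleResult:
    """Two-sided independent-samples t test, pooled-variance or Welch.

    Accepts either raw vectors ``x``/``y`` or ``summary`` as two
    ``(mean, sd, n)`` triples.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if summary is not None:
        (m1, s1, n1), (m2, s2, n2) = summary
    else:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise DegenerateSampleError("each group needs >= 2 observations")
        m1, s1, n1 = x.mean(), x.std(ddof=1), len(x)
        m2, s2, n2 = y.mean(), y.std(ddof=1), len(y)
    if variant == "pooled":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        if sp2 <= 0:
            raise DegenerateSampleError("zero pooled variance")
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df: float = n1 + n2 - 2
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        if v1 + v2 <= 0:
            raise DegenerateSampleError("zero variance in both groups")
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = (m1 - m2) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TwoSampleResult(float(t), p, f"{variant}-t", df=float(df))


def mann_whitney(x, y) -> TwoSampleResult:
    """Mann-Whitney U via midranks with tie-corrected normal z.

    ``U`` counts pairs where x exceeds y (ties count one half);
    ``z = (U - n1 n2 / 2) / sqrt(var)`` with the tie-corrected variance and
    a two-sided normal p-value (no continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise DegenerateSampleError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        raise DegenerateSampleError("undefined variance (all values tied)")
    z = (u - n1 * n2 / 2.0) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return TwoSampleResult(float(z), p, "mann-whitney", u=float(u))


def required_sample_size(spec: SampleSizeSpec) -> int:
    """Minimum n for estimating a proportion to +/- delta, dropout-inflated.

    ``n0 = ceil(u^2 pi (1 - pi) / delta^2)`` with ``u`` the two-sided
    normal quantile; final ``n = ceil(n0 / (1 - dropout))``.
    """
    u = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    n0 = math.ceil(u**2 * spec.pi * (1.0 - spec.pi) / spec.delta**2)
    return math.ceil(n0 / (1.0 - spec.dropout))


def _is_continuous(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series)


def screen(
    cohort: Cohort | pd.DataFrame,
    outcome: str,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> list[ScreenResult]:
    """Univariate screening of every column against a binary outcome.

    Categorical columns get the uncorrected chi-square test; continuous
    columns are routed by per-group Shapiro-Wilk normality (both normal at
    ``normality_alpha`` -> pooled t, otherwise Mann-Whitney).  A variable
    is ``selected`` when ``p < alpha``.  Single-state columns are skipped
    with a logged warning.
    """
    frame = cohort.records if isinstance(cohort, Cohort) else cohort
    if outcome not in frame.columns:
        raise KeyError(f"unknown outcome column {outcome!r}")
    outcome_values = frame[outcome]
    levels = sorted(outcome_values.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"outcome {outcome!r} must be binary, got {levels!r}")
    results: list[ScreenResult] = []
    for column in frame.columns:
        if column == outcome:
            continue
        series = frame[column]
        if _is_continuous(series):
            groups = [
                series[outcome_values == lv].dropna().to_numpy() for lv in levels
            ]
            normal = all(
                len(g) >= 3 and stats.shapiro(g).pvalue > normality_alpha
                for g in groups
            )
            if normal:
                res = two_sample_t(groups[0], groups[1], variant="pooled")
            else:
                res = mann_whitney(groups[0], groups[1])
            results.append(
                ScreenResult(
                    column, res.method, res.statistic, res.df, res.p, res.p < alpha
                )
            )
        else:
            table = pd.crosstab(series, outcome_values)
            if table.shape[0] < 2:
                logger.warning(
                    "screen: %r has a single observed state, skipped", column
                )
                continue
            ct = pearson_chi2(
                table.to_numpy(), variable=column, row_labels=tuple(table.index)
            )
            results.append(
                ScreenResult(
                    column, "chi2", ct.chi2, float(ct.df), ct.p, ct.p < alpha
                )
            )
    return results


def screening_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Screening report as a DataFrame (TSV/JSON-ready)."""
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "test": r.test,
                "statistic": r.statistic,
                "df": r.df,
                "p": r.p,
                "selected": r.selected,
            }
            for r in results
        ]
    )
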