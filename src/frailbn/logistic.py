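"""Binary logistic regression from first principles.

IRLS maximum-likelihood fitting with Wald inference and odds-ratio
confidence intervals, reference-cell dummy coding, tolerance/VIF
collinearity diagnostics, and the Hosmer-Lemeshow calibration test.
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

#: two-sided 95% normal quantile used for all confidence intervals
CI_MULTIPLIER = 1.959964

#: |beta| beyond which the fit is declared separated
SEPARATION_BOUND = 15.0


class SeparationError(RuntimeError):
    """Coefficients diverged; the data are (quasi-)separated."""


class RankError(np.linalg.LinAlgError):
    """The information matrix is singular."""


@dataclass
class DesignMatrix:
    """Named regressor columns (intercept first) aligned to cohort records."""

    matrix: np.ndarray
    columns: list[str]
    reference_levels: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RegressionEffect:
    """One fitted term: coefficient, Wald inference and odds-ratio scale."""

    term: str
    B: float
    SE: float
    Wald: float
    OR: float
    ci95: tuple[float, float]
    p: float
    reference: str | None = None


@dataclass
class LogisticFit:
    effects: list[RegressionEffect]
    deviance: float
    n_iter: int
    converged: bool

    def coef(self) -> np.ndarray:
        return np.array([e.B for e in self.effects])


@dataclass
class CollinearityReport:
    """Per-term tolerance (1 - R^2_j) and VIF (1 / tolerance)."""

    terms: list[str]
    tolerance: np.ndarray
    vif: np.ndarray


def build_design(
    frame: pd.DataFrame | Cohort,
    predictors: list[str],
    reference_levels: dict[str, str] | None = None,
) -> DesignMatrix:
    """Dummy-code categorical predictors (k-1 indicators, reference cell).

    The reference level defaults to the first level in sorted order unless
    overridden; continuous columns enter as-is.  Indicator columns are
    named ``variable=state``.
    """
    data = frame.records if isinstance(frame, Cohort) else frame
    reference_levels = dict(reference_levels or {})
    columns: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["intercept"]
    refs: dict[str, str] = {}
    for var in predictors:
        series = data[var]
        if pd.api.types.is_numeric_dtype(series):
            columns.append(series.to_numpy(dtype=float))
            names.append(var)
            continue
        levels = list(pd.unique(series))
        ref = reference_levels.get(var, sorted(levels)[0])
        if ref not in levels:
            raise ValueError(f"{var}: reference level {ref!r} not observed")
        refs[var] = ref
        for level in [lv for lv in sorted(levels) if lv != ref]:
            columns.append((series == level).to_numpy(dtype=float))
            names.append(f"{var}={level}")
    return DesignMatrix(np.column_stack(columns), names, refs)


def fit_logistic(
    design: DesignMatrix,
    outcome: np.ndarray | pd.Series,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic fit via iteratively reweighted least squares.

    Convergence at ``max |delta beta| < tol`` (default 1e-8) within
    ``max_iter`` iterations; standard errors from the inverse observed
    information.  Diverging coefficients (|beta| > 15) raise
    :class:`SeparationError`; a singular information matrix raises
    :class:`RankError`.
    """
    X = np.asarray(design.matrix, dtype=float)
    y = np.asarray(outcome, dtype=float).ravel()
    n, k = X.shape
    if len(y) != n:
        raise ValueError("outcome length does not match design")
    if n <= k:
        raise ValueError("need more observations than columns")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")

    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        score = X.T @ (y - p)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise RankError("singular information matrix") from exc
        beta = beta + delta
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            raise SeparationError(
                f"|beta| exceeded {SEPARATION_BOUND}; data look separated"
            )
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("IRLS did not converge in %d iterations", max_iter)

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise RankError("singular information matrix") from exc
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore"):
        ll = float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
    deviance = -2.0 * ll

    effects = []
    for j, term in enumerate(design.columns):
        b, s = float(beta[j]), float(se[j])
        wald = (b / s) ** 2 if s > 0 else math.inf
        ref = None
        if "=" in term:
            ref = design.reference_levels.get(term.split("=", 1)[0])
        effects.append(
            RegressionEffect(
                term=term,
                B=b,
                SE=s,
                Wald=wald,
                OR=math.exp(b),
                ci95=(
                    math.exp(b - CI_MULTIPLIER * s),
                    math.exp(b + CI_MULTIPLIER * s),
                ),
                p=float(stats.chi2.sf(wald, 1)),
                reference=ref,
            )
        )
    return LogisticFit(effects, deviance, it, converged)


def collinearity(design: DesignMatrix) -> CollinearityReport:
    """Tolerance and VIF per non-intercept column via OLS R-squared.

    ``VIF_j = 1 / (1 - R^2_j)`` where ``R^2_j`` comes from regressing
    column j on all the others (intercept included); exactly collinear
    columns report infinite VIF.
    """
    idx = [i for i, c in enumerate(design.columns) if c != "intercept"]
    if len(idx) < 2:
        raise ValueError("need >= 2 non-intercept columns")
    X = design.matrix
    tolerances, vifs, terms = [], [], []
    for j in idx:
        others = [i for i in range(X.shape[1]) if i != j]
        xj = X[:, j]
        Z = X[:, others]
        coef, *_ = np.linalg.lstsq(Z, xj, rcond=None)
        resid = xj - Z @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((xj - xj.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"column {design.columns[j]!r} is constant")
        r2 = 1.0 - ss_res / ss_tot
        tolerance = max(1.0 - r2, 0.0)
        tolerances.append(tolerance)
        vifs.append(1.0 / tolerance if tolerance > 0 else math.inf)
        terms.append(design.columns[j])
    return CollinearityReport(terms, np.array(tolerances), np.array(vifs))


def hosmer_lemeshow(
    predicted: np.ndarray, observed: np.ndarray, groups: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow calibration test over risk-ordered bins.

    Records are ranked by predicted probability and split into ``groups``
    near-equal bins; ``chi2 = sum (O - E)^2 / (E (1 - E / n_g))`` with
    ``df = groups - 2``.  Bins with degenerate expected counts are merged
    into their neighbor (logged), reducing df accordingly.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if groups < 3:
        raise ValueError("groups must be >= 3")
    if np.any((predicted <= 0) | (predicted >= 1)):
        raise ValueError("predicted probabilities must lie strictly in (0, 1)")
    order = np.argsort(predicted, kind="stable")
    bins = np.array_split(order, groups)
    stats_per_bin = []
    for b in bins:
        if len(b) == 0:
            continue
        stats_per_bin.append(
            (float(observed[b].sum()), float(predicted[b].sum()), len(b))
        )
    merged: list[tuple[float, float, int]] = []
    for o, e, ng in stats_per_bin:
        if merged and (e <= 0 or e >= ng):
            logger.warning("hosmer_lemeshow: merging degenerate bin")
            po, pe, png = merged[-1]
            merged[-1] = (po + o, pe + e, png + ng)
        else:
            merged.append((o, e, ng))
    chi2 = 0.0
    for o, e, ng in merged:
        denom = e * (1.0 - e / ng)
        if denom <= 0:
            logger.warning("hosmer_lemeshow: bin with zero variance skipped")
            continue
        chi2 += (o - e) ** 2 / denom
    df = len(merged) - 2
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return float(chi2), df, p


def regression_frame(fit: LogisticFit) -> pd.DataFrame:
    """Regression report shaped like a published effects table."""
    return pd.DataFrame(
        [
            {
                "term": e.term,
                "reference": e.reference,
                "B": e.B,
                "SE": e.SE,
                "Wald": e.Wald,
                "OR": e.OR,
                "ci95_low": e.ci95[0],
                "ci95_high": e.ci95[1],
                "p": e.p,
            }
            for e in fit.effects
        ]
    )
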