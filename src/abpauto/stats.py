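"""Association statistics: correlation screening, odds ratios, logistic
regression, ROC/AUC with Hanley-McNeil intervals, and two-group comparisons.

Scalar conventions used throughout: all p-values are two-sided; confidence
intervals are 95% Wald-type unless noted; AUC uses the tie-aware rank
(Mann-Whitney) estimator with midranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    ConvergenceError,
    SeparationError,
    UndefinedStatisticError,
)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class CorrelationResult:
    estimate: float
    p: float
    n: int
    method: str  # "pearson" | "spearman"


@dataclass(frozen=True)
class OddsRatioResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    p: float
    source: str  # "table_2x2" | "logistic"
    correction_applied: bool = False


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float
    p: float
    method: str  # "t" | "wilcoxon" | "chi2" | "fisher"


@dataclass(frozen=True)
class CovariateEffect:
    name: str
    coef: float
    se: float
    odds_ratio: OddsRatioResult


@dataclass(frozen=True)
class LogisticFitResult:
    intercept: float
    effects: tuple[CovariateEffect, ...]
    converged: bool
    n_iterations: int
    n: int

    def odds_ratio(self, name: str) -> OddsRatioResult:
        for e in self.effects:
            if e.name == name:
                return e.odds_ratio
        raise KeyError(name)


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with the t-transform p-value (n-2 df).

    For two binary inputs this equals the phi coefficient of the implied
    2x2 table.  Requires >= 3 complete pairs and nonzero variance in both
    inputs.
    """
    x, y = _paired(x, y)
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined: zero variance input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(estimate=float(r), p=float(p), n=n, method="pearson")


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rho: Pearson correlation on tie-aware midranks."""
    x, y = _paired(x, y)
    n = len(x)
    if n < 3:
        raise UndefinedStatisticError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined: zero variance input")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(estimate=float(rho), p=float(p), n=n, method="spearman")


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """Odds ratio ad/bc of an exposure-by-outcome 2x2 table.

    ``a`` = exposed & outcome, ``b`` = exposed & no outcome, ``c`` =
    unexposed & outcome, ``d`` = unexposed & no outcome.  The 95% CI is
    Wald on the log scale; when any cell is zero the Haldane-Anscombe 0.5
    correction is added to every cell (flagged in the result).  The p-value
    comes from the Pearson chi-squared test, switching to Fisher's exact
    test when any expected count is below 5.
    """
    cells = [a, b, c, d]
    if any((not float(v).is_integer()) or v < 0 for v in cells):
        raise ValueError("cell counts must be nonnegative integers")
    a, b, c, d = (int(v) for v in cells)
    n = a + b + c + d
    if n < 1:
        raise UndefinedStatisticError("empty table")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise UndefinedStatisticError("odds ratio undefined: zero margin")

    correction = any(v == 0 for v in (a, b, c, d))
    aa, bb, cc, dd = ((v + 0.5 if correction else float(v)) for v in (a, b, c, d))
    or_est = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(or_est)
    ci_low = math.exp(log_or - Z95 * se)
    ci_high = math.exp(log_or + Z95 * se)

    table = np.array([[a, b], [c, d]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected < 5).any():
        _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    else:
        _, p, _, _ = sps.chi2_contingency(table, correction=False)
    return OddsRatioResult(
        or_estimate=or_est, ci_low=ci_low, ci_high=ci_high, p=float(p),
        source="table_2x2", correction_applied=correction,
    )


def fit_logistic(
    outcome: Sequence[int],
    covariates,
    names: Optional[Sequence[str]] = None,
) -> LogisticFitResult:
    """Maximum-likelihood logistic regression with Wald per-covariate ORs.

    Newton iterations with tolerance 1e-8 on the coefficient change and at
    most 100 iterations.  Complete or quasi-complete separation (any
    coefficient magnitude drifting beyond 15 on the log-odds scale, or a
    singular information matrix) raises :class:`SeparationError`.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(outcome, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if names is None:
        names = [f"x{i + 1}" for i in range(k)]
    if len(names) != k:
        raise ValueError("names length must match number of covariates")
    if len(y) != n:
        raise ValueError("outcome and covariates disagree in length")
    if n <= k + 1:
        raise UndefinedStatisticError(f"need n > {k + 1} observations, got {n}")
    if y.min() == y.max():
        raise UndefinedStatisticError("outcome has a single class")

    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            res = model.fit(method="newton", tol=1e-8, maxiter=100, disp=0)
    except PerfectSeparationError as exc:
        raise SeparationError(str(exc)) from exc
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular information matrix: {exc}") from exc

    params = np.asarray(res.params)
    if np.abs(params[1:]).max(initial=0.0) > 15:
        raise SeparationError(
            "complete or quasi-complete separation: coefficient magnitude > 15"
        )
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            "logistic fit did not converge in 100 iterations",
            trace=res.mle_retvals,
        )

    ses = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    effects = []
    for i, name in enumerate(names, start=1):
        coef, se = float(params[i]), float(ses[i])
        effects.append(
            CovariateEffect(
                name=name, coef=coef, se=se,
                odds_ratio=OddsRatioResult(
                    or_estimate=math.exp(coef),
                    ci_low=math.exp(coef - Z95 * se),
                    ci_high=math.exp(coef + Z95 * se),
                    p=float(pvals[i]),
                    source="logistic",
                ),
            )
        )
    return LogisticFitResult(
        intercept=float(params[0]),
        effects=tuple(effects),
        converged=True,
        n_iterations=int(res.mle_retvals.get("iterations", 0)),
        n=n,
    )


def roc_auc(score: Sequence[float], outcome: Sequence[int]) -> ROCResult:
    """Tie-aware rank (Mann-Whitney) AUC with a Hanley-McNeil 95% CI.

    Ties between a positive and a negative score count one half.  The CI
    uses the Hanley-McNeil variance (with Q1 = A/(2-A), Q2 = 2A^2/(1+A))
    clipped to [0, 1]; the p-value is a two-sided normal test of AUC
    against 0.5 with the same variance.  Binary predictors are treated as
    two-valued scores.
    """
    s, y = _paired(score, outcome)
    y = y.astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("ROC undefined: one outcome class absent")

    ranks = sps.rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    se = math.sqrt(max(var, 0.0))
    ci_low = min(max(auc - Z95 * se, 0.0), 1.0)
    ci_high = min(max(auc + Z95 * se, 0.0), 1.0)
    if se == 0.0:
        p = 1.0 if auc == 0.5 else 0.0
    else:
        z = (auc - 0.5) / se
        p = 2.0 * sps.norm.sf(abs(z))
    return ROCResult(
        auc=float(auc), ci_low=ci_low, ci_high=ci_high, p=float(p),
        n_pos=n_pos, n_neg=n_neg,
    )


def roc_coordinates(score: Sequence[float], outcome: Sequence[int]) -> list[dict]:
    """ROC curve coordinates: one (threshold, fpr, tpr) per distinct score,
    predicting positive when score >= threshold, plus the (inf, 0, 0) anchor."""
    s, y = _paired(score, outcome)
    y = y.astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("ROC undefined: one outcome class absent")
    coords = [{"threshold": math.inf, "fpr": 0.0, "tpr": 0.0}]
    for thr in sorted(np.unique(s), reverse=True):
        pred = s >= thr
        coords.append(
            {
                "threshold": float(thr),
                "fpr": float((pred & (y == 0)).sum() / n_neg),
                "tpr": float((pred & (y == 1)).sum() / n_pos),
            }
        )
    return coords


def compare_groups(
    x: Optional[Sequence[float]] = None,
    y: Optional[Sequence[float]] = None,
    *,
    table: Optional[Sequence[Sequence[int]]] = None,
    continuous_method: str = "t",
    table_method: str = "auto",
) -> GroupComparisonResult:
    """Two-group comparison dispatching on input type.

    Continuous data (two value sequences): Welch two-sample t-test by
    default, or the exact-when-possible Wilcoxon rank-sum test with
    ``continuous_method='wilcoxon'``.  Dichotomous data (a 2x2 ``table``):
    Pearson chi-squared, switching to Fisher's exact test when any
    expected count is below 5 (``table_method`` forces ``'chi2'`` or
    ``'fisher'``).  All p-values are two-sided.
    """
    if table is not None:
        t = np.asarray(table, dtype=float)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("table must be a nonnegative 2x2 array")
        n = t.sum()
        if n == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            raise UndefinedStatisticError("comparison undefined: empty margin")
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
        if table_method not in ("auto", "chi2", "fisher"):
            raise ValueError(f"unknown table method {table_method!r}")
        use_fisher = table_method == "fisher" or (
            table_method == "auto" and (expected < 5).any()
        )
        if use_fisher:
            stat, p = sps.fisher_exact(t, alternative="two-sided")
            return GroupComparisonResult(float(stat), float(p), "fisher")
        stat, p, _, _ = sps.chi2_contingency(t, correction=False)
        return GroupComparisonResult(float(stat), float(p), "chi2")

    if x is None or y is None:
        raise ValueError("provide either two value sequences or a 2x2 table")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise UndefinedStatisticError("comparison undefined: empty group")
    if continuous_method == "t":
        stat, p = sps.ttest_ind(x, y, equal_var=False)
        if math.isnan(p):  # both groups constant: degenerate t
            stat, p = (0.0, 1.0) if x.mean() == y.mean() else (math.inf, 0.0)
        return GroupComparisonResult(float(stat), float(p), "t")
    if continuous_method == "wilcoxon":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        return GroupComparisonResult(float(res.statistic), float(res.pvalue), "wilcoxon")
    raise ValueError(f"unknown continuous method {continuous_method!r}")
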