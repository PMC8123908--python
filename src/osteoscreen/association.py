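"""Correlation screen, logistic modelling and ROC evaluation.

The modelling chain mirrors a standard diagnostic-derivation workflow:
Spearman correlations of each candidate with the site T-scores, univariate
logistic regressions of osteoporosis status on each candidate, a p < 0.2
entry filter, bidirectional AIC stepwise selection starting from the full
candidate model, and ROC evaluation of the final model's linear predictor
with a DeLong confidence interval for the AUC.

Odds ratios carry a per-unit direction: ``direction=-1`` reports exp(-b) so
that OR > 1 means risk rises as the variable falls (e.g. "grip strength per
-1 kg"), ``direction=+1`` reports exp(b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort import ValidationError

__all__ = [
    "CorrelationResult",
    "LogisticFit",
    "RocResult",
    "ConvergenceError",
    "spearman",
    "univariate_logit",
    "candidate_filter",
    "multivariate_logit",
    "stepwise_select",
    "roc_auc",
]


class ConvergenceError(RuntimeError):
    """A logistic fit failed to converge (e.g. perfect separation)."""


@dataclass(frozen=True)
class CorrelationResult:
    x_label: str
    y_label: str
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class LogisticFit:
    """One term of a logistic model, with its direction-adjusted odds ratio."""

    label: str
    direction: int  # +1 or -1: OR is per +1 or per -1 unit of the variable
    coefficient: float  # raw coefficient b (per +1 unit)
    odds_ratio: float  # exp(direction * b)
    ci95: Tuple[float, float]
    p_value: float
    intercept: float
    converged: bool = True


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci95: Tuple[float, float]
    #: staircase points as (false positive rate, true positive rate)
    curve: tuple = field(default_factory=tuple)


def spearman(x: Sequence[float], y: Sequence[float], *, x_label: str = "x", y_label: str = "y") -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValidationError("Spearman correlation requires n >= 3")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Spearman rho is undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(x_label=x_label, y_label=y_label, rho=float(rho), p_value=float(p), n=len(x))


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Fit a logistic model with an intercept; raise ConvergenceError on failure."""
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = model.fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise ConvergenceError(f"perfect separation in logistic fit on {list(X.columns)}") from exc
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular design in logistic fit on {list(X.columns)}") from exc
    if not res.mle_retvals.get("converged", False) or not np.all(np.isfinite(res.bse)):
        raise ConvergenceError(f"logistic fit did not converge on {list(X.columns)}")
    return res


def _check_outcome(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("outcome must be a 0/1 vector")
    if len(np.unique(y)) < 2:
        raise ValidationError("both outcome classes must be present")
    return y


def _term_fit(res, label: str, direction: int) -> LogisticFit:
    b = float(res.params[label])
    se = float(res.bse[label])
    z = sps.norm.ppf(0.975)
    lo, hi = np.exp(direction * b - z * se), np.exp(direction * b + z * se)
    return LogisticFit(
        label=label,
        direction=direction,
        coefficient=b,
        odds_ratio=float(np.exp(direction * b)),
        ci95=(float(min(lo, hi)), float(max(lo, hi))),
        p_value=float(res.pvalues[label]),
        intercept=float(res.params["const"]),
        converged=True,
    )


def univariate_logit(
    outcome: Sequence[int], x: Sequence[float], *, direction: int = 1, label: str = "x"
) -> LogisticFit:
    """Maximum-likelihood fit of logit P(disease) = a + b*x for one candidate."""
    if direction not in (1, -1):
        raise ValidationError("direction must be +1 or -1")
    y = _check_outcome(outcome)
    X = pd.DataFrame({label: np.asarray(x, dtype=float)})
    if len(X) != len(y):
        raise ValidationError("outcome and x must have equal length")
    res = _fit_logit(y, X)
    return _term_fit(res, label, direction)


def candidate_filter(fits: Sequence[LogisticFit], p_threshold: float = 0.2) -> list:
    """Labels whose univariate p-value is strictly below the entry threshold."""
    return [f.label for f in fits if f.p_value < p_threshold]


def multivariate_logit(
    outcome: Sequence[int], X: pd.DataFrame, *, directions: Optional[Mapping[str, int]] = None
) -> dict:
    """Joint logistic fit; returns {label: LogisticFit} for every column of X."""
    y = _check_outcome(outcome)
    directions = dict(directions or {})
    res = _fit_logit(y, X)
    return {c: _term_fit(res, c, directions.get(c, 1)) for c in X.columns}


def stepwise_select(
    outcome: Sequence[int],
    candidates: pd.DataFrame,
    *,
    criterion: str = "aic",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    directions: Optional[Mapping[str, int]] = None,
) -> tuple:
    """Bidirectional stepwise logistic selection starting from the full model.

    ``criterion='aic'`` (default) greedily applies the single add/drop move
    that most reduces AIC until no move improves it.  ``criterion='p'`` uses
    the classic Wald-p backward/forward rule with ``p_remove``/``p_enter``.
    Returns ``(selected_labels, {label: LogisticFit})``.
    """
    y = _check_outcome(outcome)
    if candidates.shape[1] < 1:
        raise ValidationError("at least one candidate is required")
    labels = list(candidates.columns)
    current = list(labels)

    def fit_aic(cols) -> float:
        if not cols:
            res = _fit_logit(y, pd.DataFrame(index=candidates.index))
        else:
            res = _fit_logit(y, candidates[cols])
        return float(res.aic)

    def guarded(fn, step: str):
        try:
            return fn()
        except ConvergenceError as exc:
            raise ConvergenceError(f"stepwise step '{step}': {exc}") from exc

    if criterion == "aic":
        best = guarded(lambda: fit_aic(current), "initial full model")
        while True:
            moves = []
            for c in current:
                cols = [k for k in current if k != c]
                moves.append(("drop", c, guarded(lambda cols=cols: fit_aic(cols), f"drop {c}")))
            for c in labels:
                if c not in current:
                    cols = current + [c]
                    moves.append(("add", c, guarded(lambda cols=cols: fit_aic(cols), f"add {c}")))
            if not moves:
                break
            kind, c, aic = min(moves, key=lambda m: m[2])
            if aic < best - 1e-9:
                best = aic
                if kind == "drop":
                    current.remove(c)
                else:
                    current.append(c)
            else:
                break
    elif criterion == "p":
        while True:
            changed = False
            if current:
                res = guarded(lambda: _fit_logit(y, candidates[current]), "backward")
                pvals = {c: float(res.pvalues[c]) for c in current}
                worst = max(pvals, key=pvals.get)
                if pvals[worst] > p_remove:
                    current.remove(worst)
                    changed = True
            for c in labels:
                if c not in current:
                    res = guarded(
                        lambda c=c: _fit_logit(y, candidates[current + [c]]), f"forward {c}"
                    )
                    if float(res.pvalues[c]) < p_enter:
                        current.append(c)
                        changed = True
                        break
            if not changed:
                break
    else:
        raise ValidationError(f"unknown stepwise criterion {criterion!r}")

    current = [c for c in labels if c in current]  # stable order
    if not current:
        return [], {}
    fits = multivariate_logit(y, candidates[current], directions=directions)
    return current, fits


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    all_scores = np.concatenate([pos, neg])
    ranks = sps.rankdata(all_scores)
    m = len(pos)
    n = len(neg)
    return (ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)


def _delong_ci(pos: np.ndarray, neg: np.ndarray, level: float = 0.95) -> Tuple[float, float]:
    """DeLong variance-based CI for the AUC of a single marker."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = sps.rankdata(all_scores)
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # structural components
    v01 = (r_all[:m] - r_pos) / n  # per diseased subject
    v10 = 1.0 - (r_all[m:] - r_neg) / m  # per non-diseased subject
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def roc_auc(scores: Sequence[float], labels: Sequence[int], *, ci: str = "delong") -> RocResult:
    """ROC analysis of a continuous score against a 0/1 outcome.

    AUC is the Mann-Whitney concordance probability (tied scores count 1/2);
    the confidence interval uses the DeLong structural-component variance.
    """
    y = _check_outcome(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValidationError("scores and labels must have equal length")
    pos = s[y == 1]
    neg = s[y == 0]
    auc = float(_mann_whitney_auc(pos, neg))
    if ci == "delong":
        ci95 = _delong_ci(pos, neg)
    elif ci == "none":
        ci95 = (float("nan"), float("nan"))
    else:
        raise ValidationError(f"unknown CI method {ci!r}")
    curve = _roc_curve(s, y)
    return RocResult(auc=auc, ci95=ci95, curve=curve)


def _roc_curve(scores: np.ndarray, y: np.ndarray) -> tuple:
    """(FPR, TPR) staircase over all distinct thresholds, positivity = score >= t."""
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    yy = y[order]
    m = yy.sum()
    n = len(yy) - m
    tps = np.cumsum(yy)
    fps = np.cumsum(1 - yy)
    # keep the last index of each tied block
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    pts = [(0.0, 0.0)] + [(float(fps[i] / n), float(tps[i] / m)) for i in distinct]
    return tuple(pts)
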