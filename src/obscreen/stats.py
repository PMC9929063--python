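"""Statistical primitives behind the tool derivation.

Four primitives carry the whole derivation: a standardized linear fit
(its coefficients, SPRCs, become item scores after multiplying by 100),
a maximum-likelihood logistic fit (odds ratios with Wald intervals),
variance-inflation factors for collinearity, and an ROC sweep with
Youden-index cutoff selection.  Spearman's rank correlation supports the
second-trimester STEP-2 rule.

Missing data are handled by listwise deletion: a record with any missing
value among the modelled columns is dropped and ``n_used`` reports the
complete-case count, matching how the derivation models report their n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import CollinearityError, DegenerateInputError
from .schema import Cohort, Record

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

OutcomeSpec = "str | Callable[[Record], Optional[int]]"


# ---------------------------------------------------------------------------
# results containers


@dataclass
class TermFit:
    item_id: str
    coefficient: float = float("nan")
    std_error: float = float("nan")
    standardized_coefficient: Optional[float] = None
    odds_ratio: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: float = float("nan")
    vif: Optional[float] = None
    separation: bool = False


@dataclass
class FitResult:
    """Terms of one fitted model plus the complete-case count."""

    terms: list[TermFit]
    model_kind: str  # "linear_standardized" | "logistic_ml"
    n_used: int

    def term(self, item_id: str) -> TermFit:
        for t in self.terms:
            if t.item_id == item_id:
                return t
        raise KeyError(item_id)

    @property
    def item_ids(self) -> list[str]:
        return [t.item_id for t in self.terms]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.terms]).set_index("item_id")


@dataclass
class RocCurve:
    """Threshold sweep (predict positive when score >= threshold) plus rank AUC."""

    points: list[tuple[float, float, float]]  # (threshold, sensitivity, specificity)
    auc: float


@dataclass
class CutoffResult:
    threshold: float
    sensitivity: float
    specificity: float
    auc: float


# ---------------------------------------------------------------------------
# design-matrix assembly


def complete_cases(
    cohort: Cohort, outcome: OutcomeSpec, items: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Outcome vector and item matrix over records complete in all modelled columns."""
    ys = cohort.outcome_values(outcome)
    rows, y_out = [], []
    for rec, y in zip(cohort, ys):
        if y is None:
            continue
        vals = [rec.indicators.get(i) for i in items]
        if any(v is None for v in vals):
            continue
        rows.append(vals)
        y_out.append(int(y))
    X = np.asarray(rows, dtype=float).reshape(len(rows), len(items))
    return np.asarray(y_out, dtype=float), X


def _check_two_classes(y: np.ndarray) -> None:
    if y.size == 0 or len(np.unique(y)) < 2:
        raise DegenerateInputError("outcome must contain both classes among complete cases")


def _aliased_columns(X: np.ndarray, items: Sequence[str]) -> list[str]:
    """Columns linearly dependent on the preceding ones (QR diagnostic)."""
    Xc = X - X.mean(axis=0)
    scale = Xc.std(axis=0, ddof=0)
    aliased = [items[j] for j in range(X.shape[1]) if scale[j] == 0.0]
    keep = [j for j in range(X.shape[1]) if scale[j] > 0.0]
    if keep:
        _, R = np.linalg.qr(Xc[:, keep] / scale[keep])
        diag = np.abs(np.diag(R))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
        aliased += [items[keep[j]] for j in range(len(keep)) if diag[j] <= max(tol, 1e-10)]
    return aliased


# ---------------------------------------------------------------------------
# fits


def fit_linear_standardized(
    cohort: Cohort,
    outcome: OutcomeSpec,
    items: Sequence[str],
    standardize_outcome: bool = True,
) -> FitResult:
    """OLS of the 0/1 outcome on 0/1 indicators after unit-variance scaling.

    The returned ``standardized_coefficient`` per item is the SPRC
    consumed by the x100 scoring rule.  Both predictors and (by default)
    the outcome are standardized; ``standardize_outcome=False`` leaves
    the outcome on its raw 0/1 scale.
    """
    y, X = complete_cases(cohort, outcome, items)
    _check_two_classes(y)
    if y.size < max(2, len(items) + 1):
        raise DegenerateInputError(f"too few complete cases ({y.size}) for {len(items)} predictors")
    aliased = _aliased_columns(X, items)
    if aliased:
        raise CollinearityError(aliased)

    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    Xs = (X - X.mean(axis=0)) / sx
    ys = (y - y.mean()) / sy if standardize_outcome else y - y.mean()
    model = sm.OLS(ys, sm.add_constant(Xs)).fit()
    terms = []
    for j, item in enumerate(items):
        # beta is the coefficient of the scaled-predictor fit; with the
        # outcome also scaled it is the SPRC proper.
        beta = model.params[j + 1]
        sprc = beta
        terms.append(
            TermFit(
                item_id=item,
                coefficient=beta * (sy if standardize_outcome else 1.0) / sx[j],
                std_error=model.bse[j + 1],
                standardized_coefficient=float(sprc),
                p_value=float(model.pvalues[j + 1]),
            )
        )
    return FitResult(terms=terms, model_kind="linear_standardized", n_used=int(y.size))


def _separation_flags(y: np.ndarray, X: np.ndarray) -> list[bool]:
    """A binary term is flagged when its 2x2 table with the outcome has an empty cell."""
    flags = []
    for j in range(X.shape[1]):
        x = X[:, j]
        cells = [
            np.sum((x == 1) & (y == 1)),
            np.sum((x == 1) & (y == 0)),
            np.sum((x == 0) & (y == 1)),
            np.sum((x == 0) & (y == 0)),
        ]
        flags.append(any(c == 0 for c in cells))
    return flags


def fit_logistic_ml(cohort: Cohort, outcome: OutcomeSpec, items: Sequence[str]) -> FitResult:
    """Maximum-likelihood logistic regression with Wald 95% intervals.

    OR = exp(beta); CI = exp(beta +/- 1.96 SE).  Complete separation is
    flagged per term (the odds ratio is reported as diverging toward 0
    or infinity) instead of raising.
    """
    y, X = complete_cases(cohort, outcome, items)
    _check_two_classes(y)
    aliased = _aliased_columns(X, items)
    if aliased:
        raise CollinearityError(aliased)
    flags = _separation_flags(y, X)

    design = sm.add_constant(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, method="newton", maxiter=100, tol=1e-10)
        except Exception:
            fit = sm.Logit(y, design).fit(disp=0, method="lbfgs", maxiter=500)

    terms = []
    for j, item in enumerate(items):
        beta = float(fit.params[j + 1])
        se = float(fit.bse[j + 1])
        if flags[j]:
            diverging = 0.0 if beta < 0 else float("inf")
            terms.append(
                TermFit(
                    item_id=item,
                    coefficient=beta,
                    std_error=se,
                    odds_ratio=diverging,
                    ci_low=0.0,
                    ci_high=float("inf"),
                    p_value=float(fit.pvalues[j + 1]),
                    separation=True,
                )
            )
        else:
            terms.append(
                TermFit(
                    item_id=item,
                    coefficient=beta,
                    std_error=se,
                    odds_ratio=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - Z_95 * se)),
                    ci_high=float(np.exp(beta + Z_95 * se)),
                    p_value=float(fit.pvalues[j + 1]),
                )
            )
    return FitResult(terms=terms, model_kind="logistic_ml", n_used=int(y.size))


def fit_crude(cohort: Cohort, outcome: OutcomeSpec, items: Sequence[str]) -> FitResult:
    """Univariate logistic fit per item, assembled into one crude-model result.

    ``n_used`` is the per-term maximum (each univariate model keeps the
    records complete for its own item).
    """
    terms: list[TermFit] = []
    n_used = 0
    for item in items:
        single = fit_logistic_ml(cohort, outcome, [item])
        terms.append(single.terms[0])
        n_used = max(n_used, single.n_used)
    return FitResult(terms=terms, model_kind="logistic_ml", n_used=n_used)


def vif(cohort: Cohort, items: Sequence[str], outcome: OutcomeSpec = "admin_cooperation") -> dict[str, float]:
    """Variance inflation factor 1/(1-R^2_j), each item regressed on the rest.

    Computed on the same complete-case set as the joint model (records
    complete in outcome and all items).  Perfect collinearity yields an
    ``inf`` sentinel.
    """
    if len(items) < 2:
        raise DegenerateInputError("VIF needs at least two items")
    _, X = complete_cases(cohort, outcome, items)
    out: dict[str, float] = {}
    for j, item in enumerate(items):
        xj = X[:, j]
        others = np.delete(X, j, axis=1)
        if xj.std(ddof=0) == 0.0:
            out[item] = float("inf")
            continue
        design = sm.add_constant(others)
        beta, *_ = np.linalg.lstsq(design, xj, rcond=None)
        resid = xj - design @ beta
        ss_tot = float(np.sum((xj - xj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        out[item] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# correlation and ROC


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise DegenerateInputError("spearman_rho needs two equal-length vectors with n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateInputError("spearman_rho undefined for a zero-variance vector")
    return float(scipy.stats.spearmanr(x, y).statistic)


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC points at the distinct score values; AUC by the Mann-Whitney statistic.

    A score tied between classes contributes 1/2 to the AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise DegenerateInputError("scores and labels must be equal-length vectors")
    _check_two_classes(y)
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    ranks = scipy.stats.rankdata(s)
    auc = (float(ranks[y == 1].sum()) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    points = []
    for t in np.unique(s):
        pred = s >= t
        sens = float(np.sum(pred & (y == 1))) / n1
        spec = float(np.sum(~pred & (y == 0))) / n0
        points.append((float(t), sens, spec))
    return RocCurve(points=points, auc=float(auc))


def select_cutoff(curve: RocCurve, criterion: str = "youden") -> CutoffResult:
    """Choose the cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties break toward the lower threshold, i.e. the more sensitive
    screen.
    """
    if criterion != "youden":
        raise ValueError(f"unknown cutoff criterion {criterion!r}")
    if not curve.points:
        raise DegenerateInputError("empty ROC curve")
    best = None
    for t, sens, spec in sorted(curve.points, key=lambda p: p[0]):
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, t, sens, spec = best
    return CutoffResult(threshold=t, sensitivity=sens, specificity=spec, auc=curve.auc)
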