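"""The statistical battery applied to (ΔpLDDT, Δ⟨pLDDT⟩, effect) triples.

Covers: Pearson/Spearman correlations with a seeded-bootstrap (or Fisher-z)
standard error, a two-predictor ordinary-least-squares regression evaluated
by train/test correlation, Kruskal–Wallis tests across mutation categories,
exact-binomial sign enrichment (the fraction of destabilizing mutations
whose site confidence drops), Benjamini–Hochberg adjustment, and a
stratified per-category correlation report with BH applied across the whole
report as one family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y
from statsmodels.stats.multitest import multipletests

from .errors import (
    EmptyInputError,
    UndefinedCorrelationError,
    UndefinedFractionError,
)

__all__ = [
    "CorrelationResult",
    "RegressionFit",
    "StratifiedReport",
    "DeltaRegressor",
    "correlation",
    "fit_two_term_regression",
    "kruskal_wallis",
    "sign_enrichment",
    "bh_adjust",
    "stratified_report",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation estimate with uncertainty, p-value and sample size."""

    estimate: float
    uncertainty: float
    p_value: float
    n: int
    method: str = "pearson"
    adjusted_p: float | None = None


def _validate_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EmptyInputError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise EmptyInputError(f"need n >= 3 points, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise EmptyInputError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    return x, y


def _point_estimate(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    return float(sps.spearmanr(x, y).statistic)


def correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    boot_reps: int = 1000,
    seed: int = 0,
    uncertainty: str = "bootstrap",
) -> CorrelationResult:
    """Correlation with a two-sided p-value and an uncertainty estimate.

    The uncertainty is the SD of the estimate over ``boot_reps`` seeded
    nonparametric bootstrap resamples (pairs resampled together); set
    ``uncertainty='fisher'`` for the closed-form Fisher-z standard error
    ``(1 - r^2) / sqrt(n - 3)`` instead. p-values use the t-distribution
    transform (on ranks for Spearman).
    """
    x, y = _validate_xy(x, y)
    if method not in {"pearson", "spearman"}:
        raise EmptyInputError(f"unknown method {method!r}")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    else:
        res = sps.spearmanr(x, y)
    estimate = float(res.statistic)
    # |r| = 1 degenerates the t-transform to p = 0; keep p in (0, 1]
    p_value = max(float(res.pvalue), float(np.nextafter(0.0, 1.0)))
    n = x.size
    if uncertainty == "fisher":
        se = (1.0 - estimate**2) / np.sqrt(n - 3)
    elif uncertainty == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(boot_reps)
        for b in range(boot_reps):
            idx = rng.integers(0, n, size=n)
            xb, yb = x[idx], y[idx]
            if np.ptp(xb) == 0 or np.ptp(yb) == 0:
                reps[b] = np.nan  # degenerate resample carries no information
            else:
                reps[b] = _point_estimate(xb, yb, method)
        se = float(np.nanstd(reps, ddof=1))
    else:
        raise EmptyInputError(f"unknown uncertainty scheme {uncertainty!r}")
    return CorrelationResult(
        estimate=estimate, uncertainty=float(se), p_value=p_value, n=n, method=method
    )


class DeltaRegressor(BaseEstimator, RegressorMixin):
    """Two-predictor OLS: effect ~ intercept + site_delta + global_delta.

    A scikit-learn-compatible estimator (plain ``LinearRegression`` on the
    two confidence deltas) so it composes with sklearn pipelines and model
    selection. Fitted attributes: ``intercept_``, ``coef_site_``,
    ``coef_global_``.
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if X.shape[1] != 2:
            raise EmptyInputError("X must have columns (site_delta, global_delta)")
        if X.shape[0] < 3:
            raise EmptyInputError("need at least 3 training points")
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < 3:
            import warnings

            warnings.warn("rank-deficient predictors; coefficients not unique")
        self._lm = LinearRegression().fit(X, y)
        self.intercept_ = float(self._lm.intercept_)
        self.coef_ = self._lm.coef_.copy()
        self.coef_site_ = float(self.coef_[0])
        self.coef_global_ = float(self.coef_[1])
        return self

    def predict(self, X):
        check_is_fitted(self, "intercept_")
        X = check_array(X)
        return self._lm.predict(X)


@dataclass(frozen=True)
class RegressionFit:
    """OLS coefficients plus predicted-vs-observed correlations."""

    intercept: float
    coef_site: float
    coef_global: float
    train_pcc: CorrelationResult
    test_pcc: CorrelationResult | None = None


def fit_two_term_regression(
    train: tuple[Sequence[float], Sequence[float], Sequence[float]],
    test: tuple[Sequence[float], Sequence[float], Sequence[float]] | None = None,
    boot_reps: int = 1000,
    seed: int = 0,
) -> RegressionFit:
    """Fit effect ~ site_delta + global_delta on ``train``; score both sets.

    ``train``/``test`` are (site_deltas, global_deltas, effects) triples;
    the reported correlations are Pearson between predicted and observed
    effects.
    """
    site, glob, y = (np.asarray(a, dtype=float) for a in train)
    X = np.column_stack([site, glob])
    model = DeltaRegressor().fit(X, y)
    train_pcc = correlation(model.predict(X), y, boot_reps=boot_reps, seed=seed)
    test_pcc = None
    if test is not None:
        site_t, glob_t, y_t = (np.asarray(a, dtype=float) for a in test)
        X_t = np.column_stack([site_t, glob_t])
        test_pcc = correlation(model.predict(X_t), y_t, boot_reps=boot_reps, seed=seed)
    return RegressionFit(
        intercept=model.intercept_,
        coef_site=model.coef_site_,
        coef_global=model.coef_global_,
        train_pcc=train_pcc,
        test_pcc=test_pcc,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p across groups.

    With no separation at all (every value identical) H is 0 and p is 1.
    """
    if len(groups) < 2:
        raise EmptyInputError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise EmptyInputError("empty group")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def sign_enrichment(
    site_deltas: Sequence[float], effects: Sequence[float]
) -> tuple[float, float]:
    """Fraction of destabilizing mutations with a site confidence drop.

    Destabilizing means effect strictly > 0 (zeros excluded); the p-value is
    a two-sided exact binomial test of that fraction against 0.5.
    """
    site = np.asarray(site_deltas, dtype=float)
    eff = np.asarray(effects, dtype=float)
    if site.shape != eff.shape:
        raise EmptyInputError("unequal lengths")
    destab = eff > 0
    m = int(destab.sum())
    if m == 0:
        raise UndefinedFractionError("no destabilizing mutations")
    k = int((site[destab] < 0).sum())
    p = sps.binomtest(k, m, 0.5, alternative="two-sided").pvalue
    return k / m, float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise EmptyInputError("no p-values")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise EmptyInputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class StratifiedReport:
    """Per-category-level correlations plus Kruskal–Wallis per category.

    ``rows`` has one record per (category, level, predictor) with PCC/SCC,
    raw and BH-adjusted p-values (one BH family per report); ``kruskal``
    holds the H statistic and p for site deltas across each category's
    levels.
    """

    rows: pd.DataFrame
    kruskal: pd.DataFrame


def stratified_report(
    data: pd.DataFrame,
    categories: Sequence[str],
    effect_col: str = "effect",
    predictors: Sequence[str] = ("site_delta", "global_delta"),
    boot_reps: int = 200,
    seed: int = 0,
    min_n: int = 3,
) -> StratifiedReport:
    """Correlations of each predictor with the effect, per category level.

    Levels with fewer than ``min_n`` mutations are emitted with absent
    correlations and flagged. BH adjustment is applied once across every
    raw p-value in the report.
    """
    missing = (set(categories) | {effect_col} | set(predictors)) - set(data.columns)
    if missing:
        raise EmptyInputError(f"data missing columns {sorted(missing)}")
    rows = []
    kw_rows = []
    rng = np.random.default_rng(seed)
    for cat in categories:
        levels = data[cat].dropna().unique()
        groups = [
            data.loc[data[cat] == level, "site_delta"].to_numpy() for level in levels
        ]
        if len(groups) >= 2:
            h, p = kruskal_wallis(groups)
            kw_rows.append({"category": cat, "H": h, "p_value": p})
        for level in levels:
            sub = data[data[cat] == level]
            for pred in predictors:
                row = {
                    "category": cat,
                    "level": level,
                    "predictor": pred,
                    "n": len(sub),
                    "flagged": len(sub) < min_n,
                }
                if len(sub) >= min_n:
                    try:
                        for method, label in (("pearson", "pcc"), ("spearman", "scc")):
                            res = correlation(
                                sub[pred],
                                sub[effect_col],
                                method=method,
                                boot_reps=boot_reps,
                                seed=int(rng.integers(2**31)),
                            )
                            row[label] = res.estimate
                            row[f"{label}_se"] = res.uncertainty
                            row[f"{label}_p"] = res.p_value
                    except UndefinedCorrelationError:
                        row["flagged"] = True
                rows.append(row)
    df = pd.DataFrame(rows)
    # One BH family per report: PCC and SCC p-values adjusted jointly.
    family: list[tuple[str, int]] = []
    raw: list[float] = []
    for label in ("pcc", "scc"):
        col = f"{label}_p"
        if col in df.columns:
            for i in df.index[df[col].notna()]:
                family.append((f"{label}_p_bh", i))
                raw.append(float(df.at[i, col]))
    if raw:
        # t-transform p-values underflow to exactly 0 for |r|=1 at tiny n;
        # floor them at the smallest positive float for the adjustment.
        tiny = float(np.nextafter(0.0, 1.0))
        adjusted = bh_adjust([max(p, tiny) for p in raw])
        for (col, i), adj in zip(family, adjusted):
            df.at[i, col] = adj
    return StratifiedReport(rows=df, kruskal=pd.DataFrame(kw_rows))
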