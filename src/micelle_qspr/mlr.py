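"""Ordinary least-squares regression on a descriptor subset.

The model form is ``y = b0 + Σ b_k x_k`` fitted by QR-based least squares
with an explicit rank check (rank-deficient designs raise, never a silent
pseudo-inverse).  Coefficient inference (standard errors, 95% confidence
intervals, two-sided t-test p-values, standardized coefficients) follows the
classical normal-theory formulas.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .data_io import DescriptorTable

__all__ = [
    "LinearModel",
    "CoefficientStats",
    "RankDeficientError",
    "fit_mlr",
    "predict",
    "predict_response_scale",
    "coefficient_stats",
    "f_statistic",
]


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is not full column rank."""


@dataclass(frozen=True)
class LinearModel:
    """Fitted OLS model on a named descriptor subset."""

    descriptor_subset: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    training_ids: tuple[str, ...]
    sse: float

    def __post_init__(self) -> None:
        coefs = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coefs)
        if coefs.shape != (len(self.descriptor_subset),):
            raise ValueError("one coefficient per descriptor required")
        if self.sse < -1e-12:
            raise ValueError("sse must be non-negative")

    def to_json(self) -> str:
        return json.dumps(
            {
                "descriptors": list(self.descriptor_subset),
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "training_ids": list(self.training_ids),
                "sse": self.sse,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        obj = json.loads(text)
        return cls(
            descriptor_subset=tuple(obj["descriptors"]),
            coefficients=np.asarray(obj["coefficients"], dtype=float),
            intercept=float(obj["intercept"]),
            training_ids=tuple(obj["training_ids"]),
            sse=float(obj["sse"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LinearModel":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class CoefficientStats:
    """Per-term inference for a fitted model (intercept first)."""

    terms: tuple[str, ...]
    b: np.ndarray
    std_error: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    standardized: np.ndarray  # NaN for the intercept
    p_value: np.ndarray
    residual_df: int
    degenerate: bool = field(default=False)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "term": self.terms,
                "B": self.b,
                "std_error": self.std_error,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "standardized_coefficient": self.standardized,
                "p_value": self.p_value,
            }
        ).set_index("term")


def _design_matrix(table: DescriptorTable, subset) -> np.ndarray:
    X = np.column_stack([np.ones(table.n_samples), table.columns(subset)]) \
        if subset else np.ones((table.n_samples, 1))
    return X


def _solve_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """QR least squares with rank check; returns (beta, sse)."""
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    if diag.size and diag.min() <= 1e-10 * max(diag.max(), 1e-300):
        raise RankDeficientError("design matrix is rank deficient")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def fit_mlr(table: DescriptorTable, subset) -> LinearModel:
    """Fit OLS of the response on ``subset`` (with intercept)."""
    subset = tuple(subset)
    if table.response is None:
        raise ValueError("table carries no response")
    missing = set(subset) - set(table.descriptor_names)
    if missing:
        raise KeyError(f"descriptors not in table: {sorted(missing)}")
    if table.n_samples <= len(subset) + 1:
        raise ValueError(
            f"{table.n_samples} samples cannot support {len(subset)} descriptors"
        )
    X = _design_matrix(table, subset)
    beta, sse = _solve_ols(X, table.response)
    return LinearModel(
        descriptor_subset=subset,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        training_ids=table.sample_ids,
        sse=sse,
    )


def predict(model: LinearModel, table: DescriptorTable) -> np.ndarray:
    """Predict the (possibly ln-scale) response for every row of ``table``."""
    X = table.columns(model.descriptor_subset)
    return model.intercept + X @ model.coefficients


def predict_response_scale(model: LinearModel, table: DescriptorTable) -> np.ndarray:
    """Predictions pushed back to the raw response scale (exp of the ln fit)."""
    pred = predict(model, table)
    return np.exp(pred) if table.response_scale == "ln" else pred


def coefficient_stats(
    model: LinearModel, table: DescriptorTable, alpha: float = 0.05
) -> CoefficientStats:
    """Normal-theory inference for every term of ``model`` refit on ``table``.

    Standardized coefficients use the convention ``B · sd(x)/sd(y)`` (sample
    sd); the intercept has no standardized analogue and is reported as NaN.
    """
    subset = model.descriptor_subset
    X = _design_matrix(table, subset)
    y = table.response
    n, k = X.shape
    df = n - k
    if df < 1:
        raise ValueError("zero residual degrees of freedom")
    beta, sse = _solve_ols(X, y)
    xtx_inv = np.linalg.inv(X.T @ X)
    sigma2 = sse / df
    degenerate = sigma2 <= 1e-28
    if degenerate:
        warnings.warn("exact fit: standard errors degenerate to zero", stacklevel=2)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    sd_y = float(np.std(y, ddof=1))
    std_coef = np.full(k, np.nan)
    if subset:
        sd_x = np.std(table.columns(subset), axis=0, ddof=1)
        std_coef[1:] = beta[1:] * sd_x / sd_y
    return CoefficientStats(
        terms=("intercept",) + tuple(subset),
        b=beta,
        std_error=se,
        ci_lower=beta - tcrit * se,
        ci_upper=beta + tcrit * se,
        standardized=std_coef,
        p_value=pvals,
        residual_df=df,
        degenerate=bool(degenerate),
    )


def f_statistic(r2: float, n: int, p: int) -> float:
    """Overall regression F: ``(R²/p) / ((1−R²)/(n−p−1))``."""
    if not 0 <= r2 <= 1:
        raise ValueError("r2 must lie in [0, 1]")
    if n <= p + 1:
        raise ValueError("n must exceed p + 1")
    if r2 == 1:
        warnings.warn("R² == 1: F statistic is infinite", stacklevel=2)
        return float("inf")
    return (r2 / p) / ((1 - r2) / (n - p - 1))
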