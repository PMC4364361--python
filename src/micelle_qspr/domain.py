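"""Leverage-based applicability domain (Williams plot analysis).

A query sample's leverage ``h_i = x_i (XᵀX)⁻¹ x_iᵀ`` (X = training design
matrix including the intercept column) measures its distance from the
training descriptor centroid; predictions with ``h_i`` above the warning
leverage ``h* = 3(p+1)/n`` extrapolate beyond the model's domain.  The
second axis of the Williams plot is the standardized cross-validated
residual: training residuals are leave-one-out residuals scaled by their own
sample sd, test residuals are prediction residuals scaled by the training
RMSE, and samples beyond ±3 standardized units fall outside the domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DescriptorTable
from .mlr import LinearModel, _design_matrix, predict
from .validation import loo_cv, rmse

__all__ = [
    "ADReport",
    "leverages",
    "critical_leverage",
    "standardized_cv_residuals",
    "williams_report",
]

RESIDUAL_LIMIT = 3.0


@dataclass(frozen=True)
class ADReport:
    """Per-sample leverage/residual table with domain flags."""

    sample_ids: tuple[str, ...]
    sets: tuple[str, ...]  # "train" / "test"
    leverage: np.ndarray
    std_residual: np.ndarray
    in_domain: np.ndarray
    h_star: float
    residual_limit: float = RESIDUAL_LIMIT
    residual_convention: str = (
        "train: LOO residual / sd(LOO residuals); test: residual / training RMSE"
    )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.sample_ids,
                "set": self.sets,
                "leverage": self.leverage,
                "std_residual": self.std_residual,
                "in_domain": self.in_domain,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "h_star": self.h_star,
                "residual_limit": self.residual_limit,
                "residual_convention": self.residual_convention,
                "samples": self.to_dataframe().to_dict(orient="records"),
            },
            indent=2,
            default=bool,
        )


def leverages(
    train_table: DescriptorTable, query_table: DescriptorTable, subset
) -> np.ndarray:
    """Hat values of query samples against the training design matrix."""
    subset = tuple(subset)
    X = _design_matrix(train_table, subset)
    Q = _design_matrix(query_table, subset)
    xtx = X.T @ X
    # solve instead of explicit inverse; equals x_i (X'X)^-1 x_i'
    sol = np.linalg.solve(xtx, Q.T)
    return np.einsum("ij,ji->i", Q, sol)


def critical_leverage(p: int, n: int) -> float:
    """Warning leverage ``h* = 3(p+1)/n``."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 3.0 * (p + 1) / n


def standardized_cv_residuals(
    table: DescriptorTable, subset, loo_predictions: np.ndarray
) -> np.ndarray:
    """Training LOO residuals standardized by their own sample sd."""
    resid = table.response - np.asarray(loo_predictions, float)
    sd = float(np.std(resid, ddof=1))
    # an (essentially) exact fit has no residual spread to standardize by
    if sd <= 1e-10 * (1.0 + float(np.abs(table.response).max())):
        return np.zeros_like(resid)
    return resid / sd


def williams_report(
    train_table: DescriptorTable,
    test_table: DescriptorTable,
    subset,
    model: LinearModel,
) -> ADReport:
    """Assemble the Williams-plot table for training and test samples."""
    subset = tuple(subset)
    h_train = leverages(train_table, train_table, subset)
    h_test = leverages(train_table, test_table, subset)
    _, loo_pred = loo_cv(train_table, subset)
    r_train = standardized_cv_residuals(train_table, subset, loo_pred)
    train_pred = predict(model, train_table)
    scale = rmse(train_table.response, train_pred)
    test_resid = test_table.response - predict(model, test_table)
    r_test = test_resid / scale if scale > 0 else np.zeros_like(test_resid)

    h = np.concatenate([h_train, h_test])
    r = np.concatenate([r_train, r_test])
    ids = train_table.sample_ids + test_table.sample_ids
    sets = ("train",) * train_table.n_samples + ("test",) * test_table.n_samples
    h_star = critical_leverage(len(subset), train_table.n_samples)
    in_domain = (h <= h_star) & (np.abs(r) <= RESIDUAL_LIMIT)
    return ADReport(
        sample_ids=ids,
        sets=sets,
        leverage=h,
        std_residual=r,
        in_domain=in_domain,
        h_star=h_star,
    )
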