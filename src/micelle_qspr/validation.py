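"""Internal and external validation statistics plus Y-randomization.

Internal: R² (training reference mean), leave-one-out cross-validated R²cv,
RMSE and the overall F statistic.  External: R²pred (note the TRAINING mean
in the denominator), test RMSE, and Roy's rm² family built from ordinary and
through-origin regressions of observed against predicted test values.
Y-randomization refits the same descriptor subset on permuted responses; a
model is only considered reliable when both mean R² and mean R²cv over the
scrambled refits stay below 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import DescriptorTable
from .mlr import LinearModel, _design_matrix, _solve_ols, f_statistic, fit_mlr, predict

__all__ = [
    "ValidationReport",
    "r_squared",
    "loo_cv",
    "rmse",
    "r2_pred",
    "rm2_metrics",
    "y_randomization",
    "validate_model",
]


@dataclass(frozen=True)
class ValidationReport:
    """Every internal/external statistic for one model, plus verdicts."""

    descriptor_subset: tuple[str, ...]
    r2: float
    r2cv: float
    rmse_train: float
    f: float
    r2_pred: float
    rmse_test: float
    rm2: float
    rm2_prime: float
    rm2_bar: float
    delta_rm2: float
    y_rand_mean_r2: float
    y_rand_mean_r2cv: float
    y_rand_iterations: int
    verdicts: dict

    def to_json(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items()}
        return json.dumps(
            payload, indent=2,
            default=lambda o: o.item() if hasattr(o, "item") else str(o),
        )

    def to_row(self) -> dict:
        """One row in the layout of the published model-ranking table."""
        return {
            "R2": self.r2,
            "R2cv": self.r2cv,
            "RMSE(a)": self.rmse_train,
            "F": self.f,
            "R2pred": self.r2_pred,
            "RMSE(b)": self.rmse_test,
            "rm2_bar": self.rm2_bar,
            "delta_rm2": self.delta_rm2,
        }


def r_squared(y_obs, y_pred, y_ref_mean: float) -> float:
    """``1 − Σ(y−ŷ)² / Σ(y−ȳ_ref)²`` with an explicit reference mean."""
    y_obs = np.asarray(y_obs, float)
    y_pred = np.asarray(y_pred, float)
    if y_obs.shape != y_pred.shape or y_obs.size < 2:
        raise ValueError("need equal-length vectors of at least 2 values")
    denom = float(np.sum((y_obs - y_ref_mean) ** 2))
    if denom == 0:
        raise ZeroDivisionError("observations constant at the reference mean")
    return 1.0 - float(np.sum((y_obs - y_pred) ** 2)) / denom


def rmse(y_obs, y_pred) -> float:
    y_obs = np.asarray(y_obs, float)
    y_pred = np.asarray(y_pred, float)
    if y_obs.shape != y_pred.shape or y_obs.size < 1:
        raise ValueError("need equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))


def loo_cv(table: DescriptorTable, subset) -> tuple[float, np.ndarray]:
    """Leave-one-out cross-validation of the OLS fit on ``subset``.

    Uses the exact hat-matrix identity ``ŷ₋ᵢ = yᵢ − eᵢ/(1−hᵢᵢ)`` (identical
    to n refits), and scores R²cv against the full training mean.
    """
    subset = tuple(subset)
    if table.n_samples <= len(subset) + 2:
        raise ValueError("too few samples for leave-one-out with this subset")
    X = _design_matrix(table, subset)
    y = table.response
    beta, _ = _solve_ols(X, y)
    resid = y - X @ beta
    # hat diagonal via the thin-QR factor
    q, _ = np.linalg.qr(X)
    h = np.sum(q * q, axis=1)
    if np.any(h >= 1 - 1e-12):
        raise np.linalg.LinAlgError("a leave-one-out fold is rank deficient")
    loo_pred = y - resid / (1.0 - h)
    return r_squared(y, loo_pred, float(np.mean(y))), loo_pred


def r2_pred(y_obs_test, y_pred_test, y_train_mean: float) -> float:
    """External predictive R²; the denominator is centred on the TRAINING mean."""
    y_obs_test = np.asarray(y_obs_test, float)
    y_pred_test = np.asarray(y_pred_test, float)
    denom = float(np.sum((y_obs_test - y_train_mean) ** 2))
    if denom == 0:
        raise ZeroDivisionError("test observations constant at the training mean")
    return 1.0 - float(np.sum((y_obs_test - y_pred_test) ** 2)) / denom


def rm2_metrics(y_obs_test, y_pred_test) -> tuple[float, float, float, float]:
    """Roy's (rm², r′m², r̄m², Δrm²) external-validation metrics.

    ``r²`` is the squared Pearson correlation; ``r0²`` comes from regressing
    observed on predicted through the origin (``r′0²`` with the axes
    swapped); then ``rm² = r²·(1 − √(r² − r0²))``.  A numerically negative
    radicand is clamped at zero with a warning.
    """
    yo = np.asarray(y_obs_test, float)
    yp = np.asarray(y_pred_test, float)
    if yo.size < 3:
        raise ValueError("Roy metrics need at least 3 test samples")
    if np.std(yo) == 0 or np.std(yp) == 0:
        raise ValueError("degenerate variance in observed or predicted values")
    r2 = float(np.corrcoef(yo, yp)[0, 1] ** 2)

    def through_origin_r2(y, x) -> float:
        k = float(np.sum(y * x) / np.sum(x * x))
        return 1.0 - float(np.sum((y - k * x) ** 2) / np.sum((y - y.mean()) ** 2))

    def rm(r0sq: float) -> float:
        radicand = r2 - r0sq
        if radicand < 0:
            if radicand < -1e-10:
                warnings.warn(
                    f"negative radicand {radicand:.3g} in rm² clamped to 0",
                    stacklevel=3,
                )
            radicand = 0.0
        return r2 * (1.0 - np.sqrt(radicand))

    rm2 = rm(through_origin_r2(yo, yp))
    rm2_prime = rm(through_origin_r2(yp, yo))
    return rm2, rm2_prime, (rm2 + rm2_prime) / 2.0, abs(rm2 - rm2_prime)


def y_randomization(
    table: DescriptorTable,
    subset,
    iterations: int = 500,
    seed: int = 0,
    permutations=None,
) -> tuple[float, float, bool]:
    """Response-scrambling robustness test.

    The descriptor matrix stays fixed; the response is permuted uniformly at
    random ``iterations`` times and the same subset is refit each time.
    Returns (mean R², mean R²cv, reliable) where reliable means both means
    stayed below 0.5.  ``permutations`` (a sequence of index arrays) overrides
    the random stream — useful for sanity checks such as the identity
    permutation, which must reproduce the unscrambled fit exactly.
    """
    subset = tuple(subset)
    if permutations is not None:
        permutations = [np.asarray(p, dtype=int) for p in permutations]
        iterations = len(permutations)
    if iterations < 1:
        raise ValueError("iterations must be positive")
    rng = np.random.default_rng(seed)
    X = _design_matrix(table, subset)
    y = table.response
    n = table.n_samples
    # X is fixed across permutations: factor once
    q, r = np.linalg.qr(X)
    h = np.sum(q * q, axis=1)
    one_minus_h = 1.0 - h
    r2s = np.empty(iterations)
    r2cvs = np.empty(iterations)
    for it in range(iterations):
        perm = rng.permutation(n) if permutations is None else permutations[it]
        yp = y[perm]
        fitted = q @ (q.T @ yp)
        resid = yp - fitted
        mean = float(np.mean(yp))
        tss = float(np.sum((yp - mean) ** 2))
        r2s[it] = 1.0 - float(resid @ resid) / tss
        loo_pred = yp - resid / one_minus_h
        r2cvs[it] = 1.0 - float(np.sum((yp - loo_pred) ** 2)) / tss
    mean_r2 = float(np.mean(r2s))
    mean_r2cv = float(np.mean(r2cvs))
    return mean_r2, mean_r2cv, bool(mean_r2 < 0.5 and mean_r2cv < 0.5)


def validate_model(
    train: DescriptorTable,
    test: DescriptorTable,
    subset,
    y_rand_iterations: int = 500,
    seed: int = 0,
) -> ValidationReport:
    """Full internal + external validation battery for one descriptor subset."""
    subset = tuple(subset)
    model = fit_mlr(train, subset)
    y_train = train.response
    train_mean = float(np.mean(y_train))
    pred_train = predict(model, train)
    r2 = r_squared(y_train, pred_train, train_mean)
    r2cv, _ = loo_cv(train, subset)
    rmse_a = rmse(y_train, pred_train)
    f = f_statistic(r2, train.n_samples, len(subset))
    pred_test = predict(model, test)
    y_test = test.response
    r2p = r2_pred(y_test, pred_test, train_mean)
    rmse_b = rmse(y_test, pred_test)
    rm2, rm2p, rm2_bar, delta = rm2_metrics(y_test, pred_test)
    yr_r2, yr_r2cv, reliable = y_randomization(
        train, subset, iterations=y_rand_iterations, seed=seed
    )
    verdicts = {
        "y_randomization_reliable": reliable,
        "rm2_bar_above_0.5": rm2_bar > 0.5,
        "delta_rm2_below_0.2": delta < 0.2,
        "r2cv_not_above_r2": r2cv <= r2 + 1e-12,
        "rm2_axis_convention": "r0^2 regresses observed on predicted through origin",
    }
    return ValidationReport(
        descriptor_subset=subset,
        r2=r2,
        r2cv=r2cv,
        rmse_train=rmse_a,
        f=f,
        r2_pred=r2p,
        rmse_test=rmse_b,
        rm2=rm2,
        rm2_prime=rm2p,
        rm2_bar=rm2_bar,
        delta_rm2=delta,
        y_rand_mean_r2=yr_r2,
        y_rand_mean_r2cv=yr_r2cv,
        y_rand_iterations=y_rand_iterations,
        verdicts=verdicts,
    )
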