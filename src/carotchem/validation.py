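"""Model validation: grouped k-fold cross-validation and external validation.

Conventions (stated because different chemometrics packages differ):

* R2 = 1 - SSres/SStot on the validation (out-of-fold or external)
  predicted/true pairs, not a squared Pearson correlation.
* RMSE uses the n denominator; the reference-set standard deviation in
  RPD uses n-1.  Because of that mismatch RPD differs slightly from
  1/sqrt(1-R2) at small n.
* bias = mean(predicted - true): positive bias means overestimation.
* RPD = SD(reference)/RMSE; an exact-zero RMSE is reported as ``inf``
  rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from carotchem.pls import CalibrationModel, fit_pls1, make_folds

__all__ = ["ValidationReport", "rpd", "bias", "r_squared", "kfold_cv", "external_validation"]


def bias(pred: np.ndarray, true: np.ndarray) -> float:
    """Mean signed prediction error, mean(pred - true)."""
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if pred.size != true.size:
        raise ValueError("pred and true must have equal length")
    return float(np.mean(pred - true))


def rpd(y_true: np.ndarray, rmse: float) -> float:
    """Residual prediction deviation SD(y_true, ddof=1) / rmse.

    Returns ``math.inf`` when rmse is exactly 0 (perfect predictions).
    """
    if rmse < 0:
        raise ValueError("rmse must be non-negative")
    sd = float(np.std(np.asarray(y_true, dtype=float), ddof=1))
    if rmse == 0:
        return math.inf
    return sd / rmse


def r_squared(pred: np.ndarray, true: np.ndarray) -> float:
    """Coefficient of determination 1 - SSres/SStot on validation pairs."""
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    resid = pred - true
    ss_res = float(resid @ resid)
    centered = true - true.mean()
    ss_tot = float(centered @ centered)
    if ss_tot == 0:
        raise ValueError("R2 undefined: reference values are constant")
    return 1.0 - ss_res / ss_tot


@dataclass
class ValidationReport:
    """Validation metrics for one analyte's calibration model."""

    analyte: str
    scheme: str              # "cross" or "external"
    rank: int
    r2: float
    rmse: float              # RMSECV (cross) or RMSEP (external)
    rpd: float
    bias: float
    n: int                   # number of validation pairs (scans)
    predictions: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    true_values: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    folds: np.ndarray | None = field(repr=False, default=None)

    def to_dict(self, include_pairs: bool = False) -> dict[str, Any]:
        d: dict[str, Any] = {
            "analyte": self.analyte,
            "scheme": self.scheme,
            "rank": self.rank,
            "R2": self.r2,
            "RMSE": self.rmse,
            "RPD": self.rpd if math.isfinite(self.rpd) else "inf",
            "bias": self.bias,
            "n": self.n,
        }
        if include_pairs:
            d["predicted"] = np.asarray(self.predictions).tolist()
            d["true"] = np.asarray(self.true_values).tolist()
        return d


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: np.ndarray | None = None,
    k: int = 5,
    rank: int | None = None,
    max_rank: int = 10,
    seed: int = 0,
    analyte: str = "",
) -> ValidationReport:
    """Grouped, concentration-stratified k-fold cross-validation.

    All replicate scans of a sample share a fold.  When ``rank`` is None
    it is chosen per the full data by minimizing RMSECV (see
    :func:`carotchem.pls.select_rank`); the chosen rank is then used for
    every fold's refit.
    """
    from carotchem.pls import select_rank  # local import to keep module load light

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if sample_ids is None:
        sample_ids = np.arange(len(y))
    sample_ids = np.asarray(sample_ids)
    if rank is None:
        rank = select_rank(X, y, sample_ids, k=k, max_rank=max_rank, seed=seed)
    folds = make_folds(sample_ids, k=k, seed=seed, y=y)
    pred = np.empty_like(y)
    for f in range(k):
        tr, te = folds != f, folds == f
        model = fit_pls1(X[tr], y[tr], rank=rank)
        pred[te] = model.predict(X[te])
    resid = pred - y
    rmsecv = float(np.sqrt(np.mean(resid**2)))
    return ValidationReport(
        analyte=analyte,
        scheme="cross",
        rank=rank,
        r2=r_squared(pred, y),
        rmse=rmsecv,
        rpd=rpd(y, rmsecv),
        bias=bias(pred, y),
        n=len(y),
        predictions=pred,
        true_values=y.copy(),
        folds=folds,
    )


def external_validation(
    model: CalibrationModel,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cal_sample_ids: np.ndarray | None = None,
    val_sample_ids: np.ndarray | None = None,
) -> ValidationReport:
    """Evaluate a fitted model on an external validation set.

    The model must have been fitted on the calibration set only; if both
    id vectors are supplied the sets must be disjoint.
    """
    if cal_sample_ids is not None and val_sample_ids is not None:
        overlap = np.intersect1d(np.asarray(cal_sample_ids), np.asarray(val_sample_ids))
        if overlap.size:
            raise ValueError(
                f"calibration and validation sets share sample ids: {overlap[:5].tolist()}"
            )
    y_val = np.asarray(y_val, dtype=float).ravel()
    pred = model.predict(X_val)
    resid = pred - y_val
    rmsep = float(np.sqrt(np.mean(resid**2)))
    return ValidationReport(
        analyte=model.analyte,
        scheme="external",
        rank=model.rank,
        r2=r_squared(pred, y_val),
        rmse=rmsep,
        rpd=rpd(y_val, rmsep),
        bias=bias(pred, y_val),
        n=len(y_val),
        predictions=pred,
        true_values=y_val.copy(),
    )
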