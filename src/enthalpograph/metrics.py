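"""Regression evaluation metrics for combustion-enthalpy predictions.

Targets are magnitudes of the standard combustion enthalpy, −Δ_cH° in
kJ·mol⁻¹, and therefore positive — a convention that keeps the RMSLE
logarithm defined.  MAPE is reported as a fraction (0.075, not 7.5);
a percent view is available via :meth:`MetricReport.as_dict`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import MetricDomainError

METRIC_NAMES = ("mae", "rmse", "mape", "rmsle", "r2")


@dataclass(frozen=True)
class MetricReport:
    """MAE/RMSE in kJ·mol⁻¹; MAPE (fraction), RMSLE and R² dimensionless."""

    mae: float
    rmse: float
    mape: float
    rmsle: float
    r2: float
    n: int

    def as_dict(self, mape_percent: bool = False) -> dict:
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        if mape_percent:
            d["mape"] = d["mape"] * 100.0
        d["n"] = self.n
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.as_dict(**kw), indent=2)


def evaluate(y: np.ndarray, y_pred: np.ndarray) -> MetricReport:
    """Compute MAE, RMSE, MAPE, RMSLE and R² for a prediction set.

    Raises :class:`MetricDomainError` for a zero actual value (MAPE
    undefined, index reported) or a negative actual value (RMSLE undefined;
    targets are positive magnitudes by convention).  Negative *predictions*
    — which unconstrained regressors can emit — are clamped to 0 inside the
    RMSLE log term only, so reports stay defined; MAE/RMSE/MAPE/R² always
    use the raw predictions.
    """
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.ndim != 1:
        raise ValueError("y and y_pred must be 1-D arrays of equal length")
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    zero = np.flatnonzero(y == 0)
    if zero.size:
        raise MetricDomainError(f"MAPE undefined: y[{zero[0]}] is zero")
    if (y < 0).any():
        raise MetricDomainError("RMSLE undefined for negative actual values")
    resid = y - y_pred
    mae = float(np.mean(np.abs(resid)))
    rmse = float(math.sqrt(np.mean(resid**2)))
    mape = float(np.mean(np.abs(resid) / np.abs(y)))
    rmsle = float(
        math.sqrt(np.mean((np.log1p(np.maximum(y_pred, 0.0)) - np.log1p(y)) ** 2))
    )
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return MetricReport(mae=mae, rmse=rmse, mape=mape, rmsle=rmsle, r2=r2, n=n)
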