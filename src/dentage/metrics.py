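"""Regression evaluation suite: SD of residuals, MAE, MSE, RMSE and R².

All denominators are population-style (``n``, not ``n - 1``): the standard
deviation is defined over the full residual population, and MSE/RMSE divide
by the number of cases. ``sd_of_errors`` summarises the *signed* residuals
``predicted - actual``, the convention used when reporting a method's bias
spread alongside its MAE.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["RegressionReport", "evaluate_regression"]

#: Tolerance for the internal RMSE² == MSE identity check.
_CONSISTENCY_TOL = 1e-12


@dataclass(frozen=True)
class RegressionReport:
    """Summary of predicted vs. actual ages for one evaluation set.

    Attributes
    ----------
    n : int
        Number of (actual, predicted) pairs.
    sd_of_errors : float
        Population standard deviation of the signed residuals
        ``predicted - actual``.
    mae : float
        Mean absolute error, in the units of the target (years).
    mse : float
        Mean squared error.
    rmse : float
        Root mean squared error, ``sqrt(mse)``.
    r2 : float
        Coefficient of determination, ``1 - SS_res / SS_tot`` with the
        total sum of squares taken about the mean of the actual values.
    """

    n: int
    sd_of_errors: float
    mae: float
    mse: float
    rmse: float
    r2: float

    @property
    def rmse_mse_consistent(self) -> bool:
        """Whether the report satisfies the identity ``rmse² == mse``.

        Always true for reports produced by :func:`evaluate_regression`;
        exposed so that externally reported (MSE, RMSE) pairs can be
        machine-checked for internal consistency before comparison.
        """
        return abs(self.rmse**2 - self.mse) <= _CONSISTENCY_TOL * max(1.0, self.mse)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rmse_mse_consistent"] = self.rmse_mse_consistent
        return d

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def to_csv_row(self) -> str:
        """One-line CSV rendering (header + row)."""
        header = "n,sd_of_errors,mae,mse,rmse,r2"
        row = f"{self.n},{self.sd_of_errors!r},{self.mae!r},{self.mse!r},{self.rmse!r},{self.r2!r}"
        return header + "\n" + row + "\n"


def evaluate_regression(actual, predicted) -> RegressionReport:
    """Evaluate age predictions against chronological ages.

    Parameters
    ----------
    actual, predicted : array-like of float, same length >= 2
        Chronological ages and model predictions, in years.

    Returns
    -------
    RegressionReport

    Raises
    ------
    ValueError
        If lengths differ, fewer than two pairs are given, values are
        non-finite, or the actual ages have zero variance (R² undefined).
    """
    y = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: actual has {y.size}, predicted has {p.size}")
    if y.size < 2:
        raise ValueError("need at least two (actual, predicted) pairs")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(p))):
        raise ValueError("actual and predicted values must all be finite")

    resid = p - y
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("actual values have zero variance; R² is undefined")
    mse = float(np.mean(resid**2))
    return RegressionReport(
        n=int(y.size),
        sd_of_errors=float(np.std(resid)),  # population SD
        mae=float(np.mean(np.abs(resid))),
        mse=mse,
        rmse=float(np.sqrt(mse)),
        r2=float(1.0 - np.sum(resid**2) / ss_tot),
    )
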