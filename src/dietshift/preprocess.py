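"""Energy adjustment (residual method) and weighted standardization.

The residual method removes the between-person variation that is explained
by total energy intake: each analysis variable x is regressed on energy e
by weighted least squares, and the adjusted value is the residual
re-centered at the value predicted at the weighted mean energy::

    x_adj_i = x_i - b * (e_i - mean_w(e))

which keeps the variable on its original units and preserves its weighted
mean, while making its weighted covariance with energy exactly zero.
Standardization divides by the weighted population SD (denominator sum(w));
centering is left to the factor analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._weights import as_weights, wmean, wsd
from .core_io import ValidationError

__all__ = ["AdjustedMatrix", "energy_adjust_residual", "scale_to_sd"]


@dataclass
class AdjustedMatrix:
    """Energy-adjusted variables plus the fitted regression metadata."""

    values: pd.DataFrame
    slope: pd.Series
    intercept: pd.Series
    reference_energy: float   # weighted mean energy the residuals are re-centered at

    def predicted_at_reference(self) -> pd.Series:
        return self.intercept + self.slope * self.reference_energy


def energy_adjust_residual(X: pd.DataFrame, energy: pd.Series,
                           weights=None) -> AdjustedMatrix:
    """Adjust every column of ``X`` for total energy by the residual method.

    Parameters
    ----------
    X : person x variable matrix (foods, nutrients, impacts ... any units).
    energy : total energy intake per person (kJ/day), aligned with ``X``.
    weights : survey weights; the regression and all moments are weighted.
    """
    energy = energy.reindex(X.index)
    if energy.isna().any():
        raise ValidationError("energy missing for some rows of X")
    e = energy.to_numpy(dtype=float)
    if (e <= 0).any():
        raise ValidationError("energy must be > 0 for every person")
    w = as_weights(weights, len(X))
    e_bar = wmean(e, w)
    var_e = float(np.sum(w * (e - e_bar) ** 2) / np.sum(w))
    if var_e == 0.0:
        raise ValidationError("energy has zero weighted variance; regression undefined")

    vals = X.to_numpy(dtype=float)
    x_bar = np.sum(w[:, None] * vals, axis=0) / np.sum(w)
    cov = np.sum(w[:, None] * (vals - x_bar) * (e - e_bar)[:, None], axis=0) / np.sum(w)
    slope = cov / var_e
    intercept = x_bar - slope * e_bar
    adjusted = vals - slope[None, :] * (e - e_bar)[:, None]
    return AdjustedMatrix(
        values=pd.DataFrame(adjusted, index=X.index, columns=X.columns),
        slope=pd.Series(slope, index=X.columns),
        intercept=pd.Series(intercept, index=X.columns),
        reference_energy=e_bar,
    )


def scale_to_sd(X: pd.DataFrame | AdjustedMatrix, weights=None
                ) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each column by its weighted population SD (no centering).

    Returns the scaled matrix and the SD factors.  Raises on zero-SD
    columns, naming them.
    """
    if isinstance(X, AdjustedMatrix):
        X = X.values
    w = as_weights(weights, len(X))
    sd = pd.Series(wsd(X.to_numpy(dtype=float), w), index=X.columns)
    zero = sd.index[sd == 0.0].tolist()
    if zero:
        raise ValidationError(f"zero weighted SD, cannot scale: {zero}")
    return X / sd, sd
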