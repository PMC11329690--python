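"""Per-person daily environmental impacts and food-group decompositions.

The footprint of a person's diet is the intake-weighted sum of per-gram
characterization factors::

    impact_c(person) = sum_food intake(person, food) * factor(food, c)

Impacts are computed on raw (not energy-adjusted) intakes; energy
adjustment enters only the downstream analysis variables.  GWP and land
use are reported on the factor scale (kg CO2-eq/day, m2/day); the two
eutrophication categories are converted from kg to g per day for
readability of typical dietary magnitudes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._weights import as_weights
from .core_io import IMPACT_COLS, ValidationError

__all__ = ["person_impacts", "group_contributions", "IMPACT_REPORT_UNITS"]

#: Reporting units of the per-person daily impact table.
IMPACT_REPORT_UNITS = {
    "gwp": "kg CO2-eq/day",
    "land_use": "m2 annual-crop-eq/day",
    "marine_eutroph": "g N-eq/day",
    "freshwater_eutroph": "g P-eq/day",
}

_KG_TO_G = ("marine_eutroph", "freshwater_eutroph")


def _resolve_factors(intakes: pd.DataFrame, factors: pd.DataFrame,
                     on_missing: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    missing = intakes.columns.difference(factors.index)
    if len(missing) > 0:
        if on_missing == "error":
            raise ValidationError(
                f"no impact factor for consumed foods: {sorted(missing)}; "
                "pass on_missing='drop' to exclude them")
        warnings.warn(f"dropping foods without impact factors: {sorted(missing)}",
                      RuntimeWarning, stacklevel=3)
        intakes = intakes.drop(columns=list(missing))
    fac = factors.loc[intakes.columns, list(IMPACT_COLS)].astype(float)
    return intakes, fac


def person_impacts(intakes: pd.DataFrame, factors: pd.DataFrame,
                   on_missing: str = "error") -> pd.DataFrame:
    """Daily impact per person for the four categories.

    ``on_missing`` controls foods without a factor row: ``'error'`` (default)
    or ``'drop'`` (excluded with a warning).
    """
    intakes, fac = _resolve_factors(intakes, factors, on_missing)
    vals = intakes.to_numpy(dtype=float) @ fac.to_numpy()
    out = pd.DataFrame(vals, index=intakes.index, columns=list(IMPACT_COLS))
    for c in _KG_TO_G:
        out[c] = out[c] * 1000.0
    return out


def group_contributions(intakes: pd.DataFrame, factors: pd.DataFrame,
                        groups: pd.Series, labels: pd.Series | None = None,
                        weights=None, on_missing: str = "error") -> pd.DataFrame:
    """Weighted mean daily impact contribution of each food group, by cluster.

    Parameters
    ----------
    groups : food_id -> group label (any aggregation level, e.g. the
        registry groups or a coarse Meat/Dairy/... map).
    labels : person_id -> cluster label; an ``ALL`` row over every person
        is always included.
    weights : survey weights (aligned with intakes rows).

    Returns a long table (cluster, food_group, impact, contribution)
    whose contributions sum, per (cluster, impact), to the cluster's
    weighted mean total impact.
    """
    intakes, fac = _resolve_factors(intakes, factors, on_missing)
    groups = groups.reindex(intakes.columns)
    if groups.isna().any():
        raise ValidationError(
            f"foods without a group label: {sorted(intakes.columns[groups.isna()])}")
    w = as_weights(weights, len(intakes))

    if labels is not None:
        labels = labels.reindex(intakes.index)
        if labels.isna().any():
            raise ValidationError(
                f"persons without a cluster label: {sorted(intakes.index[labels.isna()])}")

    # per-person per-group impact sums, one matrix per impact category
    rows = []
    group_names = sorted(groups.unique())
    member = {g: (groups == g).to_numpy() for g in group_names}
    X = intakes.to_numpy(dtype=float)
    for ci, impact in enumerate(IMPACT_COLS):
        f = fac.to_numpy()[:, ci] * (1000.0 if impact in _KG_TO_G else 1.0)
        contrib = {g: X[:, member[g]] @ f[member[g]] for g in group_names}
        blocks: list[tuple[str, np.ndarray]] = [("ALL", np.ones(len(intakes), bool))]
        if labels is not None:
            blocks += [(str(k), (labels == k).to_numpy())
                       for k in sorted(labels.unique(), key=str)]
        for cl, mask in blocks:
            wm = w[mask]
            for g in group_names:
                rows.append({
                    "cluster": cl, "food_group": g, "impact": impact,
                    "contribution": float(np.sum(wm * contrib[g][mask]) / np.sum(wm)),
                })
    return pd.DataFrame(rows)
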