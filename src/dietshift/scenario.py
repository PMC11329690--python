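"""Dietary-transition scenario accounting.

If the whole adult population adopted a target cluster's diet, each
environmental impact would change by the relative difference between the
cluster's mean daily impact and the sample mean.  The absolute national
effect is the per-capita daily delta scaled to the adult population and a
365-day year, optionally expressed as a share of a national baseline
(e.g. total territorial GHG emissions).  Per-capita annual food-intake
changes translate the g/day differences in food-group means to
kg/capita/year.

Percentage changes are computed from energy-adjusted cluster means when an
energy-adjusted impact table is supplied, so they reflect differences in
dietary composition rather than in caloric intake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._weights import as_weights
from .core_io import ValidationError

__all__ = ["percent_change", "national_extrapolation", "per_capita_food_change",
           "ScenarioReport", "scenario_report"]

_UNIT_SCALE = {None: 1.0, "same": 1.0, "t_from_kg": 1e-3, "Mt_from_kg": 1e-9,
               "t_from_g": 1e-6, "kt_from_kg": 1e-6}


def percent_change(cluster_mean: float, sample_mean: float) -> float:
    """100 * (cluster - sample) / sample; requires a positive sample mean."""
    if sample_mean <= 0:
        raise ValidationError("sample mean must be > 0 for a percentage change")
    return 100.0 * (cluster_mean - sample_mean) / sample_mean


def national_extrapolation(daily_delta_per_capita: float, population: float,
                           national_baseline: float | None = None,
                           unit: str | None = None) -> tuple[float, float | None]:
    """(annual national delta, share of baseline in %).

    ``daily_delta_per_capita`` is in the impact's per-day unit;
    ``unit`` converts the annual total (e.g. ``"Mt_from_kg"`` when the
    daily unit is kg and the baseline is in Mt).  The share is omitted
    (None) without a positive baseline.
    """
    if population <= 0:
        raise ValidationError("population must be > 0")
    scale = _UNIT_SCALE.get(unit)
    if scale is None:
        raise ValueError(f"unknown unit conversion {unit!r}")
    annual = daily_delta_per_capita * population * 365.0 * scale
    share = None
    if national_baseline is not None and national_baseline > 0:
        share = 100.0 * annual / national_baseline
    return annual, share


def per_capita_food_change(cluster_means_g_day: pd.Series,
                           sample_means_g_day: pd.Series) -> pd.Series:
    """kg/capita/year change per food group: (cluster - sample) g/day x 365 / 1000."""
    cluster = pd.Series(cluster_means_g_day, dtype=float)
    sample = pd.Series(sample_means_g_day, dtype=float).reindex(cluster.index)
    if sample.isna().any():
        raise ValidationError("food-group vocabularies do not match")
    return ((cluster - sample) * 365.0 / 1000.0).rename("kg_per_capita_year")


@dataclass
class ScenarioReport:
    target_cluster: object
    impacts: pd.DataFrame          # per impact: sample/cluster mean, pct change, annual delta, share
    food_changes: pd.Series        # kg/capita/year per food group
    population: float


def scenario_report(impact_table: pd.DataFrame, labels: pd.Series,
                    target_cluster, weights=None, population: float = 4.3e6,
                    national_baselines: dict[str, float] | None = None,
                    units: dict[str, str] | None = None,
                    group_intakes: pd.DataFrame | None = None) -> ScenarioReport:
    """Full scenario for adopting ``target_cluster``'s diet.

    ``impact_table`` is person x impact (per day, typically
    energy-adjusted); ``group_intakes`` person x food-group g/day for the
    per-capita intake changes.  ``national_baselines``/``units`` map impact
    name to the annual national total and the unit conversion of the
    annual delta.
    """
    labels = labels.reindex(impact_table.index)
    if labels.isna().any():
        raise ValidationError("persons without cluster labels in scenario")
    mask = (labels == target_cluster).to_numpy()
    if not mask.any():
        raise ValidationError(f"no persons in target cluster {target_cluster!r}")
    w = as_weights(weights, len(impact_table))

    rows = []
    for impact in impact_table.columns:
        x = impact_table[impact].to_numpy(dtype=float)
        sample_mean = float(np.sum(w * x) / np.sum(w))
        cluster_mean = float(np.sum(w[mask] * x[mask]) / np.sum(w[mask]))
        pct = percent_change(cluster_mean, sample_mean)
        baseline = (national_baselines or {}).get(impact)
        unit = (units or {}).get(impact)
        annual, share = national_extrapolation(cluster_mean - sample_mean,
                                               population, baseline, unit)
        rows.append({"impact": impact, "sample_mean": sample_mean,
                     "cluster_mean": cluster_mean, "pct_change": pct,
                     "annual_delta": annual, "share_of_baseline_pct": share})
    impacts = pd.DataFrame(rows).set_index("impact")

    food_changes = pd.Series(dtype=float)
    if group_intakes is not None:
        g = group_intakes.reindex(impact_table.index).to_numpy(dtype=float)
        sample = np.sum(w[:, None] * g, axis=0) / np.sum(w)
        clus = np.sum(w[mask, None] * g[mask], axis=0) / np.sum(w[mask])
        food_changes = per_capita_food_change(
            pd.Series(clus, index=group_intakes.columns),
            pd.Series(sample, index=group_intakes.columns))
    return ScenarioReport(target_cluster=target_cluster, impacts=impacts,
                          food_changes=food_changes, population=population)
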