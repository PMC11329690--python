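"""Modified Baltic Sea Diet Score (mBSDS).

An a-priori index of adherence to a healthy Nordic diet with eight
components: fruits & berries, vegetables, whole-grain cereals, low-fat
milk, fish, red & processed meat (reverse-scored), the fatty-acid ratio
PUFA/(SFA + trans), and alcohol.  The seven intake/ratio components score
0-3 points by sex-specific quartile of the population distribution
(reverse components 3-0); alcohol scores 1 point when intake does not
exceed the sex-specific threshold.  Total range 0-22; higher is better in
relative terms, with no target threshold.

Quartiles are computed on the survey-weighted distribution by default;
externally supplied cut points take precedence when provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._weights import as_weights, wquantile
from .core_io import ValidationError

__all__ = ["Component", "BsdsConfig", "compute_mbsds", "component_intakes"]


@dataclass(frozen=True)
class Component:
    """One quartile-scored component.

    ``source`` is 'food_group' (sum of intakes over the listed groups) or
    'nutrient_ratio' (first listed nutrient divided by the sum of the
    rest).  ``positive`` components score 0..3 upward, reverse components
    3..0.
    """

    name: str
    source: str
    items: tuple[str, ...]
    positive: bool = True


DEFAULT_COMPONENTS: tuple[Component, ...] = (
    Component("fruits_berries", "food_group", ("Fruits and berries",)),
    Component("vegetables", "food_group", ("Vegetables",)),
    Component("whole_grain", "food_group", ("Whole-grain cereals",)),
    Component("low_fat_milk", "food_group", ("Low-fat milk",)),
    Component("fish", "food_group", ("Fish",)),
    Component("red_processed_meat", "food_group",
              ("Beef", "Pork", "Processed meat"), positive=False),
    Component("fat_ratio", "nutrient_ratio", ("pufa_g", "sfa_g", "trans_fat_g")),
)


@dataclass
class BsdsConfig:
    """Scoring configuration: 7 quartile components x 0-3 + alcohol 0-1 = 0-22.

    ``alcohol_threshold_g`` gives the sex-specific daily ethanol limits under
    which the alcohol point is awarded.  ``external_cutpoints`` maps
    ``(component, sex)`` to (Q1, Q2, Q3); when absent, quartiles are taken
    from the (weighted) sample distribution by sex.
    """

    components: tuple[Component, ...] = DEFAULT_COMPONENTS
    alcohol_threshold_g: dict[str, float] = field(
        default_factory=lambda: {"female": 10.0, "male": 20.0})
    alcohol_nutrient: str = "alcohol_g"
    external_cutpoints: dict[tuple[str, str], tuple[float, float, float]] | None = None
    weighted_quartiles: bool = True

    def __post_init__(self) -> None:
        max_points = 3 * len(self.components) + 1
        if max_points != 22:
            raise ValidationError(
                f"component point ranges sum to {max_points}, expected 22")
        if any(v <= 0 for v in self.alcohol_threshold_g.values()):
            raise ValidationError("alcohol thresholds must be > 0")


def component_intakes(intakes: pd.DataFrame, nutrients: pd.DataFrame,
                      food_groups: pd.Series, config: BsdsConfig) -> pd.DataFrame:
    """Per-person raw values of every scored component (pre-binning)."""
    out = pd.DataFrame(index=intakes.index)
    for comp in config.components:
        if comp.source == "food_group":
            cols = [f for f in intakes.columns if food_groups.get(f) in comp.items]
            if not cols:
                raise ValidationError(f"component {comp.name}: no foods in groups {comp.items}")
            out[comp.name] = intakes[cols].sum(axis=1)
        elif comp.source == "nutrient_ratio":
            num = nutrients[comp.items[0]]
            den = nutrients[list(comp.items[1:])].sum(axis=1)
            if (den <= 0).any():
                raise ValidationError(f"component {comp.name}: non-positive denominator")
            out[comp.name] = num / den
        else:
            raise ValidationError(f"unknown component source {comp.source!r}")
    return out


def _quartile_points(x: np.ndarray, cuts: tuple[float, float, float],
                     positive: bool) -> np.ndarray:
    q1, q2, q3 = cuts
    # right-closed bins, ties fall to the lower bin
    pts = np.zeros(len(x), dtype=int)
    pts[x > q1] = 1
    pts[x > q2] = 2
    pts[x > q3] = 3
    return pts if positive else 3 - pts


def compute_mbsds(intakes: pd.DataFrame, nutrients: pd.DataFrame,
                  persons: pd.DataFrame, food_groups: pd.Series,
                  config: BsdsConfig | None = None) -> pd.DataFrame:
    """Per-person mBSDS total and per-component breakdown.

    Returns a DataFrame indexed by person with one integer column per
    component (0-3), an ``alcohol`` column (0/1) and ``mbsds`` (0-22).

    Raises :class:`ValidationError` when a component variable is constant
    within a sex stratum (its quartiles are undefined); supply
    ``config.external_cutpoints`` in that case.
    """
    config = config or BsdsConfig()
    persons = persons.reindex(intakes.index)
    if persons["sex"].isna().any():
        raise ValidationError("every scored person needs a sex attribute")
    raw = component_intakes(intakes, nutrients.reindex(intakes.index), food_groups, config)

    weights = persons["survey_weight"].to_numpy(dtype=float) \
        if config.weighted_quartiles else None
    scores = pd.DataFrame(index=intakes.index)
    sexes = persons["sex"]
    for comp in config.components:
        pts = np.zeros(len(raw), dtype=int)
        for sex in ("male", "female"):
            mask = (sexes == sex).to_numpy()
            if not mask.any():
                continue
            x = raw[comp.name].to_numpy()[mask]
            key = (comp.name, sex)
            if config.external_cutpoints and key in config.external_cutpoints:
                cuts = config.external_cutpoints[key]
            else:
                w = as_weights(weights[mask] if weights is not None else None, mask.sum())
                cuts = tuple(wquantile(x, [0.25, 0.5, 0.75], w))
                if cuts[0] == cuts[2]:
                    raise ValidationError(
                        f"component {comp.name!r} is constant for sex {sex!r}: quartiles "
                        "undefined; supply external cut points")
            pts[mask] = _quartile_points(x, cuts, comp.positive)
        scores[comp.name] = pts

    alc = nutrients.reindex(intakes.index)[config.alcohol_nutrient]
    limit = sexes.map(config.alcohol_threshold_g).astype(float)
    scores["alcohol"] = (alc <= limit).astype(int)
    scores["mbsds"] = scores.sum(axis=1)
    return scores
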