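"""Country adaptation of life-cycle impact factors.

A base factor table (characterized per-gram impacts, typically from a French
LCI database) is adapted to the consuming country's conditions with two
rules:

* electricity-mix substitution — a food's life-cycle impact contains an
  electricity share; that share is swapped from the source country's mix to
  the European mix for imported foods (import/export ratio > 1) or to the
  domestic mix for domestically produced foods (ratio <= 1);
* feed-origin substitution — livestock foods get a multiplicative
  correction reflecting domestically grown feed.

The adaptation operates on characterized impacts, not on unit processes:
``adapted = base - share * intensity_source + share * intensity_target``
per impact category, then ``x feed_factor`` for livestock foods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import IMPACT_COLS, ValidationError

__all__ = [
    "AdaptationRules",
    "import_export_ratio",
    "classify_origin",
    "apply_adaptation",
]


@dataclass
class AdaptationRules:
    """Electricity and feed substitution parameters.

    ``intensity_*`` map impact -> impact units per unit of the electricity
    share (same per-gram scale as the factor table).  ``electricity_share``
    maps food_id -> fraction of the food's life-cycle impact attributable
    to electricity, in [0, 1].  ``feed_factor`` maps impact -> multiplier
    applied to livestock foods.
    """

    intensity_source: dict[str, float]
    intensity_europe: dict[str, float]
    intensity_domestic: dict[str, float]
    electricity_share: pd.Series
    livestock_foods: frozenset = frozenset()
    feed_factor: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        share = pd.Series(self.electricity_share, dtype=float)
        if ((share < 0) | (share > 1)).any():
            raise ValidationError("electricity shares must lie in [0, 1]")
        self.electricity_share = share
        for d in (self.intensity_source, self.intensity_europe, self.intensity_domestic):
            if any(v < 0 for v in d.values()):
                raise ValidationError("electricity intensities must be >= 0")

    @classmethod
    def identity(cls) -> "AdaptationRules":
        """Rules that leave every factor unchanged (zero shares, unit feed)."""
        zero = {c: 0.0 for c in IMPACT_COLS}
        return cls(intensity_source=zero, intensity_europe=dict(zero),
                   intensity_domestic=dict(zero),
                   electricity_share=pd.Series(dtype=float))


def import_export_ratio(import_mass: float, export_mass: float) -> float:
    """import/export ratio; 0/0 is defined as 0 (treated as domestic),
    x/0 with x > 0 as +inf (imported)."""
    if import_mass < 0 or export_mass < 0:
        raise ValidationError("trade masses must be >= 0")
    if export_mass == 0.0:
        return float("inf") if import_mass > 0 else 0.0
    return import_mass / export_mass


def classify_origin(ratio: float) -> str:
    """'imported' iff ratio > 1; the boundary ratio == 1 counts as domestic
    (imported status requires the ratio to exceed 1)."""
    if ratio < 0:
        raise ValidationError("ratio must be >= 0")
    return "imported" if ratio > 1.0 else "domestic"


def apply_adaptation(base: pd.DataFrame, trade: pd.DataFrame,
                     rules: AdaptationRules,
                     default_origin: str | None = None) -> pd.DataFrame:
    """Apply electricity-mix and feed-origin substitution to ``base``.

    Parameters
    ----------
    base : impact-factor table (per gram), indexed by food_id.
    trade : table with import_t / export_t columns, indexed by food_id.
    rules : substitution parameters.
    default_origin : origin assumed for foods without a trade record;
        ``None`` makes such foods an error.

    Returns a copy with the four impact columns adjusted, ``origin_flag``
    set from the trade ratios and ``adapted`` set to 1.  Factors that would
    go negative are clipped at 0 with a warning.
    """
    missing = base.index.difference(trade.index)
    if len(missing) > 0 and default_origin is None:
        raise ValidationError(
            f"no trade record and no default origin for foods: {sorted(missing)}")
    if default_origin is not None and default_origin not in {"domestic", "imported"}:
        raise ValueError("default_origin must be 'domestic' or 'imported'")

    out = base.copy()
    origins = {}
    for food in base.index:
        if food in trade.index:
            r = import_export_ratio(trade.at[food, "import_t"], trade.at[food, "export_t"])
            origins[food] = classify_origin(r)
        else:
            origins[food] = default_origin
    origin = pd.Series(origins)

    share = rules.electricity_share.reindex(base.index).fillna(0.0)
    clipped = []
    for impact in IMPACT_COLS:
        target = origin.map({
            "imported": rules.intensity_europe.get(impact, 0.0),
            "domestic": rules.intensity_domestic.get(impact, 0.0),
        }).astype(float)
        src = rules.intensity_source.get(impact, 0.0)
        adapted = base[impact] - share * src + share * target
        if rules.feed_factor:
            livestock = base.index.isin(rules.livestock_foods)
            adapted = adapted.where(~livestock, adapted * rules.feed_factor.get(impact, 1.0))
        neg = adapted < 0
        if neg.any():
            clipped.extend(adapted.index[neg].tolist())
            adapted = adapted.clip(lower=0.0)
        out[impact] = adapted
    if clipped:
        warnings.warn(f"adapted factors clipped at 0 for: {sorted(set(clipped))}",
                      RuntimeWarning, stacklevel=2)
    out["origin_flag"] = origin
    out["adapted"] = 1
    return out
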