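"""Synthetic survey population with planted diet-cluster structure.

The real survey data behind this kind of analysis (FFQ-derived intakes of a
few thousand adults, linked to nutrient intakes, LCA impact factors and
sociodemographics) is access-restricted, so this module generates populations
with the same dimensionality and statistical shape:

* ~25 ingredient-level food groups over 81 foods, 46 nutrient variables,
  4 ReCiPe midpoint impact categories;
* log-normal, right-skewed intakes (FFQ intakes are non-negative and
  right-skewed, which is also why the downstream characterization uses
  non-parametric tests);
* latent cluster structure with unequal shares (default 16/38/18/24/4 %),
  expressed as cluster-specific log-scale shifts of food-group intakes
  (plant-forward, average, high-fish "compromise", meat-leaning, heavy
  animal-source patterns);
* total energy correlated with total intake through a per-person scale
  factor;
* survey weights from a non-response propensity model in age and sex,
  normalized to mean 1 so weighted and unweighted n coincide.

Every draw is governed by ``spec.seed``; two runs with the same spec are
identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (FOOD_GROUPS, IMPACT_COLS, FOODS_SCHEMA, INTAKE_SCHEMA,
                      NUTRIENT_SCHEMA, PERSON_SCHEMA, IMPACT_FACTOR_SCHEMA,
                      TRADE_SCHEMA, validate_table)

__all__ = [
    "SpecError",
    "PopulationSpec",
    "default_spec",
    "food_registry",
    "generate_population",
    "generate_impact_factors",
    "generate_trade_records",
    "NUTRIENTS",
]


class SpecError(ValueError):
    """Inconsistent population specification."""


# ---------------------------------------------------------------------------
# Food registry: 81 ingredient-level foods over the 25 groups.

GROUP_FOOD_COUNTS: dict[str, int] = {
    "Fruits and berries": 6, "Vegetables": 8, "Potatoes": 2, "Legumes": 3,
    "Nuts and seeds": 2, "Whole-grain cereals": 4, "Refined grains": 4,
    "Beef": 3, "Pork": 3, "Poultry": 2, "Processed meat": 4, "Fish": 5,
    "Eggs": 1, "Low-fat milk": 2, "Liquid dairy": 4, "Solid dairy": 4,
    "Vegetable-based fat": 3, "Animal fat": 2, "Sweets and chocolate": 4,
    "Sugared beverages": 3, "Juices": 2, "Alcoholic beverages": 4,
    "Coffee and tea": 2, "Condiments": 2, "Other": 2,
}
assert sum(GROUP_FOOD_COUNTS.values()) == 81

ANIMAL_GROUPS = {"Beef", "Pork", "Poultry", "Processed meat", "Fish", "Eggs",
                 "Low-fat milk", "Liquid dairy", "Solid dairy", "Animal fat"}
LIVESTOCK_GROUPS = {"Beef", "Pork", "Poultry", "Processed meat", "Eggs",
                    "Low-fat milk", "Liquid dairy", "Solid dairy", "Animal fat"}

#: 46 nutrient intake variables (energy first; g/day unless suffixed).
NUTRIENTS: tuple[str, ...] = (
    "energy_kj", "protein_g", "plant_protein_g", "animal_protein_g",
    "carbohydrate_g", "sucrose_g", "starch_g", "fiber_g", "fat_g", "sfa_g",
    "mufa_g", "pufa_g", "trans_fat_g", "n3_fa_g", "n6_fa_g",
    "cholesterol_mg", "alcohol_g", "vitamin_a_ug", "vitamin_d_ug",
    "vitamin_e_mg", "vitamin_k_ug", "thiamin_mg", "riboflavin_mg",
    "niacin_mg", "vitamin_b6_mg", "folate_ug", "vitamin_b12_ug",
    "vitamin_c_mg", "calcium_mg", "phosphorus_mg", "magnesium_mg",
    "iron_mg", "zinc_mg", "iodine_ug", "selenium_ug", "potassium_mg",
    "sodium_mg", "salt_g", "water_g", "lactose_g", "fructose_g",
    "maltose_g", "beta_carotene_ug", "retinol_ug", "niacin_eq_mg",
    "caffeine_mg",
)
assert len(NUTRIENTS) == 46


def food_registry() -> pd.DataFrame:
    """The synthetic food registry: 81 foods with group labels, indexed by food_id."""
    rows = []
    for group, count in GROUP_FOOD_COUNTS.items():
        stem = group.lower().replace(" ", "_").replace("-", "_")
        for j in range(1, count + 1):
            rows.append({"food_id": f"{stem}_{j:02d}",
                         "name": f"{group} item {j}",
                         "food_group": group})
    df = pd.DataFrame(rows)
    return validate_table(df, FOODS_SCHEMA)


# Baseline mean intake per group, g/person/day (sample mixture).
BASE_GROUP_INTAKE: dict[str, float] = {
    "Fruits and berries": 180.0, "Vegetables": 260.0, "Potatoes": 120.0,
    "Legumes": 2.5, "Nuts and seeds": 7.0, "Whole-grain cereals": 80.0,
    "Refined grains": 47.0, "Beef": 29.0, "Pork": 32.0, "Poultry": 40.0,
    "Processed meat": 40.0, "Fish": 37.0, "Eggs": 35.0,
    "Low-fat milk": 200.0, "Liquid dairy": 246.0, "Solid dairy": 62.0,
    "Vegetable-based fat": 20.0, "Animal fat": 12.0,
    "Sweets and chocolate": 26.0, "Sugared beverages": 120.0,
    "Juices": 80.0, "Alcoholic beverages": 140.0, "Coffee and tea": 600.0,
    "Condiments": 15.0, "Other": 30.0,
}

# Energy density archetype, kJ per g of food as eaten.
GROUP_ENERGY_DENSITY: dict[str, float] = {
    "Fruits and berries": 2.0, "Vegetables": 1.2, "Potatoes": 3.2,
    "Legumes": 4.0, "Nuts and seeds": 25.0, "Whole-grain cereals": 12.0,
    "Refined grains": 11.0, "Beef": 8.0, "Pork": 9.0, "Poultry": 7.0,
    "Processed meat": 11.0, "Fish": 7.0, "Eggs": 6.0, "Low-fat milk": 1.6,
    "Liquid dairy": 2.5, "Solid dairy": 14.0, "Vegetable-based fat": 30.0,
    "Animal fat": 30.0, "Sweets and chocolate": 18.0,
    "Sugared beverages": 1.8, "Juices": 1.9, "Alcoholic beverages": 3.0,
    "Coffee and tea": 0.3, "Condiments": 4.0, "Other": 3.0,
}

# Cluster log-scale intake shifts by food group.  Columns are "signature"
# group blocks; each pair of cluster rows differs by >= 3 sigma (sigma = 0.3)
# on at least one block of >= 5 foods, which is what makes the planted
# structure recoverable by the full pipeline.
_SIG = {
    "meat": ("Beef", "Pork", "Processed meat", "Poultry"),
    "plant": ("Fruits and berries", "Vegetables"),
    "fish": ("Fish",),
    "dairy": ("Low-fat milk", "Liquid dairy", "Solid dairy"),
    "grain": ("Whole-grain cereals", "Refined grains"),
    "legume": ("Legumes", "Nuts and seeds"),
    "sweet": ("Sweets and chocolate", "Sugared beverages"),
    "egg": ("Eggs",),
}
# rows: cluster 1..5 (lowest impact, average, good compromise, meat-leaning,
# highest impact); columns: the signature blocks above.
_PROFILE = {
    #        meat  plant  fish  dairy  grain legume sweet   egg
    1: dict(meat=-1.6, plant=0.0, fish=-1.2, dairy=-1.0, grain=1.0, legume=1.0, sweet=0.6, egg=-1.0),
    2: dict(meat=0.0, plant=0.0, fish=0.0, dairy=0.0, grain=0.0, legume=0.0, sweet=0.0, egg=0.0),
    3: dict(meat=-0.9, plant=0.8, fish=1.4, dairy=-0.5, grain=0.0, legume=1.6, sweet=-0.7, egg=0.1),
    4: dict(meat=1.2, plant=0.0, fish=0.0, dairy=0.7, grain=-0.7, legume=-1.0, sweet=0.9, egg=0.8),
    5: dict(meat=2.2, plant=0.2, fish=0.4, dairy=1.3, grain=-1.3, legume=-1.6, sweet=-1.1, egg=1.5),
}

# Per-cluster sociodemographic models (loosely mirroring the published
# cluster portraits: the compromise cluster older/more women/more educated,
# the heaviest-impact cluster younger and predominantly male).
_SOCIO = {
    1: dict(age=(61.0, 13.0), female=0.53, bmi=26.6,
            edu=(0.31, 0.38, 0.31), act=(0.29, 0.45, 0.20, 0.06),
            smoke=(0.59, 0.22, 0.04, 0.15), income_mean=4.5,
            urban=(0.65, 0.20, 0.15)),
    2: dict(age=(55.0, 14.0), female=0.58, bmi=27.4,
            edu=(0.34, 0.36, 0.30), act=(0.28, 0.44, 0.21, 0.07),
            smoke=(0.57, 0.22, 0.04, 0.17), income_mean=5.0,
            urban=(0.65, 0.20, 0.15)),
    3: dict(age=(61.0, 12.0), female=0.66, bmi=27.0,
            edu=(0.22, 0.36, 0.42), act=(0.14, 0.48, 0.28, 0.10),
            smoke=(0.65, 0.22, 0.03, 0.10), income_mean=5.0,
            urban=(0.72, 0.16, 0.12)),
    4: dict(age=(51.0, 13.0), female=0.51, bmi=28.2,
            edu=(0.34, 0.37, 0.29), act=(0.23, 0.43, 0.24, 0.10),
            smoke=(0.55, 0.24, 0.04, 0.17), income_mean=5.4,
            urban=(0.69, 0.18, 0.13)),
    5: dict(age=(49.0, 12.0), female=0.35, bmi=28.0,
            edu=(0.31, 0.38, 0.31), act=(0.21, 0.40, 0.26, 0.13),
            smoke=(0.56, 0.23, 0.04, 0.17), income_mean=5.8,
            urban=(0.67, 0.19, 0.14)),
}

# Relative impact-factor ranges per kg of food (rescaled at spec build time
# so the expected population totals land near realistic daily diet
# footprints).  Orderings encode the qualitative structure: ruminant meat
# and dairy dominate GWP/land/marine eutrophication; farmed fish dominates
# freshwater eutrophication.
_BASE_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "gwp": {
        "Beef": (25, 35), "Pork": (5, 7), "Poultry": (4, 6),
        "Processed meat": (7, 10), "Fish": (5, 8), "Eggs": (3.5, 5),
        "Low-fat milk": (1.2, 1.6), "Liquid dairy": (1.2, 1.8),
        "Solid dairy": (7, 11), "Animal fat": (8, 12),
        "Vegetable-based fat": (2.5, 4), "Fruits and berries": (0.7, 1.1),
        "Vegetables": (1.0, 1.6), "Potatoes": (0.4, 0.6),
        "Legumes": (0.8, 1.6), "Nuts and seeds": (1.5, 3),
        "Whole-grain cereals": (1.2, 1.8), "Refined grains": (1.3, 1.9),
        "Sweets and chocolate": (3, 5), "Sugared beverages": (0.6, 1.0),
        "Juices": (0.8, 1.2), "Alcoholic beverages": (1.0, 1.6),
        "Coffee and tea": (0.3, 0.5), "Condiments": (1.5, 2.5),
        "Other": (1.5, 2.5),
    },
    "land_use": {
        "Beef": (120, 200), "Pork": (10, 14), "Poultry": (7, 10),
        "Processed meat": (12, 18), "Fish": (3, 6), "Eggs": (5, 7),
        "Low-fat milk": (1.5, 2.2), "Liquid dairy": (1.5, 2.5),
        "Solid dairy": (9, 14), "Animal fat": (10, 16),
        "Vegetable-based fat": (7, 11), "Fruits and berries": (0.8, 1.4),
        "Vegetables": (0.4, 0.8), "Potatoes": (0.3, 0.5),
        "Legumes": (3, 5), "Nuts and seeds": (8, 13),
        "Whole-grain cereals": (2.5, 4), "Refined grains": (2.5, 4),
        "Sweets and chocolate": (3, 6), "Sugared beverages": (0.5, 1.0),
        "Juices": (1.0, 1.6), "Alcoholic beverages": (1.5, 2.5),
        "Coffee and tea": (3, 6), "Condiments": (1, 2), "Other": (1, 2),
    },
    "marine_eutroph": {
        "Beef": (30, 40), "Pork": (12, 18), "Poultry": (10, 15),
        "Processed meat": (15, 22), "Fish": (12, 20), "Eggs": (8, 12),
        "Low-fat milk": (3, 6), "Liquid dairy": (4, 7),
        "Solid dairy": (15, 25), "Animal fat": (8, 14),
        "Vegetable-based fat": (2, 4), "Fruits and berries": (1, 2),
        "Vegetables": (1, 2.5), "Potatoes": (0.5, 1),
        "Legumes": (1, 2), "Nuts and seeds": (2, 4),
        "Whole-grain cereals": (2, 4), "Refined grains": (2, 4),
        "Sweets and chocolate": (2, 4), "Sugared beverages": (0.5, 1),
        "Juices": (0.8, 1.5), "Alcoholic beverages": (1, 2),
        "Coffee and tea": (0.5, 1), "Condiments": (1, 2), "Other": (1, 2),
    },
    "freshwater_eutroph": {
        "Beef": (10, 15), "Pork": (8, 12), "Poultry": (5, 8),
        "Processed meat": (8, 14), "Fish": (50, 80), "Eggs": (4, 6),
        "Low-fat milk": (2, 4), "Liquid dairy": (2, 4),
        "Solid dairy": (6, 10), "Animal fat": (4, 8),
        "Vegetable-based fat": (1, 2), "Fruits and berries": (0.4, 0.8),
        "Vegetables": (0.5, 1), "Potatoes": (0.3, 0.6),
        "Legumes": (0.5, 1), "Nuts and seeds": (1, 2),
        "Whole-grain cereals": (0.8, 1.5), "Refined grains": (0.8, 1.5),
        "Sweets and chocolate": (1, 2), "Sugared beverages": (0.3, 0.6),
        "Juices": (0.3, 0.6), "Alcoholic beverages": (0.5, 1),
        "Coffee and tea": (0.2, 0.4), "Condiments": (0.5, 1),
        "Other": (0.5, 1),
    },
}

#: Expected population-mean daily totals the factor magnitudes are calibrated
#: to (kg CO2-eq, m2, kg N-eq, kg P-eq per person per day) — the scale of a
#: present-day Nordic adult diet.
CALIBRATION_TARGETS: dict[str, float] = {
    "gwp": 6.23,
    "land_use": 5.58,
    "marine_eutroph": 5.84e-3,
    "freshwater_eutroph": 2.42e-3,
}

#: Groups whose import mass exceeds exports in the default trade table.
DEFAULT_IMPORTED_GROUPS = frozenset({
    "Fruits and berries", "Nuts and seeds", "Legumes", "Juices",
    "Alcoholic beverages", "Coffee and tea", "Sweets and chocolate",
    "Condiments", "Other",
})

_COMPOSITION_SEED = 170_501  # fixes the food-composition constants of the default spec


@dataclass
class PopulationSpec:
    """Complete recipe for one synthetic survey population.

    ``mu`` holds the per-cluster, per-food log-normal location (rows:
    clusters 1..K, columns: food_ids); ``sigma_log`` the shared log-scale
    SD.  ``nutrient_composition`` maps grams of food to nutrient amounts
    (energy_kj doubles as the energy density, kJ/g).
    """

    n_persons: int
    cluster_proportions: np.ndarray
    mu: pd.DataFrame                      # K x 81 log-scale intake locations
    sigma_log: float
    nutrient_composition: pd.DataFrame    # 81 x 46 per-gram matrix
    impact_factor_ranges: dict[str, dict[str, tuple[float, float]]]  # per kg
    foods: pd.DataFrame
    socio: dict[int, dict] = field(default_factory=lambda: dict(_SOCIO))
    person_scale_sd: float = 0.20
    sex_log_scale: float = 0.12           # males eat slightly more overall
    nutrient_noise_sd: float = 0.05
    weight_model: tuple[float, float, float] = (1.2, 0.45, 0.35)  # b0, b_age, b_female
    imported_groups: frozenset = DEFAULT_IMPORTED_GROUPS
    seed: int = 0

    def __post_init__(self) -> None:
        self.cluster_proportions = np.asarray(self.cluster_proportions, dtype=float)
        if abs(self.cluster_proportions.sum() - 1.0) > 1e-9:
            raise SpecError("cluster_proportions must sum to 1")
        if (self.cluster_proportions < 0).any():
            raise SpecError("cluster_proportions must be non-negative")
        if self.sigma_log < 0 or self.person_scale_sd < 0 or self.nutrient_noise_sd < 0:
            raise SpecError("scale parameters must be >= 0")
        if len(self.mu) != self.n_clusters:
            raise SpecError(
                f"{len(self.mu)} intake-parameter rows for "
                f"{self.n_clusters} cluster proportions")
        if (self.nutrient_composition["energy_kj"] <= 0).any():
            raise SpecError("energy densities must be > 0")
        if list(self.mu.columns) != list(self.foods.index):
            raise SpecError("mu columns must match the food registry")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_proportions)

    def replace(self, **kw) -> "PopulationSpec":
        return dataclasses.replace(self, **kw)

    def separation_counts(self, k_sigma: float = 3.0) -> pd.DataFrame:
        """Foods on which each cluster pair is separated by >= k_sigma in log mean."""
        ks = list(self.mu.index)
        out = {}
        for i, a in enumerate(ks):
            for b in ks[i + 1:]:
                diff = (self.mu.loc[a] - self.mu.loc[b]).abs()
                out[(a, b)] = int((diff >= k_sigma * max(self.sigma_log, 1e-12)).sum())
        return pd.Series(out, name="n_separated_foods").rename_axis(["cluster_a", "cluster_b"]).to_frame()


def _food_shares(count: int) -> np.ndarray:
    w = 0.65 ** np.arange(count)
    return w / w.sum()


def _build_composition(foods: pd.DataFrame) -> pd.DataFrame:
    """Per-gram nutrient composition with group archetypes + fixed jitter."""
    rng = np.random.default_rng(_COMPOSITION_SEED)
    comp = pd.DataFrame(0.0, index=foods.index, columns=list(NUTRIENTS))
    g = foods["food_group"]

    def set_group(nutrient, mapping, default=0.0):
        comp[nutrient] = g.map(lambda x: mapping.get(x, default)).astype(float)

    comp["energy_kj"] = g.map(GROUP_ENERGY_DENSITY).astype(float)
    protein = {"Beef": 0.20, "Pork": 0.19, "Poultry": 0.20, "Processed meat": 0.14,
               "Fish": 0.18, "Eggs": 0.12, "Low-fat milk": 0.035, "Liquid dairy": 0.034,
               "Solid dairy": 0.25, "Legumes": 0.08, "Nuts and seeds": 0.20,
               "Whole-grain cereals": 0.10, "Refined grains": 0.09, "Potatoes": 0.02,
               "Vegetables": 0.02, "Fruits and berries": 0.008, "Sweets and chocolate": 0.05,
               "Condiments": 0.02, "Other": 0.02}
    set_group("protein_g", protein)
    is_animal = g.isin(ANIMAL_GROUPS).to_numpy()
    comp["animal_protein_g"] = np.where(is_animal, comp["protein_g"], 0.0)
    comp["plant_protein_g"] = np.where(is_animal, 0.0, comp["protein_g"])

    set_group("carbohydrate_g", {"Whole-grain cereals": 0.60, "Refined grains": 0.65,
                                 "Potatoes": 0.17, "Fruits and berries": 0.12,
                                 "Vegetables": 0.04, "Legumes": 0.12,
                                 "Sweets and chocolate": 0.60, "Sugared beverages": 0.10,
                                 "Juices": 0.10, "Low-fat milk": 0.05, "Liquid dairy": 0.05,
                                 "Solid dairy": 0.03, "Nuts and seeds": 0.15,
                                 "Alcoholic beverages": 0.03, "Other": 0.10})
    set_group("sucrose_g", {"Sweets and chocolate": 0.40, "Sugared beverages": 0.09,
                            "Juices": 0.08, "Fruits and berries": 0.05, "Other": 0.03})
    set_group("fiber_g", {"Whole-grain cereals": 0.10, "Legumes": 0.06, "Vegetables": 0.025,
                          "Fruits and berries": 0.022, "Nuts and seeds": 0.07,
                          "Potatoes": 0.015, "Refined grains": 0.03})
    set_group("fat_g", {"Vegetable-based fat": 0.80, "Animal fat": 0.82, "Nuts and seeds": 0.55,
                        "Solid dairy": 0.28, "Processed meat": 0.25, "Pork": 0.15,
                        "Beef": 0.12, "Poultry": 0.08, "Fish": 0.10, "Eggs": 0.10,
                        "Sweets and chocolate": 0.25, "Liquid dairy": 0.025,
                        "Low-fat milk": 0.005, "Whole-grain cereals": 0.03,
                        "Refined grains": 0.03})
    set_group("sfa_g", {"Animal fat": 0.50, "Solid dairy": 0.18, "Processed meat": 0.10,
                        "Sweets and chocolate": 0.14, "Pork": 0.055, "Beef": 0.05,
                        "Vegetable-based fat": 0.12, "Poultry": 0.022, "Fish": 0.02,
                        "Eggs": 0.03, "Liquid dairy": 0.015, "Low-fat milk": 0.003,
                        "Nuts and seeds": 0.06})
    set_group("pufa_g", {"Vegetable-based fat": 0.30, "Nuts and seeds": 0.25, "Fish": 0.035,
                         "Animal fat": 0.04, "Whole-grain cereals": 0.012,
                         "Poultry": 0.018, "Pork": 0.02, "Eggs": 0.015,
                         "Processed meat": 0.025, "Beef": 0.01})
    comp["mufa_g"] = (comp["fat_g"] - comp["sfa_g"] - comp["pufa_g"]).clip(lower=0.0) * 0.8
    set_group("trans_fat_g", {"Animal fat": 0.02, "Solid dairy": 0.01,
                              "Processed meat": 0.004, "Beef": 0.004,
                              "Sweets and chocolate": 0.005})
    set_group("n3_fa_g", {"Fish": 0.018, "Vegetable-based fat": 0.05, "Nuts and seeds": 0.04})
    comp["n6_fa_g"] = (comp["pufa_g"] - comp["n3_fa_g"]).clip(lower=0.0)
    set_group("alcohol_g", {"Alcoholic beverages": 0.045})
    set_group("vitamin_c_mg", {"Fruits and berries": 0.45, "Vegetables": 0.30,
                               "Juices": 0.30, "Potatoes": 0.10, "Legumes": 0.05})
    set_group("vitamin_d_ug", {"Fish": 0.10, "Eggs": 0.018, "Low-fat milk": 0.01,
                               "Liquid dairy": 0.01, "Vegetable-based fat": 0.08})
    set_group("vitamin_b12_ug", {"Beef": 0.02, "Fish": 0.04, "Liquid dairy": 0.004,
                                 "Low-fat milk": 0.004, "Solid dairy": 0.015,
                                 "Eggs": 0.01, "Pork": 0.007, "Processed meat": 0.008,
                                 "Poultry": 0.004})
    set_group("calcium_mg", {"Low-fat milk": 1.2, "Liquid dairy": 1.2, "Solid dairy": 7.0,
                             "Fish": 0.5, "Legumes": 0.5, "Nuts and seeds": 1.0,
                             "Vegetables": 0.4, "Whole-grain cereals": 0.3})
    set_group("iron_mg", {"Beef": 0.026, "Whole-grain cereals": 0.035, "Legumes": 0.02,
                          "Processed meat": 0.015, "Nuts and seeds": 0.03,
                          "Vegetables": 0.008, "Eggs": 0.018, "Pork": 0.01})
    set_group("sodium_mg", {"Processed meat": 9.0, "Solid dairy": 6.0, "Condiments": 20.0,
                            "Refined grains": 4.0, "Whole-grain cereals": 4.0,
                            "Sweets and chocolate": 1.0, "Fish": 3.0, "Other": 3.0})
    comp["salt_g"] = comp["sodium_mg"] * 2.5 / 1000.0
    set_group("caffeine_mg", {"Coffee and tea": 0.35, "Sugared beverages": 0.08,
                              "Sweets and chocolate": 0.15})
    set_group("water_g", {"Sugared beverages": 0.89, "Juices": 0.88, "Coffee and tea": 0.98,
                          "Low-fat milk": 0.90, "Liquid dairy": 0.88, "Vegetables": 0.92,
                          "Fruits and berries": 0.85, "Alcoholic beverages": 0.92,
                          "Fish": 0.70, "Beef": 0.65, "Pork": 0.62, "Poultry": 0.70,
                          "Potatoes": 0.78}, default=0.30)
    set_group("lactose_g", {"Low-fat milk": 0.047, "Liquid dairy": 0.045, "Solid dairy": 0.01})

    # Remaining micro-nutrients: small positive group-specific archetypes so
    # every group has a distinct micro-signature.
    remaining = [n for n in NUTRIENTS if (comp[n] == 0).all()]
    for nutrient in remaining:
        base = rng.uniform(0.2, 1.0, size=len(FOOD_GROUPS))
        mapping = dict(zip(FOOD_GROUPS, base))
        scale = {"_ug": 1.0, "_mg": 0.05, "_g": 0.005}.get(nutrient[-3:], 0.01)
        comp[nutrient] = g.map(mapping).astype(float) * scale

    # Per-food jitter (fixed): each food deviates from its group archetype.
    jitter = rng.lognormal(mean=0.0, sigma=0.15, size=comp.shape)
    comp = comp * jitter
    comp["protein_g"] = comp["plant_protein_g"] + comp["animal_protein_g"]
    comp["energy_kj"] = g.map(GROUP_ENERGY_DENSITY).astype(float) * \
        rng.lognormal(0.0, 0.08, size=len(comp))
    return comp


# Cluster mean energy relative to the baseline pattern.  Diet patterns differ
# mainly in composition; energy differs only moderately between them (the
# heaviest-eating pattern ~25% above, the compromise pattern near average).
_ENERGY_LEVEL = {1: 1.08, 2: 0.98, 3: 1.00, 4: 1.08, 5: 1.25}


def _build_mu(foods: pd.DataFrame, sigma: float, profile: dict[int, dict]) -> pd.DataFrame:
    block_of = {grp: name for name, grps in _SIG.items() for grp in grps}
    density = foods["food_group"].map(GROUP_ENERGY_DENSITY).to_numpy()
    rows = {}
    for k, prof in profile.items():
        mus = []
        for group, count in GROUP_FOOD_COUNTS.items():
            shares = _food_shares(count)
            shift = prof.get(block_of.get(group, ""), 0.0)
            base = BASE_GROUP_INTAKE[group] * shares
            mus.extend(np.log(base) - sigma ** 2 / 2 + shift)
        mus = np.asarray(mus)
        # re-center so the cluster's expected energy sits at its target level:
        # a uniform log-offset preserves the compositional signature
        e_base = float(np.sum(np.exp(np.log(np.concatenate(
            [BASE_GROUP_INTAKE[g] * _food_shares(c)
             for g, c in GROUP_FOOD_COUNTS.items()]))) * density))
        e_k = float(np.sum(np.exp(mus + sigma ** 2 / 2) * density))
        level = _ENERGY_LEVEL.get(k, 1.0)
        rows[k] = mus + np.log(level * e_base / e_k)
    return pd.DataFrame(rows, index=foods.index).T


def default_spec(n_persons: int = 5125, seed: int = 0,
                 sigma_log: float = 0.30) -> PopulationSpec:
    """The default five-cluster population: shares 16/38/18/24/4 %,
    log-normal intakes, calibrated impact-factor magnitudes."""
    foods = food_registry()
    mu = _build_mu(foods, sigma_log, _PROFILE)
    comp = _build_composition(foods)
    spec = PopulationSpec(
        n_persons=n_persons,
        cluster_proportions=np.array([0.16, 0.38, 0.18, 0.24, 0.04]),
        mu=mu,
        sigma_log=sigma_log,
        nutrient_composition=comp,
        impact_factor_ranges={k: dict(v) for k, v in _BASE_RANGES.items()},
        foods=foods,
        seed=seed,
    )
    return _calibrate_ranges(spec)


def _expected_intake(spec: PopulationSpec) -> pd.Series:
    """Analytic survey-weighted expected g/day per food under the mixture.

    Accounts for the log-normal variance inflation, the male intake shift
    and the covariance between survey weights and sex/age (weights are
    inverse response propensities evaluated at each cluster's mean age).
    """
    var = spec.sigma_log ** 2 + spec.person_scale_sd ** 2
    b0, b_age, b_fem = spec.weight_model
    num = np.zeros(spec.mu.shape[1])
    den = 0.0
    for k, pi in zip(spec.mu.index, spec.cluster_proportions):
        s = spec.socio.get(k, _SOCIO[2])
        base = np.exp(spec.mu.loc[k].to_numpy() + var / 2)
        for female, p_sex in ((True, s["female"]), (False, 1.0 - s["female"])):
            lin = b0 + b_age * (s["age"][0] - 55.0) / 10.0 + b_fem * female
            w_sex = 1.0 + np.exp(-lin)          # 1 / logistic propensity
            x_factor = 1.0 if female else np.exp(spec.sex_log_scale)
            num += pi * p_sex * w_sex * base * x_factor
            den += pi * p_sex * w_sex
    return pd.Series(num / den, index=spec.mu.columns)


def _calibrate_ranges(spec: PopulationSpec) -> PopulationSpec:
    """Rescale each impact's factor ranges so the expected population mean
    daily total matches the calibration target for that impact."""
    expected = _expected_intake(spec)
    groups = spec.foods["food_group"]
    scaled: dict[str, dict[str, tuple[float, float]]] = {}
    for impact, ranges in spec.impact_factor_ranges.items():
        mid = groups.map(lambda grp: sum(ranges[grp]) / 2.0) / 1000.0  # per g
        total = float((expected * mid).sum())
        s = CALIBRATION_TARGETS[impact] / total
        scaled[impact] = {grp: (lo * s, hi * s) for grp, (lo, hi) in ranges.items()}
    return spec.replace(impact_factor_ranges=scaled)


# ---------------------------------------------------------------------------
# Generators


def generate_population(spec: PopulationSpec
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Draw one population: (IntakeTable, NutrientTable, PersonTable, GroundTruth).

    Intakes are log-normal per cluster; nutrient intakes are
    ``intakes @ composition`` with multiplicative noise (energy kept exactly
    equal to sum(intake x energy density)); survey weights come from the
    non-response propensity model and are normalized to mean 1.
    """
    rng = np.random.default_rng(spec.seed)
    n, K = spec.n_persons, spec.n_clusters
    person_ids = [f"p{i:05d}" for i in range(1, n + 1)]
    clusters = spec.mu.index.to_numpy()

    labels = rng.choice(clusters, size=n, p=spec.cluster_proportions)
    socio = {k: spec.socio.get(k, _SOCIO[2]) for k in clusters}

    female = np.array([rng.random() < socio[k]["female"] for k in labels])
    sex = np.where(female, "female", "male")
    scale = rng.normal(0.0, spec.person_scale_sd, size=n) + \
        np.where(female, 0.0, spec.sex_log_scale)

    mu_rows = spec.mu.loc[labels].to_numpy()
    noise = rng.normal(0.0, 1.0, size=mu_rows.shape) * spec.sigma_log
    intake = np.exp(mu_rows + scale[:, None] + noise)
    intakes = pd.DataFrame(intake, index=pd.Index(person_ids, name="person_id"),
                           columns=spec.mu.columns)

    comp = spec.nutrient_composition
    nutrients = intakes.to_numpy() @ comp.to_numpy()
    nutrients = pd.DataFrame(nutrients, index=intakes.index, columns=comp.columns)
    energy = intakes.to_numpy() @ comp["energy_kj"].to_numpy()
    if spec.nutrient_noise_sd > 0:
        noise_n = rng.lognormal(0.0, spec.nutrient_noise_sd, size=nutrients.shape)
        nutrients = nutrients * noise_n
    nutrients["protein_g"] = nutrients["plant_protein_g"] + nutrients["animal_protein_g"]
    nutrients["energy_kj"] = energy  # exact: sum of intake x density

    age = np.empty(n)
    bmi = np.empty(n)
    edu = np.empty(n, dtype=int)
    act = np.empty(n, dtype=int)
    smoke = np.empty(n, dtype=int)
    income = np.empty(n, dtype=int)
    muni = np.empty(n, dtype=object)
    muni_levels = np.array(["urban", "semi-urban", "rural"])
    for i, k in enumerate(labels):
        s = socio[k]
        age[i] = np.clip(rng.normal(*s["age"]), 18, 95)
        bmi[i] = np.clip(rng.normal(s["bmi"], 4.0), 16, 55)
        edu[i] = rng.choice([1, 2, 3], p=np.asarray(s["edu"]) / np.sum(s["edu"]))
        act[i] = rng.choice([1, 2, 3, 4], p=np.asarray(s["act"]) / np.sum(s["act"]))
        smoke[i] = rng.choice([1, 2, 3, 4], p=np.asarray(s["smoke"]) / np.sum(s["smoke"]))
        income[i] = int(np.clip(round(rng.normal(s["income_mean"], 2.2)), 1, 10))
        muni[i] = muni_levels[rng.choice(3, p=np.asarray(s["urban"]) / np.sum(s["urban"]))]
    waist = bmi * 2.55 + np.where(female, -4.0, 6.0) + rng.normal(0, 4.0, size=n)

    # Non-response: younger men respond less, so their weights are larger.
    b0, b_age, b_fem = spec.weight_model
    lin = b0 + b_age * (age - 55.0) / 10.0 + b_fem * female
    propensity = 1.0 / (1.0 + np.exp(-lin))
    weights = 1.0 / propensity
    weights *= n / weights.sum()

    persons = pd.DataFrame({
        "person_id": person_ids, "sex": sex, "age": age, "education": edu,
        "income": income, "municipality": muni, "smoking": smoke,
        "physical_activity": act, "bmi": bmi, "waist": waist,
        "survey_weight": weights,
    })
    persons = validate_table(persons, PERSON_SCHEMA)
    intakes = validate_table(intakes.reset_index(), INTAKE_SCHEMA)
    nutrients = validate_table(nutrients.reset_index(), NUTRIENT_SCHEMA)
    truth = pd.Series(labels, index=intakes.index, name="cluster")
    return intakes, nutrients, persons, truth


def generate_impact_factors(spec: PopulationSpec) -> pd.DataFrame:
    """Per-food impact factors drawn uniformly within the spec's group ranges.

    Ranges are stated per kg of food and converted to the per-gram storage
    convention.  A seed offset keeps factor draws independent of the
    population draw under the same spec seed.
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)
    groups = spec.foods["food_group"]
    out = pd.DataFrame(index=spec.foods.index.copy())
    for impact in IMPACT_COLS:
        ranges = spec.impact_factor_ranges[impact]
        lo = groups.map(lambda grp: ranges[grp][0]).to_numpy()
        hi = groups.map(lambda grp: ranges[grp][1]).to_numpy()
        out[impact] = rng.uniform(lo, hi) / 1000.0
    out["origin_flag"] = np.where(groups.isin(spec.imported_groups), "imported", "domestic")
    out["adapted"] = 0
    return validate_table(out.reset_index(), IMPACT_FACTOR_SCHEMA)


def generate_trade_records(spec: PopulationSpec) -> pd.DataFrame:
    """Annual import/export masses (t/year) per food, with import/export
    ratio > 1 exactly for the spec's imported groups."""
    rng = np.random.default_rng(spec.seed + 2_000_003)
    groups = spec.foods["food_group"]
    export = rng.lognormal(mean=9.0, sigma=1.0, size=len(groups))
    imported = groups.isin(spec.imported_groups).to_numpy()
    ratio = np.where(imported, rng.uniform(1.5, 6.0, len(groups)),
                     rng.uniform(0.1, 0.9, len(groups)))
    trade = pd.DataFrame({
        "food_id": spec.foods.index,
        "import_t": export * ratio,
        "export_t": export,
    })
    return validate_table(trade, TRADE_SCHEMA)
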