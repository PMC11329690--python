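import numpy as np
import pandas as pd
import pytest

import dietshift as ds


@pytest.fixture(scope="session")
def small_spec():
    return ds.default_spec(n_persons=250, seed=11)


@pytest.fixture(scope="session")
def small_population(small_spec):
    intakes, nutrients, persons, truth = ds.generate_population(small_spec)
    factors = ds.generate_impact_factors(small_spec)
    return {"spec": small_spec, "intakes": intakes, "nutrients": nutrients,
            "persons": persons, "truth": truth, "factors": factors,
            "weights": persons["survey_weight"].to_numpy()}


@pytest.fixture()
def tiny_tables():
    """Hand-built 3-person, 2-food input set with fully known arithmetic."""
    foods = pd.DataFrame({
        "food_id": ["a", "b"],
        "name": ["Apple", "Beef cut"],
        "food_group": ["Fruits and berries", "Beef"],
    }).set_index("food_id")
    intakes = pd.DataFrame(
        {"a": [100.0, 0.0, 50.0], "b": [0.0, 200.0, 50.0]},
        index=pd.Index(["p1", "p2", "p3"], name="person_id"))
    factors = pd.DataFrame({
        "gwp": [1e-3, 30e-3],
        "land_use": [1e-3, 150e-3],
        "marine_eutroph": [1e-6, 30e-6],
        "freshwater_eutroph": [0.5e-6, 10e-6],
    }, index=pd.Index(["a", "b"], name="food_id"))
    persons = pd.DataFrame({
        "person_id": ["p1", "p2", "p3"],
        "sex": ["female", "male", "female"],
        "age": [40.0, 55.0, 63.0],
        "education": [1, 2, 3],
        "income": [3, 5, 7],
        "municipality": ["urban", "rural", "semi-urban"],
        "smoking": [1, 4, 2],
        "physical_activity": [2, 1, 3],
        "bmi": [24.0, 28.0, 26.0],
        "waist": [80.0, 100.0, 90.0],
        "survey_weight": [1.0, 1.5, 0.5],
    }).set_index("person_id")
    return {"foods": foods, "intakes": intakes, "factors": factors,
            "persons": persons}
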