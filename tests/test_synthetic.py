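import numpy as np
import pandas as pd
import pytest

import dietshift as ds
from dietshift.synthetic import SpecError, _expected_intake


def test_determinism_same_seed(small_spec):
    a = ds.generate_population(small_spec)
    b = ds.generate_population(small_spec)
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y) if isinstance(x, pd.DataFrame) \
            else pd.testing.assert_series_equal(x, y)
    pd.testing.assert_frame_equal(ds.generate_impact_factors(small_spec),
                                  ds.generate_impact_factors(small_spec))
    pd.testing.assert_frame_equal(ds.generate_trade_records(small_spec),
                                  ds.generate_trade_records(small_spec))


def test_degenerate_single_cluster_zero_sigma():
    """With one cluster and all dispersion parameters zero, everyone eats
    the same diet."""
    spec = ds.default_spec(n_persons=5, seed=3)
    spec = spec.replace(cluster_proportions=np.array([1.0]),
                        mu=spec.mu.iloc[[1]],
                        sigma_log=0.0, person_scale_sd=0.0, sex_log_scale=0.0)
    intakes, _, _, truth = ds.generate_population(spec)
    assert (truth == 2).all()
    assert np.allclose(intakes.to_numpy(), intakes.to_numpy()[0], rtol=1e-12)


def test_cluster_shares_within_binomial_error():
    """Sample cluster shares land within 3 binomial SEs of the target
    proportions (two-cluster spec with disjoint food support)."""
    spec = ds.default_spec(n_persons=2000, seed=5)
    props = np.array([0.3, 0.7])
    spec = spec.replace(cluster_proportions=props, mu=spec.mu.iloc[:2])
    _, _, _, truth = ds.generate_population(spec)
    n = len(truth)
    for k, p in zip(spec.mu.index, props):
        se = np.sqrt(p * (1 - p) / n)
        assert abs((truth == k).mean() - p) < 3 * se


def test_energy_equals_intake_times_density(small_population):
    spec = small_population["spec"]
    intakes = small_population["intakes"]
    energy = intakes.to_numpy() @ spec.nutrient_composition["energy_kj"].to_numpy()
    np.testing.assert_allclose(small_population["nutrients"]["energy_kj"].to_numpy(),
                               energy, rtol=1e-12)


def test_weights_mean_one_and_positive(small_population):
    w = small_population["weights"]
    assert np.all(w > 0)
    assert np.isclose(w.mean(), 1.0, rtol=1e-12)


def test_registry_dimensions():
    foods = ds.food_registry()
    assert len(foods) == 81
    assert foods["food_group"].nunique() == 25
    assert foods.index.is_unique


def test_protein_split_consistent(small_population):
    nut = small_population["nutrients"]
    assert (nut["plant_protein_g"] + nut["animal_protein_g"]
            <= nut["protein_g"] * (1 + 1e-9) + 1e-9).all()


def test_impact_factor_ordering(small_population):
    """Animal-source groups get higher GWP factors than plant groups; fish
    dominates the freshwater-eutrophication range."""
    spec = small_population["spec"]
    factors = small_population["factors"]
    groups = spec.foods["food_group"]
    mean_by_group = factors.groupby(groups)["gwp"].mean()
    assert mean_by_group["Beef"] > mean_by_group["Vegetables"]
    assert mean_by_group["Pork"] > mean_by_group["Fruits and berries"]
    fw = factors.groupby(groups)["freshwater_eutroph"].mean()
    assert fw.idxmax() == "Fish"


def test_zero_width_ranges_give_exact_factors(small_spec):
    ranges = {imp: {g: (1.0, 1.0) for g in ds.FOOD_GROUPS}
              for imp in ds.IMPACT_COLS}
    spec = small_spec.replace(impact_factor_ranges=ranges)
    factors = ds.generate_impact_factors(spec)
    np.testing.assert_allclose(factors[list(ds.IMPACT_COLS)].to_numpy(), 1e-3)


def test_separation_precondition_holds(small_spec):
    """Every cluster pair of the default spec differs by >= 3 sigma on at
    least 5 foods — the precondition of the recovery benchmark."""
    counts = small_spec.separation_counts(k_sigma=3.0)
    assert (counts["n_separated_foods"] >= 5).all()


def test_trade_ratio_classes(small_spec):
    trade = ds.generate_trade_records(small_spec)
    groups = small_spec.foods["food_group"]
    ratio = trade["import_t"] / trade["export_t"]
    imported = groups.isin(small_spec.imported_groups)
    assert (ratio[imported.to_numpy()] > 1).all()
    assert (ratio[~imported.to_numpy()] < 1).all()


def test_spec_validation_errors(small_spec):
    with pytest.raises(SpecError, match="sum to 1"):
        small_spec.replace(cluster_proportions=np.array([0.5, 0.6]))
    with pytest.raises(SpecError, match="cluster proportions"):
        small_spec.replace(cluster_proportions=np.array([0.5, 0.5]))


def test_calibration_targets_hit_in_expectation(small_spec):
    """The analytic expected daily totals equal the calibration targets at
    the midpoint of the factor ranges."""
    expected = _expected_intake(small_spec)
    groups = small_spec.foods["food_group"]
    for impact, target in ds.synthetic.CALIBRATION_TARGETS.items():
        ranges = small_spec.impact_factor_ranges[impact]
        mid = groups.map(lambda g: sum(ranges[g]) / 2) / 1000.0
        assert float((expected * mid).sum()) == pytest.approx(target, rel=1e-9)
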