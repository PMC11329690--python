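import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dietshift as ds
from dietshift.core_io import ValidationError


# ---------------------------------------------------------------------------
# quantitative v-test

def test_vtest_zero_when_means_equal():
    x = np.array([1.0, 2.0, 1.0, 2.0])
    labels = np.array([1, 1, 2, 2])
    res = ds.vtest_quant(x, labels)
    assert res.loc[1, "v"] == 0.0
    assert res.loc[2, "v"] == 0.0


def test_vtest_hand_oracle():
    """{0,0,10,10}, cluster = the two 10s: v = 5 / sqrt(12.5 * 2/3)."""
    x = np.array([0.0, 0.0, 10.0, 10.0])
    labels = np.array([1, 1, 2, 2])
    res = ds.vtest_quant(x, labels)
    expected = 5.0 / np.sqrt(12.5 * (2.0 / 3.0))
    assert res.loc[2, "v"] == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(1.7320508, abs=1e-6)
    assert res.loc[1, "v"] == pytest.approx(-expected, abs=1e-9)


def test_vtest_grows_with_duplication():
    """Duplicating the dataset scales |v| by about sqrt(2)."""
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 40)
    x[:10] += 1.0
    labels = np.array([1] * 10 + [2] * 30)
    v1 = ds.vtest_quant(x, labels).loc[1, "v"]
    v2 = ds.vtest_quant(np.tile(x, 2), np.tile(labels, 2)).loc[1, "v"]
    assert v2 / v1 == pytest.approx(np.sqrt(2.0), rel=0.02)


def test_vtest_weight_scale_invariance():
    """Weights are normalized to mean 1, so rescaling all weights by a
    constant leaves v unchanged, and unit weights equal the unweighted
    test; the weighted means themselves match the replication oracle."""
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 30)
    labels = rng.integers(1, 3, 30)
    w = rng.integers(1, 4, 30).astype(float)
    vw = ds.vtest_quant(x, labels, w)
    v_scaled = ds.vtest_quant(x, labels, 7.3 * w)
    v_const = ds.vtest_quant(x, labels, np.full(30, 5.0))
    v_unit = ds.vtest_quant(x, labels)
    rep = np.repeat(np.arange(30), w.astype(int))
    v_rep = ds.vtest_quant(x[rep], labels[rep])
    for k in (1, 2):
        assert vw.loc[k, "v"] == pytest.approx(v_scaled.loc[k, "v"], rel=1e-9)
        assert v_const.loc[k, "v"] == pytest.approx(v_unit.loc[k, "v"], rel=1e-9)
        assert vw.loc[k, "cluster_mean"] == pytest.approx(
            v_rep.loc[k, "cluster_mean"], rel=1e-9)


def test_vtest_single_cluster_undefined():
    with pytest.raises(ValidationError):
        ds.vtest_quant(np.arange(4.0), np.ones(4, dtype=int))


def test_vtest_matches_permutation_null():
    """The v statistic agrees with a permutation z-score of the cluster mean."""
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 50)
    labels = np.array([1] * 15 + [2] * 35)
    v = ds.vtest_quant(x, labels).loc[1, "v"]
    perm_means = np.array([
        rng.permutation(x)[:15].mean() for _ in range(10_000)])
    z_perm = (x[:15].mean() - perm_means.mean()) / perm_means.std()
    assert v == pytest.approx(z_perm, abs=0.08)


def test_vtest_null_calibration():
    """Under a global null, about 5% of |v| values exceed 1.96."""
    rng = np.random.default_rng(3)
    n, reps = 400, 800
    labels = np.array([1] * 100 + [2] * 300)
    hits = 0
    for _ in range(reps):
        v = ds.vtest_quant(rng.normal(0, 1, n), labels).loc[1, "v"]
        hits += abs(v) > 1.96
    assert hits / reps == pytest.approx(0.05, abs=0.02)


# ---------------------------------------------------------------------------
# categorical v-test

def test_vtest_cat_hand_oracle():
    """N=10, n_k=5, n_j=4, n_kj=4 -> v = 2 / sqrt(5*0.4*0.6*5/9) = 2.449."""
    category = np.array(["a"] * 4 + ["b"] * 6)
    labels = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2])
    res = ds.vtest_cat(category, labels)
    v = res.loc[(1, "a"), "v"]
    assert v == pytest.approx(2.0 / np.sqrt(5 * 0.4 * 0.6 * 5 / 9), abs=1e-9)
    assert v == pytest.approx(2.449, abs=1e-3)


def test_vtest_cat_zero_when_balanced():
    category = np.array(["a", "b"] * 10)
    labels = np.array([1] * 10 + [2] * 10)
    res = ds.vtest_cat(category, labels)
    assert (res["v"].abs() < 1e-12).all()


def test_vtest_cat_complement_symmetry():
    rng = np.random.default_rng(4)
    category = rng.choice(["a", "b"], 60)
    labels = rng.integers(1, 4, 60)
    res = ds.vtest_cat(category, labels)
    for k in np.unique(labels):
        assert res.loc[(k, "a"), "v"] == pytest.approx(-res.loc[(k, "b"), "v"],
                                                       abs=1e-9)


def test_vtest_cat_skips_missing_level():
    category = np.array(["a", "missing", "b", "a", "b", "a"])
    labels = np.array([1, 1, 1, 2, 2, 2])
    res = ds.vtest_cat(category, labels)
    assert "missing" not in res.index.get_level_values("category")


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn

def test_kruskal_identical_groups():
    x = np.array([1.0, 1.0, 1.0, 1.0])
    res = ds.kruskal_dunn(x, np.array([1, 1, 2, 2]))
    assert res.p == 1.0
    assert not res.pairwise["significant"].any()


def _brute_force_dunn(x, labels, a, b):
    ranks = stats.rankdata(x)
    N = len(x)
    _, counts = np.unique(x, return_counts=True)
    tie = np.sum(counts ** 3 - counts) / (12.0 * (N - 1))
    na, nb = np.sum(labels == a), np.sum(labels == b)
    ra, rb = ranks[labels == a].mean(), ranks[labels == b].mean()
    return (ra - rb) / np.sqrt((N * (N + 1) / 12.0 - tie) * (1 / na + 1 / nb))


def test_dunn_matches_bruteforce_separated_groups():
    x = np.array([1.0, 2, 3, 10, 11, 12, 20, 21, 22])
    labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
    res = ds.kruskal_dunn(x, labels, adjust="none")
    for (a, b), row in res.pairwise.iterrows():
        assert row["z"] == pytest.approx(_brute_force_dunn(x, labels, a, b),
                                         rel=1e-12)


def test_dunn_matches_bruteforce_with_ties():
    rng = np.random.default_rng(5)
    x = rng.integers(0, 6, 30).astype(float)  # plenty of ties
    labels = rng.integers(1, 4, 30)
    res = ds.kruskal_dunn(x, labels, adjust="none")
    for (a, b), row in res.pairwise.iterrows():
        assert row["z"] == pytest.approx(_brute_force_dunn(x, labels, a, b),
                                         rel=1e-12)


def test_kruskal_h_matches_scipy(small_population):
    pop = small_population
    imp = ds.person_impacts(pop["intakes"], pop["factors"])["gwp"].to_numpy()
    labels = pop["truth"].to_numpy()
    res = ds.kruskal_dunn(imp, labels)
    h, p = stats.kruskal(*[imp[labels == k] for k in np.unique(labels)])
    assert res.h == pytest.approx(h, rel=1e-12)
    assert res.p == pytest.approx(p, rel=1e-12)


def test_label_permutation_invariance():
    rng = np.random.default_rng(6)
    x = rng.normal(0, 1, 40)
    labels = rng.integers(1, 4, 40)
    res1 = ds.kruskal_dunn(x, labels)
    relabel = {1: 3, 2: 1, 3: 2}
    res2 = ds.kruskal_dunn(x, np.vectorize(relabel.get)(labels))
    assert res1.h == pytest.approx(res2.h, rel=1e-12)


def test_adjusted_p_never_below_raw():
    rng = np.random.default_rng(7)
    x = rng.normal(0, 1, 60)
    x[:20] += 1.0
    labels = np.array([1] * 20 + [2] * 20 + [3] * 20)
    for method in ("bonferroni", "holm"):
        res = ds.kruskal_dunn(x, labels, adjust=method)
        assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-15).all()
        assert res.pairwise["p_adj"].between(0, 1).all()


# ---------------------------------------------------------------------------
# diagnostics

def test_levene_null_size_calibrated():
    """Under equal-variance normal groups the Levene test rejects at about
    the nominal 5% rate."""
    rng = np.random.default_rng(8)
    reps = 2000
    labels = np.array([1] * 40 + [2] * 40 + [3] * 40)
    hits = 0
    for _ in range(reps):
        x = rng.normal(0, 1, 120)
        diag = ds.variance_normality_diag(x, labels)
        hits += diag.query("test == 'levene'")["p"].iloc[0] < 0.05
    se = np.sqrt(0.05 * 0.95 / reps)
    assert hits / reps == pytest.approx(0.05, abs=4 * se)


def test_levene_detects_tenfold_sd():
    rng = np.random.default_rng(9)
    x = np.concatenate([rng.normal(0, 1, 100), rng.normal(0, 10, 100)])
    labels = np.array([1] * 100 + [2] * 100)
    diag = ds.variance_normality_diag(x, labels)
    assert diag.query("test == 'levene'")["p"].iloc[0] < 1e-6


def test_shapiro_skipped_for_tiny_or_constant_groups():
    x = np.array([1.0, 2.0, 5.0, 5.0, 5.0, 7.0, 8.0, 9.0, 10.0])
    labels = np.array([1, 1, 2, 2, 2, 3, 3, 3, 3])
    diag = ds.variance_normality_diag(x, labels)
    sw = diag.query("test == 'shapiro_wilk'").set_index("cluster")
    assert np.isnan(sw.loc[1, "stat"])   # n < 3
    assert np.isnan(sw.loc[2, "stat"])   # constant
    assert np.isfinite(sw.loc[3, "stat"])


# ---------------------------------------------------------------------------
# pairwise proportions

def test_chisq_identical_proportions_no_pairs():
    category = np.array(["a", "b"] * 40)
    labels = np.array([1] * 40 + [2] * 40)
    res = ds.chisq_pairwise_props(category, labels)
    assert res["p"] > 0.05
    assert len(res["pairwise"]) == 0


def test_chisq_strong_difference_significant():
    """Proportions 0.9 vs 0.1 at n = 100 per cluster clear the Marascuilo
    critical value."""
    category = np.array(["a"] * 90 + ["b"] * 10 + ["a"] * 10 + ["b"] * 90)
    labels = np.array([1] * 100 + [2] * 100)
    res = ds.chisq_pairwise_props(category, labels)
    assert res["p"] < 1e-6
    row = res["pairwise"].loc[(1, 2)]
    assert row["max_diff"] == pytest.approx(0.8)
    # hand-computed critical value: sqrt(chi2_{0.95, 1}) * sqrt(2 * .09/100)
    crit = np.sqrt(stats.chi2.ppf(0.95, 1)) * np.sqrt(2 * 0.9 * 0.1 / 100)
    assert row["critical"] == pytest.approx(crit, rel=1e-9)
    assert row["significant"]


def test_chisq_bonferroni_not_more_liberal():
    """With more clusters (more pairs), the critical value only grows."""
    rng = np.random.default_rng(10)
    category = rng.choice(["a", "b"], 300, p=[0.7, 0.3])
    category[:50] = "a"  # force an omnibus signal
    labels2 = np.array([1] * 150 + [2] * 150)
    labels3 = np.array([1] * 100 + [2] * 100 + [3] * 100)
    r2 = ds.chisq_pairwise_props(category, labels2)
    r3 = ds.chisq_pairwise_props(category, labels3)
    if len(r2["pairwise"]) and len(r3["pairwise"]):
        chi2_m1 = stats.chi2.ppf(1 - 0.05 / 1, 1)
        chi2_m3 = stats.chi2.ppf(1 - 0.05 / 3, 1)
        assert chi2_m3 > chi2_m1


def test_chisq_low_expected_warning_flag():
    category = np.array(["a"] * 3 + ["b"] * 1 + ["a"] * 1 + ["b"] * 3)
    labels = np.array([1] * 4 + [2] * 4)
    res = ds.chisq_pairwise_props(category, labels)
    assert res["low_expected_warning"] in (True, False)  # flag present
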