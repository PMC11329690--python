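import numpy as np
import pandas as pd
import pytest

import dietshift as ds
from dietshift._weights import wcorr
from dietshift.core_io import ValidationError
from dietshift.mfa import MFAInput, _weighted_pca_eigs


def _frame(X, prefix="v"):
    return pd.DataFrame(X, index=pd.Index([f"p{i}" for i in range(len(X))],
                                          name="person_id"),
                        columns=[f"{prefix}{j}" for j in range(X.shape[1])])


def _standardize(X, w):
    w = w / w.sum()
    mean = w @ X
    sd = np.sqrt(w @ (X - mean) ** 2)
    return X / sd


def test_single_variable_single_dimension():
    X = _frame(np.array([[1.0], [2.0], [4.0]]))
    res = ds.fit_mfa(MFAInput(groups={"g": X}, n_dims=3))
    assert res.n_dims == 1
    assert res.pct_variance[0] == pytest.approx(100.0)


def test_duplicated_group_first_eigenvalue_equals_group_count():
    """Two active groups holding the same standardized variable: lambda1 = 1
    per group and the first global eigenvalue equals the number of groups."""
    rng = np.random.default_rng(0)
    w = rng.uniform(0.5, 2.0, 100)
    x = _standardize(rng.normal(0, 1, (100, 1)), w)
    res = ds.fit_mfa(MFAInput(groups={"a": _frame(x, "a"), "b": _frame(x, "b")},
                              weights=w, n_dims=2))
    assert res.group_lambda1["a"] == pytest.approx(1.0, rel=1e-9)
    assert res.eigenvalues[0] == pytest.approx(2.0, rel=1e-9)
    assert res.pct_variance[0] == pytest.approx(100.0, abs=1e-6)


def test_single_group_equals_weighted_pca_up_to_sign():
    """MFA with one active group is the group's weighted PCA scaled by
    1/sqrt(lambda1): scores are proportional up to sign per dimension."""
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, (200, 10))
    w = rng.uniform(0.5, 2.0, 200)
    Xs = _standardize(X, w)
    res = ds.fit_mfa(MFAInput(groups={"g": _frame(Xs)}, weights=w, n_dims=5))

    wn = w / w.sum()
    vals, vecs = _weighted_pca_eigs(Xs, wn)
    scores_pca = (Xs - wn @ Xs) @ vecs[:, :5] / np.sqrt(vals[0])
    got = res.scores.to_numpy()
    for j in range(5):
        agree = np.allclose(got[:, j], scores_pca[:, j], rtol=1e-8, atol=1e-10)
        flipped = np.allclose(got[:, j], -scores_pca[:, j], rtol=1e-8, atol=1e-10)
        assert agree or flipped


def test_eigenvalue_sum_equals_total_inertia(small_population):
    pop = small_population
    X = pop["nutrients"].drop(columns=["energy_kj"])
    e = pop["nutrients"]["energy_kj"]
    w = pop["weights"]
    sn, _ = ds.scale_to_sd(ds.energy_adjust_residual(X, e, w), w)
    imp = ds.person_impacts(pop["intakes"], pop["factors"])
    si, _ = ds.scale_to_sd(ds.energy_adjust_residual(imp, e, w), w)
    res = ds.fit_mfa(MFAInput(groups={"nutrients": sn, "impacts": si}, weights=w))
    assert res.eigenvalues.sum() == pytest.approx(res.total_inertia, rel=1e-9)
    assert res.pct_variance.sum() == pytest.approx(100.0, rel=1e-9)
    # MFA normalization: first global eigenvalue cannot exceed group count
    assert res.eigenvalues[0] <= 2.0 + 1e-9
    # eigenvalues non-increasing
    assert (np.diff(res.eigenvalues) <= 1e-9).all()


def test_sign_convention_deterministic():
    rng = np.random.default_rng(2)
    X = _standardize(rng.normal(0, 1, (50, 4)), np.ones(50))
    r1 = ds.fit_mfa(MFAInput(groups={"g": _frame(X)}))
    r2 = ds.fit_mfa(MFAInput(groups={"g": _frame(X)}))
    pd.testing.assert_frame_equal(r1.scores, r2.scores)


def test_supplementary_identical_to_active_same_correlation():
    rng = np.random.default_rng(3)
    w = rng.uniform(0.5, 2.0, 120)
    X = _standardize(rng.normal(0, 1, (120, 5)), w)
    Xf = _frame(X)
    res = ds.fit_mfa(MFAInput(groups={"g": Xf}, weights=w,
                              sup_quant=Xf.rename(columns=lambda c: f"sup_{c}")))
    for j, col in enumerate(Xf.columns):
        np.testing.assert_allclose(
            res.sup_quant_correlations.loc[f"sup_{col}"].to_numpy(),
            res.var_correlations.loc[col].to_numpy(), atol=1e-10)


def test_supplementary_orthogonal_variable_zero_correlation():
    rng = np.random.default_rng(4)
    X = _standardize(rng.normal(0, 1, (100, 2)), np.ones(100))
    res = ds.fit_mfa(MFAInput(groups={"g": _frame(X)}, n_dims=1))
    s = res.scores["dim1"].to_numpy()
    noise = rng.normal(0, 1, 100)
    ortho = noise - (noise @ s) / (s @ s) * s  # exactly orthogonal (unit weights)
    ortho = ortho - ortho.mean()
    sq = pd.DataFrame({"o": ortho}, index=res.scores.index)
    quant, _ = ds.project_supplementary(res, sq, None)
    assert abs(quant.loc["o", "dim1"]) < 1e-10


def test_supplementary_category_coordinates_opposite_signs():
    """A two-level variable splitting persons exactly by the sign of dim-1
    scores gets category barycenters of opposite sign."""
    rng = np.random.default_rng(5)
    w = rng.uniform(0.5, 2.0, 150)
    X = _standardize(rng.normal(0, 1, (150, 3)), w)
    res = ds.fit_mfa(MFAInput(groups={"g": _frame(X)}, weights=w, n_dims=2))
    s = res.scores["dim1"].to_numpy()
    cat = pd.DataFrame({"side": np.where(s > 0, "pos", "neg")},
                       index=res.scores.index)
    _, coords = ds.project_supplementary(res, None, cat)
    coords = coords.set_index("category")
    assert coords.loc["pos", "dim1"] > 0 > coords.loc["neg", "dim1"]
    # direct weighted-mean oracle
    wn = res.weights
    m = s > 0
    assert coords.loc["pos", "dim1"] == pytest.approx(
        float(np.sum(wn[m] * s[m]) / np.sum(wn[m])), rel=1e-9)


def test_overlapping_groups_rejected():
    X = _frame(np.random.default_rng(6).normal(0, 1, (10, 2)))
    with pytest.raises(ValidationError, match="overlap"):
        MFAInput(groups={"a": X, "b": X})


def test_constant_group_rejected():
    X = _frame(np.zeros((10, 2)))
    with pytest.raises(ValidationError, match="zero first eigenvalue"):
        ds.fit_mfa(MFAInput(groups={"a": X}))
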