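"""Weighted multiple factor analysis (MFA), implemented from its definition.

MFA is a principal component analysis of several concatenated variable
groups in which each group's columns are first divided by the square root
of the group's own first PCA eigenvalue.  This normalization caps every
group's contribution to any global axis at 1, so no group dominates merely
by being larger or more redundant.  Persons carry survey weights used as
row masses throughout (weighted centering, weighted covariance, weighted
correlations).

Supplementary variables do not shape the axes: quantitative ones are
projected as weighted correlations with the retained dimension scores;
categorical ones as weighted mean scores per category, with a v-test
assessing whether the category's barycenter deviates from the origin more
than random assignment of its (weighted) size would allow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from ._weights import as_weights, normalize_mean_one, wcorr
from .core_io import MISSING, ValidationError

__all__ = ["MFAInput", "MFAResult", "fit_mfa", "project_supplementary"]


@dataclass
class MFAInput:
    """Active variable groups plus optional supplementary variables.

    ``groups`` maps group name -> standardized person x variable block;
    blocks must share their row index and be column-disjoint.
    """

    groups: dict[str, pd.DataFrame]
    weights: np.ndarray | None = None
    sup_quant: pd.DataFrame | None = None
    sup_cat: pd.DataFrame | None = None
    n_dims: int = 5

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("need at least one active group")
        blocks = list(self.groups.values())
        index = blocks[0].index
        cols: set[str] = set()
        for name, b in self.groups.items():
            if not b.index.equals(index):
                raise ValidationError(f"group {name!r} has a different row index")
            overlap = cols & set(b.columns)
            if overlap:
                raise ValidationError(f"active groups overlap on columns {sorted(overlap)}")
            cols |= set(b.columns)


@dataclass
class MFAResult:
    """Eigenstructure, person scores and variable/category projections."""

    group_lambda1: dict[str, float]
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    scores: pd.DataFrame                    # person x retained dims
    var_correlations: pd.DataFrame          # active variable x dim (weighted corr)
    weights: np.ndarray                     # row masses, sum 1
    total_inertia: float
    sup_quant_correlations: pd.DataFrame | None = None
    sup_cat_coords: pd.DataFrame | None = None
    group_names: list[str] = field(default_factory=list)

    @property
    def n_dims(self) -> int:
        return self.scores.shape[1]


def _weighted_pca_eigs(X: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the weighted covariance of row-weighted, centered X."""
    mean = w @ X
    Xc = X - mean
    C = (Xc * w[:, None]).T @ Xc
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def fit_mfa(inp: MFAInput) -> MFAResult:
    """Fit the weighted MFA.

    Steps: (1) first eigenvalue of each active group's weighted PCA;
    (2) rescale the group's columns by 1/sqrt(lambda1); (3) weighted PCA of
    the concatenated matrix.  Dimension signs are fixed so the
    largest-|loading| active variable loads positively on each axis,
    making results reproducible across platforms.
    """
    blocks = list(inp.groups.values())
    index = blocks[0].index
    w = as_weights(inp.weights, len(index))
    w = w / w.sum()

    lambda1: dict[str, float] = {}
    rescaled = []
    for name, block in inp.groups.items():
        X = block.to_numpy(dtype=float)
        vals, _ = _weighted_pca_eigs(X, w)
        if vals[0] <= 1e-12:
            raise ValidationError(f"active group {name!r} has zero first eigenvalue")
        lambda1[name] = float(vals[0])
        rescaled.append(X / np.sqrt(vals[0]))

    Xg = np.concatenate(rescaled, axis=1)
    columns = [c for b in inp.groups.values() for c in b.columns]
    mean = w @ Xg
    Xc = Xg - mean
    total_inertia = float(np.sum(w[:, None] * Xc ** 2))

    vals, vecs = _weighted_pca_eigs(Xg, w)
    vals = np.clip(vals, 0.0, None)
    pct = 100.0 * vals / vals.sum()

    n_dims = min(inp.n_dims, Xg.shape[1])
    V = vecs[:, :n_dims]
    # deterministic sign: largest |entry| of each eigenvector is positive
    for j in range(n_dims):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    scores = Xc @ V
    dims = [f"dim{j + 1}" for j in range(n_dims)]
    scores_df = pd.DataFrame(scores, index=index, columns=dims)

    # correlation-circle coordinates: weighted corr of standardized active
    # variables (pre group-rescaling; scale does not affect correlation)
    corr = np.empty((Xg.shape[1], n_dims))
    for ci in range(Xg.shape[1]):
        for j in range(n_dims):
            corr[ci, j] = wcorr(Xg[:, ci], scores[:, j], w)
    var_corr = pd.DataFrame(corr, index=columns, columns=dims)

    result = MFAResult(
        group_lambda1=lambda1,
        eigenvalues=vals,
        pct_variance=pct,
        scores=scores_df,
        var_correlations=var_corr,
        weights=w,
        total_inertia=total_inertia,
        group_names=list(inp.groups),
    )
    if inp.sup_quant is not None or inp.sup_cat is not None:
        sq, sc = project_supplementary(result, inp.sup_quant, inp.sup_cat, w)
        result.sup_quant_correlations = sq
        result.sup_cat_coords = sc
    return result


def project_supplementary(result: MFAResult, sup_quant: pd.DataFrame | None,
                          sup_cat: pd.DataFrame | None, weights=None
                          ) -> tuple[pd.DataFrame | None, pd.DataFrame | None]:
    """Project supplementary variables onto the retained dimensions.

    Quantitative: weighted correlation with each dimension's scores.
    Categorical: weighted mean score (barycenter) per category and a
    categorical v-test per dimension; explicit ``missing`` levels and
    zero-weight categories are skipped.
    """
    scores = result.scores
    dims = list(scores.columns)
    w = result.weights if weights is None else np.asarray(weights, dtype=float) / np.sum(weights)
    S = scores.to_numpy()

    quant = None
    if sup_quant is not None:
        sup_quant = sup_quant.reindex(scores.index)
        rows = {}
        for col in sup_quant.columns:
            x = sup_quant[col].to_numpy(dtype=float)
            rows[col] = [wcorr(x, S[:, j], w) for j in range(len(dims))]
        quant = pd.DataFrame.from_dict(rows, orient="index", columns=dims)

    cat = None
    if sup_cat is not None:
        sup_cat = sup_cat.reindex(scores.index)
        # effective sizes on the n scale so the v-test denominator is interpretable
        w_eff = normalize_mean_one(w)
        N = float(np.sum(w_eff))
        lam = np.array([float(np.sum(w / w.sum() * S[:, j] ** 2)) for j in range(len(dims))])
        recs = []
        for var in sup_cat.columns:
            levels = sup_cat[var].astype(str)
            for level in sorted(levels.unique()):
                if level == MISSING:
                    continue
                mask = (levels == level).to_numpy()
                n_c = float(np.sum(w_eff[mask]))
                if n_c == 0.0:
                    warnings.warn(f"category {var}={level} has zero weight; skipped",
                                  RuntimeWarning, stacklevel=2)
                    continue
                coord = [float(np.sum(w[mask] * S[mask, j]) / np.sum(w[mask]))
                         for j in range(len(dims))]
                rec = {"variable": var, "category": level, "n_weighted": n_c}
                for j, d in enumerate(dims):
                    rec[d] = coord[j]
                    if N - n_c <= 0 or N <= 1:
                        rec[f"{d}_v_test"] = np.nan
                    else:
                        se = np.sqrt(((N - n_c) / (N - 1)) * lam[j] / n_c)
                        rec[f"{d}_v_test"] = coord[j] / se if se > 0 else np.nan
                recs.append(rec)
        cat = pd.DataFrame(recs)
    return quant, cat
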