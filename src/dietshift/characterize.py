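"""Cluster characterization: v-tests and the non-parametric post-hoc battery.

The v-test standardizes the deviation of a cluster's mean (or category
frequency) from the sample value under the null of random assignment of
the cluster's members, sampled without replacement::

    quantitative:  v_k = (xbar_k - xbar) / sqrt( s^2/n_k * (N - n_k)/(N - 1) )
    categorical:   v   = (n_kj - n_k n_j / N)
                         / sqrt( n_k (n_j/N)(1 - n_j/N)(N - n_k)/(N - 1) )

with s^2 the (weighted) population variance and n the (weighted) counts on
the mean-1 weight scale.  |v| > 1.96 flags a variable as characterizing
the cluster at the 5% level.

Because cluster variables are typically heteroscedastic and non-normal
(Levene and Shapiro-Wilk diagnostics are provided to document this), the
pairwise comparisons use Kruskal-Wallis with Dunn's rank-based post-hoc z
tests; non-ordinal categorical variables use an omnibus chi-square
followed by Marascuilo-style pairwise proportion comparisons.  Rank tests
run unweighted on the raw values (rank statistics with survey weights are
ill-defined; see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._weights import as_weights, normalize_mean_one
from .core_io import MISSING, ValidationError

__all__ = [
    "vtest_quant", "vtest_cat", "kruskal_dunn", "variance_normality_diag",
    "chisq_pairwise_props", "PosthocResult",
]

Z_05 = float(stats.norm.ppf(0.975))


def _split(labels: pd.Series | np.ndarray):
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 clusters")
    return labels, uniq


def vtest_quant(x, labels, weights=None, alpha: float = 0.05) -> pd.DataFrame:
    """Quantitative v-test of every cluster against the whole sample.

    Returns one row per cluster: cluster/sample means, v statistic and the
    two-sided significance flag at ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    labels, uniq = _split(labels)
    w = normalize_mean_one(as_weights(weights, len(x)))
    N = float(np.sum(w))
    mean = float(np.sum(w * x) / N)
    s2 = float(np.sum(w * (x - mean) ** 2) / N)
    zcrit = float(stats.norm.ppf(1 - alpha / 2))
    rows = []
    for k in uniq:
        m = labels == k
        n_k = float(np.sum(w[m]))
        if n_k >= N:
            raise ValidationError("v-test undefined for a cluster covering the whole sample")
        mean_k = float(np.sum(w[m] * x[m]) / n_k)
        se = np.sqrt(s2 / n_k * (N - n_k) / (N - 1))
        v = 0.0 if mean_k == mean else (mean_k - mean) / se
        rows.append({"cluster": k, "cluster_mean": mean_k, "sample_mean": mean,
                     "v": v, "significant": bool(abs(v) > zcrit)})
    return pd.DataFrame(rows).set_index("cluster")


def vtest_cat(category, labels, weights=None, alpha: float = 0.05) -> pd.DataFrame:
    """Categorical v-test (normal approximation of the hypergeometric).

    One row per (cluster, category level); explicit ``missing`` levels are
    excluded; levels covering nobody or everybody are skipped.
    """
    category = pd.Series(np.asarray(category, dtype=object))
    labels, uniq = _split(labels)
    w = normalize_mean_one(as_weights(weights, len(category)))
    keep = category.astype(str) != MISSING
    cat = category[keep].astype(str).to_numpy()
    lab = labels[keep.to_numpy()]
    ww = w[keep.to_numpy()]
    N = float(np.sum(ww))
    zcrit = float(stats.norm.ppf(1 - alpha / 2))
    rows = []
    for level in sorted(np.unique(cat)):
        in_level = cat == level
        n_j = float(np.sum(ww[in_level]))
        if n_j <= 0 or n_j >= N:
            continue
        p_j = n_j / N
        for k in uniq:
            m = lab == k
            n_k = float(np.sum(ww[m]))
            n_kj = float(np.sum(ww[m & in_level]))
            expected = n_k * p_j
            se = np.sqrt(n_k * p_j * (1 - p_j) * (N - n_k) / (N - 1))
            v = 0.0 if n_kj == expected else (n_kj - expected) / se
            rows.append({"cluster": k, "category": level,
                         "cluster_prop": n_kj / n_k, "sample_prop": p_j,
                         "v": v, "significant": bool(abs(v) > zcrit)})
    return pd.DataFrame(rows).set_index(["cluster", "category"])


@dataclass
class PosthocResult:
    """Kruskal-Wallis omnibus plus Dunn pairwise comparisons."""

    h: float
    p: float
    pairwise: pd.DataFrame   # index (a, b): z, p_raw, p_adj, significant


def _p_adjust(p: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if method == "none":
        return p
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        m = len(p)
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def kruskal_dunn(x, labels, adjust: str = "bonferroni",
                 alpha: float = 0.05) -> PosthocResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn pairwise z tests.

    Dunn's z for clusters i, j compares mean ranks over the pooled sample::

        z = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T) (1/n_i + 1/n_j) )

    with tie correction T = sum(t^3 - t) / (12 (N - 1)).  Two-sided p
    values are adjusted with Bonferroni by default (``adjust`` in
    none/holm/bonferroni).  When all values are tied, H is undefined and
    reported as p = 1.
    """
    x = np.asarray(x, dtype=float)
    labels, uniq = _split(labels)
    N = len(x)
    groups = [x[labels == k] for k in uniq]
    if np.all(x == x[0]):
        pairs = pd.DataFrame(
            [{"a": a, "b": b, "z": 0.0, "p_raw": 1.0, "p_adj": 1.0, "significant": False}
             for a, b in combinations(uniq, 2)]).set_index(["a", "b"])
        return PosthocResult(h=0.0, p=1.0, pairwise=pairs)
    h, p = stats.kruskal(*groups)

    ranks = stats.rankdata(x)
    _, counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    rbar = {k: float(np.mean(ranks[labels == k])) for k in uniq}
    n = {k: int(np.sum(labels == k)) for k in uniq}
    rows = []
    for a, b in combinations(uniq, 2):
        se = np.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
        z = (rbar[a] - rbar[b]) / se
        rows.append({"a": a, "b": b, "z": z,
                     "p_raw": 2.0 * stats.norm.sf(abs(z))})
    pairs = pd.DataFrame(rows)
    pairs["p_adj"] = _p_adjust(pairs["p_raw"].to_numpy(), adjust)
    pairs["significant"] = pairs["p_adj"] < alpha
    return PosthocResult(h=float(h), p=float(p),
                         pairwise=pairs.set_index(["a", "b"]))


def variance_normality_diag(x, labels) -> pd.DataFrame:
    """Levene (mean-centered) and per-cluster Shapiro-Wilk diagnostics.

    These justify the non-parametric path in reports: heteroscedasticity
    rules out ANOVA/Tukey, non-normal clusters rule out Welch-ANOVA /
    Games-Howell.  Shapiro-Wilk is skipped (NaN) for clusters smaller than
    3 or constant.
    """
    x = np.asarray(x, dtype=float)
    labels, uniq = _split(labels)
    groups = [x[labels == k] for k in uniq]
    lev_stat, lev_p = stats.levene(*groups, center="mean")
    rows = [{"test": "levene", "cluster": "all", "stat": float(lev_stat),
             "p": float(lev_p)}]
    for k, g in zip(uniq, groups):
        if len(g) < 3 or np.all(g == g[0]):
            rows.append({"test": "shapiro_wilk", "cluster": k,
                         "stat": np.nan, "p": np.nan})
        else:
            w_stat, p = stats.shapiro(g)
            rows.append({"test": "shapiro_wilk", "cluster": k,
                         "stat": float(w_stat), "p": float(p)})
    return pd.DataFrame(rows)


def chisq_pairwise_props(category, labels, alpha: float = 0.05) -> dict:
    """Omnibus chi-square on the cluster x category table; if significant,
    Marascuilo-style pairwise tests on the maximum proportion difference.

    For each cluster pair (i, j) the largest |p_i - p_j| over categories is
    compared with sqrt(chi2_{1 - alpha/m, df}) * sqrt(p_i(1-p_i)/n_i +
    p_j(1-p_j)/n_j) evaluated at the maximizing category, m the number of
    pairs (Bonferroni) and df = (number of categories - 1).  Returns a dict
    with the omnibus statistics, a validity warning flag when some expected
    cell count is below 1, and the pairwise decision table (empty when the
    omnibus is not significant).
    """
    category = pd.Series(np.asarray(category, dtype=object)).astype(str)
    labels, uniq = _split(labels)
    keep = category != MISSING
    cat = category[keep]
    lab = labels[keep.to_numpy()]
    table = pd.crosstab(pd.Series(lab, name="cluster"), cat)
    if table.shape[1] < 2:
        raise ValidationError("need at least 2 categories")
    chi2, p, dof, expected = stats.chi2_contingency(table)
    low_expected = bool((expected < 1).any())

    pairs = []
    if p < alpha:
        props = table.div(table.sum(axis=1), axis=0)
        n = table.sum(axis=1)
        pair_list = list(combinations(table.index, 2))
        m = len(pair_list)
        df_crit = table.shape[1] - 1
        chi_crit = stats.chi2.ppf(1 - alpha / m, df_crit)
        for a, b in pair_list:
            diffs = (props.loc[a] - props.loc[b]).abs()
            cstar = diffs.idxmax()
            pa, pb = props.at[a, cstar], props.at[b, cstar]
            crit = np.sqrt(chi_crit) * np.sqrt(pa * (1 - pa) / n[a] + pb * (1 - pb) / n[b])
            pairs.append({"a": a, "b": b, "category": cstar,
                          "max_diff": float(diffs[cstar]), "critical": float(crit),
                          "significant": bool(diffs[cstar] > crit)})
    pairwise = pd.DataFrame(pairs)
    if len(pairwise):
        pairwise = pairwise.set_index(["a", "b"])
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof),
            "low_expected_warning": low_expected, "pairwise": pairwise}
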