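"""Shapley explainers and the heterogeneity analysis.

The tree explainer is checked against an independent brute-force oracle:
subset enumeration over the Shapley formula with the tree's cover-weighted
conditional expectation as the value function.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from emastress.explain import (
    ShapMatrix,
    _tree_arrays,
    beeswarm_export,
    feature_shap_heterogeneity,
    importance_ranks,
    linear_shap,
    median_rank_table,
    median_ranks,
    permutation_shap,
    tree_shap,
)

# ------------------------------------------------- brute-force tree oracle --


def _cond_exp(cl, cr, feat, thr, val, cover, x, subset, node=0):
    """Tree value function: follow x for features in the subset, otherwise
    average children by training cover."""
    if cl[node] < 0:
        return val[node]
    f = feat[node]
    if f in subset:
        nxt = cl[node] if x[f] <= thr[node] else cr[node]
        return _cond_exp(cl, cr, feat, thr, val, cover, x, subset, nxt)
    left, right = cl[node], cr[node]
    return (
        cover[left] * _cond_exp(cl, cr, feat, thr, val, cover, x, subset, left)
        + cover[right] * _cond_exp(cl, cr, feat, thr, val, cover, x, subset, right)
    ) / cover[node]


def _brute_shap(tree, x, n_features):
    cl, cr, feat, thr, val, cover = _tree_arrays(tree)
    phi = np.zeros(n_features)
    for i in range(n_features):
        others = [j for j in range(n_features) if j != i]
        for k in range(n_features):
            for subset in itertools.combinations(others, k):
                weight = (
                    math.factorial(k)
                    * math.factorial(n_features - k - 1)
                    / math.factorial(n_features)
                )
                s = set(subset)
                phi[i] += weight * (
                    _cond_exp(cl, cr, feat, thr, val, cover, x, s | {i})
                    - _cond_exp(cl, cr, feat, thr, val, cover, x, s)
                )
    return phi


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(120, 5))
    y = 2 * x[:, 0] - x[:, 1] + 0.5 * x[:, 0] * x[:, 2] + rng.normal(0, 0.1, 120)
    return x, y


def test_tree_shap_matches_brute_force(toy_data):
    x, y = toy_data
    tree = DecisionTreeRegressor(max_depth=4, random_state=0).fit(x, y)
    rows = x[:5]
    phi, base = tree_shap(tree, rows)
    for r in range(len(rows)):
        oracle = _brute_shap(tree, rows[r], 5)
        assert np.allclose(phi[r], oracle, atol=1e-9)
        assert base + phi[r].sum() == pytest.approx(tree.predict(rows[r : r + 1])[0], abs=1e-9)


def test_forest_shap_additivity(toy_data):
    x, y = toy_data
    rf = RandomForestRegressor(n_estimators=30, max_depth=6, random_state=0).fit(x, y)
    rows = x[:20]
    phi, base = tree_shap(rf, rows)
    resid = rf.predict(rows) - (base + phi.sum(axis=1))
    assert np.abs(resid).max() < 1e-6


# --------------------------------------------------------- linear explainer --


def test_linear_shap_identity(toy_data):
    x, y = toy_data
    model = Lasso(alpha=1e-3, max_iter=10_000).fit(x, y)
    bg = x[:50]
    phi, base = linear_shap(model.coef_, model.intercept_, x[50:60], bg)
    expected = model.coef_[None, :] * (x[50:60] - bg.mean(axis=0)[None, :])
    assert np.allclose(phi, expected)
    resid = model.predict(x[50:60]) - (base + phi.sum(axis=1))
    assert np.abs(resid).max() < 1e-10


def test_linear_shap_constant_feature_zero():
    w = np.array([1.0, 2.0])
    x = np.array([[3.0, 5.0], [3.0, 7.0]])  # feature 0 constant everywhere
    bg = np.array([[3.0, 1.0], [3.0, 2.0]])
    phi, _ = linear_shap(w, 0.0, x, bg)
    assert (phi[:, 0] == 0).all()


# ------------------------------------------------------- sampling explainer --


def test_permutation_shap_exact_additivity_and_convergence(toy_data):
    x, y = toy_data
    svr = SVR(kernel="rbf", C=10.0).fit(x, y)
    bg = x[:40]
    rows = x[100:105]
    phi, base = permutation_shap(svr.predict, rows, bg, n_permutations=4, seed=0)
    resid = svr.predict(rows) - (base + phi.sum(axis=1))
    assert np.abs(resid).max() < 1e-10  # additivity is exact by telescoping
    # on a *linear* model the permutation estimate converges to the closed form
    lin = Lasso(alpha=1e-4, max_iter=10_000).fit(x, y)
    phi_p, _ = permutation_shap(lin.predict, rows, bg, n_permutations=3, seed=1)
    phi_l, _ = linear_shap(lin.coef_, lin.intercept_, rows, bg)
    assert np.allclose(phi_p, phi_l, atol=1e-8)  # exact for additive models


def test_permutation_shap_empty_background():
    with pytest.raises(ValueError):
        permutation_shap(lambda a: a.sum(axis=1), np.ones((2, 3)), np.empty((0, 3)))


# ------------------------------------------------------ importance rankings --


def _matrix(values, feature_values=None, model="rf", scope=0):
    values = np.asarray(values, dtype=float)
    names = [f"f{j}" for j in range(values.shape[1])]
    fv = feature_values if feature_values is not None else np.zeros_like(values)
    return ShapMatrix(
        mode="nomothetic",
        model=model,
        scope=scope,
        base_value=0.0,
        values=values,
        feature_values=pd.DataFrame(fv, columns=names),
        feature_names=names,
    )


def test_importance_dominant_feature_ranks_first():
    sm = _matrix([[3.0, 0.0, 0.1], [-2.0, 0.0, 0.1]])
    ranks = importance_ranks(sm)
    assert ranks["f0"] == 1.0
    assert ranks["f1"] == 3.0


def test_importance_ties_share_rank():
    sm = _matrix([[1.0, 1.0, 0.2], [-1.0, -1.0, 0.1]])
    ranks = importance_ranks(sm)
    assert ranks["f0"] == ranks["f1"] == 1.0
    assert ranks["f2"] == 2.0  # dense ranking


def test_importance_permutation_invariance():
    values = np.array([[3.0, 1.0, 0.5], [2.0, -1.0, 0.2]])
    ranks = importance_ranks(_matrix(values))
    perm = [2, 0, 1]
    sm_p = _matrix(values[:, perm])
    ranks_p = importance_ranks(sm_p)
    for new_j, old_j in enumerate(perm):
        assert ranks_p[f"f{new_j}"] == ranks[f"f{old_j}"]


def test_median_rank_table_medians_and_order():
    feats = ["a", "b", "c"]
    rankings = {
        ("nomothetic", "lasso"): pd.Series([1.0, 2.0, 3.0], index=feats),
        ("nomothetic", "rf"): pd.Series([2.0, 1.0, 3.0], index=feats),
        ("idiographic", "rf"): pd.Series([9.0, 1.0, 2.0], index=feats),
    }
    table = median_rank_table(rankings, top_k=10)
    assert table.loc["a", "N-median"] == 1.5  # "double value" marks the tie
    assert table.loc["a", "I-median"] == 9.0
    assert list(table.index) == ["a", "b", "c"]  # ordered by N-median
    # three models ranking a feature 1, 2, 9 -> median 2
    assert median_ranks([r for r in rankings.values()])["a"] == 2.0


def test_median_rank_table_requires_both_modes():
    with pytest.raises(ValueError):
        median_rank_table({("nomothetic", "rf"): pd.Series([1.0], index=["a"])})


def test_beeswarm_export_shape_and_order():
    sm = _matrix([[3.0, 0.1], [2.0, -0.1], [1.0, 0.0]])
    out = beeswarm_export(sm)
    assert len(out) == 3 * 2  # n_obs * n_features rows
    assert list(out["feature"].unique()) == ["f0", "f1"]  # importance order
    assert (out.groupby("feature")["rank"].first().sort_values().index == ["f0", "f1"]).all()


def test_beeswarm_monotone_positive_feature():
    """A feature the model uses positively concentrates its high values at
    positive attributions."""
    rng = np.random.default_rng(0)
    fv = rng.uniform(0, 1, 100)
    sm = _matrix(
        np.c_[fv - fv.mean(), rng.normal(0, 1e-3, 100)], feature_values=np.c_[fv, fv]
    )
    out = beeswarm_export(sm)
    f0 = out[out["feature"] == "f0"]
    high = f0[f0["feature_value"] > 0.5]["shap_value"]
    low = f0[f0["feature_value"] <= 0.5]["shap_value"]
    assert high.mean() > 0 > low.mean()


# ------------------------------------------------------------ heterogeneity --


def test_heterogeneity_signs_and_conservation():
    rng = np.random.default_rng(0)
    n = 40
    mats = {}
    for pid, slope in [("up", 1.0), ("down", -1.0), ("flat", 0.0)]:
        fv = rng.uniform(0, 1, n)
        shap = slope * fv + (rng.normal(0, 1e-6, n) if slope == 0 else 0)
        mats[pid] = _matrix(
            np.c_[shap, np.zeros(n)], feature_values=np.c_[fv, np.full(n, 0.3)]
        )
    het, summary = feature_shap_heterogeneity(mats)
    het = het.set_index(["person_id", "feature"])
    assert het.loc[("up", "f0"), "sign"] == 1
    assert het.loc[("down", "f0"), "sign"] == -1
    assert het.loc[("flat", "f0"), "sign"] == 0
    # constant feature -> undefined, sign 0
    assert bool(het.loc[("up", "f1"), "undefined"]) is True
    assert het.loc[("up", "f1"), "sign"] == 0
    # proportions conserve: positive + negative + zero = 1 per feature
    s = summary.set_index("feature")
    for f in ("f0", "f1"):
        assert s.loc[f, ["prop_positive", "prop_negative", "prop_zero"]].sum() == pytest.approx(1.0)


def test_lasso_shap_sign_matches_coefficient_sign(demo_matrix):
    """For the linear model the feature-vs-attribution correlation sign
    equals the fitted coefficient's sign wherever it is nonzero (linear
    Shapley identity)."""
    from emastress.features import FEATURE_COLUMNS, minmax_fit_apply
    from emastress.modeling import FittedModelRecord, person_time_split, tune_and_fit
    from emastress.explain import compute_shap

    person = demo_matrix[demo_matrix["person_id"] == "p001"].reset_index(drop=True)
    tr, te = person_time_split(person)
    train, test = person.iloc[tr], person.iloc[te]
    [x_train, _], scaler = minmax_fit_apply(train, test, columns=list(FEATURE_COLUMNS))
    est, best = tune_and_fit(
        "lasso", x_train, train["stress_centered"].to_numpy(), grid={"alpha": [0.01]}
    )
    rec = FittedModelRecord(
        model_kind="lasso", mode="idiographic", scope="p001", estimator=est,
        scaler=scaler, best_params=best, search_type="grid", seed=0,
    )
    sm = compute_shap(rec, test, train, seed=0)
    het, _ = feature_shap_heterogeneity({"p001": sm})
    het = het.set_index("feature")
    for j, feat in enumerate(sm.feature_names):
        coef = est.coef_[j]
        if coef != 0 and not het.loc[feat, "undefined"] and het.loc[feat, "sign"] != 0:
            assert het.loc[feat, "sign"] == np.sign(coef)
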