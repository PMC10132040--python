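"""Shapley-value model explanations and across-person heterogeneity.

Three explainers, one per model family, all additive in the same sense:
``base_value + sum(contributions) = prediction`` for every explained row.

* **Linear** (LASSO): the closed form ``phi_i = w_i * (x_i - mean_i(bg))``
  over a background sample, exact.
* **Tree** (random forest): the path-dependent polynomial-time tree
  algorithm, which computes exact Shapley values of the tree's own
  cover-weighted conditional expectation; exact additivity against the
  forest prediction.
* **Sampling** (SVR and any black box): a permutation estimator over a
  fixed, seeded background; each sampled permutation telescopes, so
  additivity holds exactly even at small sample sizes and only the
  per-feature split is stochastic.

On top of the raw attributions: feature-importance rankings by mean
absolute contribution, cross-model median-rank tables, beeswarm-style
exports, and the per-person heterogeneity analysis that rank-correlates
feature values with their attributions for each idiographic model — the
sign pattern of those correlations across persons is the package's measure
of how person-specific a digital marker's relation to stress is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .evaluation import ALPHA, spearman_with_p
from .modeling import BASELINE, FittedModelRecord

# --------------------------------------------------------- tree explainer --


@njit(cache=False)
def _ts_recurse(cl, cr, feat, thr, val, cover, x, phi, node, pd_, pz_, po_, pw_, plen, pz, po, pi):
    # Path-dependent tree Shapley: maintain, along the root-to-leaf path,
    # the weights of all subset sizes for features that were split on, with
    # "cold" (z) and "hot" (o) fractions per feature. Each call copies and
    # extends the parent path, so sibling branches stay independent.
    d = np.empty(plen + 1, np.int64)
    z = np.empty(plen + 1, np.float64)
    o = np.empty(plen + 1, np.float64)
    w = np.empty(plen + 1, np.float64)
    for i in range(plen):
        d[i] = pd_[i]
        z[i] = pz_[i]
        o[i] = po_[i]
        w[i] = pw_[i]
    d[plen] = pi
    z[plen] = pz
    o[plen] = po
    w[plen] = 1.0 if plen == 0 else 0.0
    for i in range(plen - 1, -1, -1):
        w[i + 1] += po * w[i] * (i + 1.0) / (plen + 1.0)
        w[i] = pz * w[i] * (plen - i) / (plen + 1.0)
    length = plen + 1
    last = length - 1

    if cl[node] < 0:  # leaf: unwind each path feature to get its weight sum
        leaf_v = val[node]
        for i in range(1, length):
            if o[i] != 0.0:
                n_ = w[last]
                tot = 0.0
                for j in range(last - 1, -1, -1):
                    tmp = n_ * (last + 1.0) / ((j + 1.0) * o[i])
                    tot += tmp
                    n_ = w[j] - tmp * z[i] * (last - j) / (last + 1.0)
            else:
                tot = 0.0
                for j in range(last - 1, -1, -1):
                    tot += w[j] * (last + 1.0) / (z[i] * (last - j))
            phi[d[i]] += tot * (o[i] - z[i]) * leaf_v
        return

    fj = feat[node]
    if x[fj] <= thr[node]:
        hot, cold = cl[node], cr[node]
    else:
        hot, cold = cr[node], cl[node]
    iz = 1.0
    io = 1.0
    k = -1
    for i in range(1, length):  # previous split on the same feature?
        if d[i] == fj:
            k = i
            break
    if k >= 0:
        iz = z[k]
        io = o[k]
        ll = length - 1
        n_ = w[ll]
        for j in range(ll - 1, -1, -1):
            if io != 0.0:
                t = w[j]
                w[j] = n_ * (ll + 1.0) / ((j + 1.0) * io)
                n_ = t - w[j] * iz * (ll - j) / (ll + 1.0)
            else:
                w[j] = w[j] * (ll + 1.0) / (iz * (ll - j))
        for j in range(k, ll):
            d[j] = d[j + 1]
            z[j] = z[j + 1]
            o[j] = o[j + 1]
        length -= 1

    _ts_recurse(
        cl, cr, feat, thr, val, cover, x, phi, hot, d, z, o, w, length,
        iz * cover[hot] / cover[node], io, fj,
    )
    _ts_recurse(
        cl, cr, feat, thr, val, cover, x, phi, cold, d, z, o, w, length,
        iz * cover[cold] / cover[node], 0.0, fj,
    )


@njit(cache=False)
def _ts_tree(cl, cr, feat, thr, val, cover, X, phi):
    d0 = np.empty(0, np.int64)
    f0 = np.empty(0, np.float64)
    for r in range(X.shape[0]):
        _ts_recurse(
            cl, cr, feat, thr, val, cover, X[r], phi[r], 0, d0, f0, f0, f0, 0, 1.0, 1.0, -1
        )


def _tree_arrays(tree):
    t = tree.tree_
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        t.value.reshape(-1).astype(np.float64),
        t.weighted_n_node_samples.astype(np.float64),
    )


def tree_shap(estimator, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact path-dependent Shapley attributions for a decision tree or a
    random forest (attributions and base value average over trees)."""
    # sklearn trees predict on float32 inputs; mirror that cast so rows that
    # straddle a split threshold route to the same leaf as the estimator.
    X = np.ascontiguousarray(
        np.asarray(X, dtype=np.float32).astype(np.float64)
    )
    trees = getattr(estimator, "estimators_", [estimator])
    phi = np.zeros((X.shape[0], X.shape[1]))
    base = 0.0
    for tree in trees:
        cl, cr, feat, thr, val, cover = _tree_arrays(tree)
        p = np.zeros_like(phi)
        _ts_tree(cl, cr, feat, thr, val, cover, X, p)
        phi += p
        leaves = cl < 0
        base += float(np.sum(cover[leaves] * val[leaves]) / cover[0])
    return phi / len(trees), base / len(trees)


# ------------------------------------------------------- linear explainer --


def linear_shap(coef, intercept, X, background) -> tuple[np.ndarray, float]:
    """Closed-form Shapley values of a linear model over a background:
    ``phi_i = w_i * (x_i - mean_i(background))``."""
    coef = np.asarray(coef, dtype=float)
    X = np.asarray(X, dtype=float)
    mu = np.asarray(background, dtype=float).mean(axis=0)
    phi = coef[None, :] * (X - mu[None, :])
    base = float(intercept + coef @ mu)
    return phi, base


# ----------------------------------------------------- sampling explainer --


def permutation_shap(
    predict, X, background, n_permutations: int = 5, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley values for a black-box regressor.

    For each sampled feature ordering, features are switched one at a time
    from background values to the explained row's values and the marginal
    change in the mean prediction over the background is credited to the
    switched feature. Each ordering telescopes from the background mean to
    the row's prediction, so additivity is exact; more permutations only
    sharpen the per-feature split.
    """
    X = np.asarray(X, dtype=float)
    B = np.asarray(background, dtype=float)
    if len(B) == 0:
        raise ValueError("background must be non-empty")
    rng = np.random.default_rng(seed)
    n, m = X.shape
    nb = len(B)
    base = float(np.mean(predict(B)))
    phi = np.zeros((n, m))
    for r in range(n):
        x = X[r]
        for _ in range(n_permutations):
            perm = rng.permutation(m)
            big = np.repeat(B[None, :, :], m + 1, axis=0)  # step k: x on perm[:k]
            for k, i in enumerate(perm):
                big[k + 1 :, :, i] = x[i]
            preds = np.asarray(predict(big.reshape(-1, m))).reshape(m + 1, nb).mean(axis=1)
            phi[r, perm] += (preds[1:] - preds[:-1]) / n_permutations
    return phi, base


# ------------------------------------------------------------ shap matrix --

MAX_BACKGROUND = 100  # background rows for the linear/sampling explainers


@dataclass
class ShapMatrix:
    """Per-observation, per-feature additive attributions for one model,
    with the (scaled) feature values they align to."""

    mode: str
    model: str
    scope: object
    base_value: float
    values: np.ndarray  # (n_obs, n_features), stress-scale units
    feature_values: pd.DataFrame  # scaled features, same shape/order
    feature_names: list[str]

    def additivity_residual(self, predictions: np.ndarray) -> np.ndarray:
        return np.asarray(predictions, dtype=float) - (
            self.base_value + self.values.sum(axis=1)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "mode", self.mode)
        df.insert(1, "model", self.model)
        df.insert(2, "scope", str(self.scope))
        df.insert(3, "base_value", self.base_value)
        return df


def compute_shap(
    record: FittedModelRecord,
    rows: pd.DataFrame,
    background: pd.DataFrame | None = None,
    *,
    seed: int = 0,
    n_permutations: int = 5,
    max_background: int = MAX_BACKGROUND,
) -> ShapMatrix:
    """Shapley attributions for ``rows`` (raw, unscaled features) under one
    fitted model record.

    The record's own scaler transforms the rows, so attributions live on
    the model's input scale but in stress-scale output units. LASSO uses
    the closed linear form, random forests the exact tree algorithm, SVR
    the seeded permutation-sampling estimator; the latter two need a
    non-empty ``background`` (typically the record's training rows), which
    is subsampled to ``max_background`` rows with the given seed.
    """
    names = record.feature_names
    x = record.scaler.transform(rows[names]).to_numpy() if record.scaler else None
    kind = record.model_kind

    if kind == BASELINE:
        raise ValueError("the naive baseline has no feature attributions")

    if kind == "rf":
        phi, base = tree_shap(record.estimator, x)
    else:
        if background is None or len(background) == 0:
            raise ValueError(f"{kind} explanations need a non-empty background")
        bg = record.scaler.transform(background[names]).to_numpy()
        if len(bg) > max_background:
            idx = np.random.default_rng(seed).choice(len(bg), max_background, replace=False)
            bg = bg[idx]
        if kind == "lasso":
            phi, base = linear_shap(record.estimator.coef_, record.estimator.intercept_, x, bg)
        elif kind == "svr":
            phi, base = permutation_shap(
                record.estimator.predict, x, bg, n_permutations=n_permutations, seed=seed
            )
        else:
            raise ValueError(f"no explainer for model kind {kind!r}")

    return ShapMatrix(
        mode=record.mode,
        model=kind,
        scope=record.scope,
        base_value=base,
        values=phi,
        feature_values=pd.DataFrame(
            record.scaler.transform(rows[names]).to_numpy(), columns=names
        ),
        feature_names=list(names),
    )


# -------------------------------------------------- importance & rankings --


def importance_ranks(shap: ShapMatrix) -> pd.Series:
    """Features ranked by mean absolute attribution (rank 1 = most
    important; ties share a dense rank)."""
    if shap.values.shape[0] == 0:
        raise ValueError("cannot rank an empty attribution matrix")
    imp = pd.Series(np.abs(shap.values).mean(axis=0), index=shap.feature_names)
    return imp.rank(ascending=False, method="dense").astype(float)


def median_ranks(per_scope_ranks: list[pd.Series]) -> pd.Series:
    """Median rank per feature across scopes (per-person rankings for
    idiographic models)."""
    if not per_scope_ranks:
        raise ValueError("need at least one ranking")
    return pd.concat(per_scope_ranks, axis=1).median(axis=1)


def median_rank_table(rankings: dict[tuple[str, str], pd.Series], top_k: int = 10) -> pd.DataFrame:
    """Cross-model feature-rank table.

    ``rankings`` maps (mode, model) -> per-feature ranks (already
    median-aggregated over persons for idiographic models). Keeps features
    ranked in any model's top ``top_k``, adds N-median and I-median columns
    (median across nomothetic and idiographic models; .5 values mark ties),
    and orders rows by N-median.
    """
    n_cols = {k: v for k, v in rankings.items() if k[0] == "nomothetic"}
    i_cols = {k: v for k, v in rankings.items() if k[0] == "idiographic"}
    if not n_cols or not i_cols:
        raise ValueError("need at least one nomothetic and one idiographic ranking")
    table = pd.DataFrame({f"{m[0].upper()}-{k}": v for (m, k), v in rankings.items()})
    keep = (table <= top_k).any(axis=1)
    table = table[keep]
    table["N-median"] = table[[f"N-{k}" for (_, k) in n_cols]].median(axis=1)
    table["I-median"] = table[[f"I-{k}" for (_, k) in i_cols]].median(axis=1)
    return table.sort_values("N-median", kind="mergesort")


def beeswarm_export(shap: ShapMatrix) -> pd.DataFrame:
    """Long-format plot data: one row per (observation, feature) with the
    scaled feature value and its attribution, features ordered by
    importance."""
    ranks = importance_ranks(shap)
    frames = []
    for feat in ranks.sort_values().index:
        j = shap.feature_names.index(feat)
        frames.append(
            pd.DataFrame(
                {
                    "feature": feat,
                    "rank": ranks[feat],
                    "feature_value": shap.feature_values[feat].to_numpy(),
                    "shap_value": shap.values[:, j],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------- heterogeneity --


def feature_shap_heterogeneity(
    matrices: dict[object, ShapMatrix], alpha: float = ALPHA
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Across-person heterogeneity of feature-attribution relations.

    For each person and feature, the Spearman correlation between feature
    values and their attributions on that person's explained rows; the sign
    is +1/-1 when p < alpha and 0 otherwise (including constant features,
    which are flagged undefined). The summary gives, per feature, the
    proportion of persons with each sign (positive + negative + zero = 1).
    """
    rows = []
    for pid, sm in matrices.items():
        for j, feat in enumerate(sm.feature_names):
            x = sm.feature_values[feat].to_numpy()
            s = sm.values[:, j]
            undefined = len(x) < 3 or np.ptp(x) == 0 or np.ptp(s) == 0
            if undefined:
                rho, p, sign = float("nan"), float("nan"), 0
            else:
                rho, p = spearman_with_p(x, s)
                if np.isnan(rho) or p >= alpha:
                    sign = 0
                else:
                    sign = int(np.sign(rho))
            rows.append(
                {
                    "person_id": pid,
                    "model": sm.model,
                    "feature": feat,
                    "rho": rho,
                    "p_value": p,
                    "sign": sign,
                    "undefined": undefined,
                }
            )
    het = pd.DataFrame(rows)
    summary = (
        het.groupby(["model", "feature"])["sign"]
        .agg(
            prop_positive=lambda s: float((s == 1).mean()),
            prop_negative=lambda s: float((s == -1).mean()),
            prop_zero=lambda s: float((s == 0).mean()),
        )
        .reset_index()
    )
    return het, summary
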