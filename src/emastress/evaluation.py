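"""Person-by-person out-of-sample evaluation and the summary table.

Predictive accuracy is always judged per person: Spearman rank correlation
between a model's out-of-sample predictions and the person's self-reports
(significant when two-sided p < .05), and mean absolute error (MAE) against
the person's observed centered stress, compared with the naive baseline
that predicts the person's average stress. The summary aggregates these
per-person scores per model: median and range of rho, percent of persons
significant, median and range of MAE, percent of persons for whom the model
beats the baseline, and the share of persons for whom the model is the
single most accurate (MAE ties split credit equally so shares sum to 100).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .modeling import BASELINE

ALPHA = 0.05


def spearman_with_p(pred, obs) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and two-sided p.

    Constant inputs have no rank variance: rho and p come back NaN and the
    pair is counted nonsignificant downstream. Fewer than 3 pairs is an
    error.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs):
        raise ValueError("prediction and observation lengths differ")
    if len(pred) < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(pred, obs)
    return float(res.statistic), float(res.pvalue)


def mae(pred, obs) -> float:
    """Mean absolute error."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs) or len(pred) == 0:
        raise ValueError("need equal-length, non-empty vectors")
    return float(np.mean(np.abs(pred - obs)))


def evaluate_persons(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per (mode, model, person) accuracy scores.

    ``predictions`` is the tidy frame produced by the modeling drivers
    (person_id, prompt_time, mode, model, prediction, observed) and must
    include baseline rows. Returns one row per person per model with
    spearman_rho, p_value, mae, baseline_mae, significant (positive rho,
    p < .05), significant_negative, beats_baseline and rho_undefined.
    """
    rows = []
    for (mode, model, pid), grp in predictions.groupby(
        ["mode", "model", "person_id"], sort=True
    ):
        pred = grp["prediction"].to_numpy()
        obs = grp["observed"].to_numpy()
        if len(pred) >= 3:
            rho, p = spearman_with_p(pred, obs)
        else:
            rho, p = float("nan"), float("nan")
        rows.append(
            {
                "mode": mode,
                "model": model,
                "person_id": pid,
                "n_test": len(grp),
                "spearman_rho": rho,
                "p_value": p,
                "mae": mae(pred, obs),
            }
        )
    ev = pd.DataFrame(rows)

    base = ev[ev["model"] == BASELINE][["mode", "person_id", "mae"]].rename(
        columns={"mae": "baseline_mae"}
    )
    ev = ev.merge(base, on=["mode", "person_id"], how="left")
    sig = ev["p_value"] < ALPHA
    ev["significant"] = (sig & (ev["spearman_rho"] > 0)).fillna(False)
    ev["significant_negative"] = (sig & (ev["spearman_rho"] < 0)).fillna(False)
    ev["rho_undefined"] = ev["spearman_rho"].isna()
    ev["beats_baseline"] = ev["mae"] < ev["baseline_mae"]
    return ev


def _best_model_shares(ev: pd.DataFrame) -> pd.Series:
    """Per model, the percent of persons for whom it attains the lowest MAE
    (baseline included); t-way ties split 1/t so shares sum to 100."""
    share = {m: 0.0 for m in ev["model"].unique()}
    persons = ev["person_id"].unique()
    for pid in persons:
        sub = ev[ev["person_id"] == pid]
        lo = sub["mae"].min()
        winners = sub.loc[sub["mae"] <= lo + 1e-12, "model"]
        for m in winners:
            share[m] += 1.0 / len(winners)
    return pd.Series({m: 100.0 * v / len(persons) for m, v in share.items()})


def summarize(evaluations: pd.DataFrame) -> pd.DataFrame:
    """Per-model summary of person-wise accuracy, one frame row per
    (mode, model).

    Median rho excludes persons whose rho is undefined (constant
    predictions); those persons are tallied in ``n_rho_undefined``.
    ``pct_significant`` counts positive significant correlations only;
    negative significant persons are reported separately.
    """
    out = []
    for mode, ev in evaluations.groupby("mode", sort=True):
        shares = _best_model_shares(ev)
        for model, grp in ev.groupby("model", sort=True):
            rho = grp.loc[~grp["rho_undefined"], "spearman_rho"]
            is_base = model == BASELINE
            out.append(
                {
                    "mode": mode,
                    "model": model,
                    "n_persons": len(grp),
                    "median_rho": float("nan") if is_base else float(rho.median()),
                    "min_rho": float("nan") if is_base else float(rho.min()),
                    "max_rho": float("nan") if is_base else float(rho.max()),
                    "pct_significant": float("nan")
                    if is_base
                    else 100.0 * float(grp["significant"].mean()),
                    "pct_significant_negative": float("nan")
                    if is_base
                    else 100.0 * float(grp["significant_negative"].mean()),
                    "median_mae": float(grp["mae"].median()),
                    "min_mae": float(grp["mae"].min()),
                    "max_mae": float(grp["mae"].max()),
                    "pct_better_than_baseline": float("nan")
                    if is_base
                    else 100.0 * float(grp["beats_baseline"].mean()),
                    "pct_best_model": float(shares.get(model, 0.0)),
                    "n_rho_undefined": int(grp["rho_undefined"].sum()),
                }
            )
    return pd.DataFrame(out)


def render_table(summary: pd.DataFrame) -> str:
    """Plain-text rendering of the summary in the usual layout: one row per
    model, median (range) columns for rho and MAE, then the percent
    columns."""
    lines = [
        f"{'Model':<24}{'rho median (range)':<26}{'% sig':>7}"
        f"{'MAE median (range)':>26}{'> base %':>10}{'best %':>8}"
    ]
    for _, r in summary.iterrows():
        name = f"{r['mode'][0].upper()}-{r['model']}"
        if r["model"] == BASELINE:
            rho_s, sig_s, base_s = "N/A", "N/A", "N/A"
        else:
            rho_s = f"{r['median_rho']:.2f} ({r['min_rho']:.2f} to {r['max_rho']:.2f})"
            sig_s = f"{r['pct_significant']:.1f}"
            base_s = f"{r['pct_better_than_baseline']:.1f}"
        mae_s = f"{r['median_mae']:.2f} ({r['min_mae']:.2f} to {r['max_mae']:.2f})"
        lines.append(
            f"{name:<24}{rho_s:<26}{sig_s:>7}{mae_s:>26}{base_s:>10}"
            f"{r['pct_best_model']:>8.1f}"
        )
    return "\n".join(lines)
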