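"""End-to-end orchestration: generate -> ingest -> featurize -> split ->
fit -> evaluate -> explain, as one reproducible, seeded run.

A run is driven by a :class:`RunConfig` (YAML-serializable) and leaves a
directory of plain-text artifacts: the input tables, the feature matrix,
tidy out-of-sample predictions, the person-by-person evaluation, the
summary table, Shapley exports (importance table, beeswarm data,
heterogeneity summary), a daily-compliance series, and a manifest with
content hashes, seeds and library versions. Stages run in order; a failing
stage raises with its name while earlier artifacts stay on disk. Rerunning
with the same config and seed reproduces the evaluation artifacts
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import explain as ex
from . import features as ft
from . import modeling as md
from . import synthetic as sy
from .app_log import CategoryMap, load_events

log = logging.getLogger("emastress")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``synthetic`` is set (a cohort is generated) or ``events_path``
    and ``ema_path`` point at real input CSVs. Defaults mirror the emulated
    study design: 60-minute feature windows, 5 person-grouped folds,
    80/20 idiographic time splits, alpha = .05.
    """

    outdir: str = "emastress_run"
    seed: int = 0
    synthetic: sy.SyntheticConfig | None = None
    events_path: str | None = None
    ema_path: str | None = None
    category_map_path: str | None = None  # None -> shipped seed map
    lockdown_date: str | None = None  # None + synthetic -> from the generator
    window_minutes: int = 60
    k_folds: int = 5
    train_frac: float = 0.8
    min_obs: int = md.IDIOGRAPHIC_MIN_OBS
    mode: str = "both"  # nomothetic | idiographic | both
    model_kinds: tuple[str, ...] = md.MODEL_KINDS
    grids: dict | None = None  # per-kind grid overrides
    centering: str = "full"  # "full" | "train_only" (nomothetic leakage switch)
    explain_top_k: int = 10
    explain_max_rows: int = 200  # explained rows per scope (tree/linear)
    svr_explain_rows: int = 50  # explained rows per scope for the sampling explainer
    n_permutations: int = 5
    max_background: int = ex.MAX_BACKGROUND

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "effects" in syn:
                syn["effects"] = {
                    k: sy.Effect(**v) for k, v in syn["effects"].items()
                }
            raw["synthetic"] = sy.SyntheticConfig(**syn)
        if "model_kinds" in raw:
            raw["model_kinds"] = tuple(raw["model_kinds"])
        return cls(**raw)

    def validate(self) -> None:
        if self.synthetic is None and (self.events_path is None or self.ema_path is None):
            raise ValueError("need either a synthetic config or events_path + ema_path")
        if self.mode not in ("nomothetic", "idiographic", "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.centering not in ("full", "train_only"):
            raise ValueError(f"unknown centering {self.centering!r}")


# ------------------------------------------------------------- compliance --


def compliance_report(ema: pd.DataFrame, n_persons: int, prompts_per_day: int) -> pd.DataFrame:
    """Daily compliance: answered prompts on each study day as a percent of
    the prompts scheduled cohort-wide (n_persons x prompts_per_day)."""
    if prompts_per_day < 1:
        raise ValueError("prompts_per_day must be >= 1")
    denom = n_persons * prompts_per_day
    answered = ema.groupby(ema["prompt_time"].dt.normalize()).size()
    if len(answered) == 0:
        return pd.DataFrame(columns=["day", "n_answered", "n_scheduled", "compliance_pct"])
    days = pd.date_range(answered.index.min(), answered.index.max(), freq="D")
    answered = answered.reindex(days, fill_value=0)
    return pd.DataFrame(
        {
            "day": days,
            "n_answered": answered.to_numpy(),
            "n_scheduled": denom,
            "compliance_pct": 100.0 * answered.to_numpy() / denom,
        }
    )


# ---------------------------------------------------------------- stages --


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _load_inputs(cfg: RunConfig, outdir: Path):
    if cfg.synthetic is not None:
        syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        events, ema, truth = sy.generate_cohort(syn)
        sy.write_cohort(events, ema, truth, outdir / "inputs")
        lockdown = cfg.lockdown_date or syn.lockdown_date
        return events, ema, truth, lockdown, syn
    cmap = CategoryMap.from_yaml(cfg.category_map_path)
    events, report = load_events(cfg.events_path, cmap)
    log.info("loaded %d events (%d rejected)", report.n_kept, report.n_rejected)
    ema = ft.load_ema(cfg.ema_path)
    return events, ema, None, cfg.lockdown_date, None


def _featurize(cfg: RunConfig, events, ema, lockdown, outdir: Path) -> pd.DataFrame:
    matrix, report = ft.build_feature_matrix(
        events, ema, lockdown_date=lockdown, window_minutes=cfg.window_minutes
    )
    if report.dropped_persons:
        log.warning("dropped persons without any detected night: %s", report.dropped_persons)
    _write_csv(matrix, outdir / "features.csv")
    return matrix


def _fit(cfg: RunConfig, matrix: pd.DataFrame):
    results = {}
    if cfg.mode in ("nomothetic", "both"):
        m = matrix
        if cfg.centering == "train_only":
            # leakage-free variant: recentering happens inside each fold is
            # not possible post hoc for the outcome, so the switch recenters
            # on the first-80% rows per person before any fold sees data.
            m = matrix.copy()
            order = m.groupby("person_id")["prompt_time"].rank(method="first")
            n_per = m.groupby("person_id")["prompt_time"].transform("count")
            train_mask = order <= np.floor(cfg.train_frac * n_per)
            m["stress_centered"] = ft.center_within_person(
                m["stress_raw"], m["person_id"], train_mask=train_mask.to_numpy()
            )
        results["nomothetic"] = md.fit_nomothetic(
            m, cfg.model_kinds, k=cfg.k_folds, seed=cfg.seed, grids=cfg.grids
        )
    if cfg.mode in ("idiographic", "both"):
        results["idiographic"] = md.fit_idiographic(
            matrix,
            cfg.model_kinds,
            seed=cfg.seed,
            grids=cfg.grids,
            train_frac=cfg.train_frac,
            min_obs=cfg.min_obs,
        )
    return results


def _evaluate(results, outdir: Path):
    preds = pd.concat([r.predictions for r in results.values()], ignore_index=True)
    _write_csv(preds, outdir / "predictions.csv")
    evals = ev.evaluate_persons(preds)
    _write_csv(evals, outdir / "person_evaluation.csv")
    summary = ev.summarize(evals)
    _write_csv(summary, outdir / "summary.csv")
    (outdir / "summary.txt").write_text(ev.render_table(summary) + "\n")
    return preds, evals, summary


def _explain(cfg: RunConfig, matrix: pd.DataFrame, results, outdir: Path):
    rng = np.random.default_rng(cfg.seed)
    rankings: dict[tuple[str, str], pd.Series] = {}
    het_frames, het_sum_frames = [], []
    beeswarm_written = False

    for mode, res in results.items():
        per_kind_ranks: dict[str, list[pd.Series]] = {}
        per_kind_matrices: dict[str, dict] = {}
        for rec in res.records:
            if rec.model_kind == md.BASELINE:
                continue
            rows, background = _scope_rows(cfg, matrix, res, rec)
            if rows is None or len(rows) < 3:
                continue
            cap = cfg.svr_explain_rows if rec.model_kind == "svr" else cfg.explain_max_rows
            if len(rows) > cap:
                keep = np.sort(rng.choice(len(rows), cap, replace=False))
                rows = rows.iloc[keep]
            sm = ex.compute_shap(
                rec,
                rows,
                background,
                seed=cfg.seed,
                n_permutations=cfg.n_permutations,
                max_background=cfg.max_background,
            )
            per_kind_ranks.setdefault(rec.model_kind, []).append(ex.importance_ranks(sm))
            if mode == "idiographic":
                per_kind_matrices.setdefault(rec.model_kind, {})[rec.scope] = sm
            if mode == "nomothetic" and rec.model_kind == "rf" and not beeswarm_written:
                _write_csv(ex.beeswarm_export(sm), outdir / "beeswarm_nomothetic_rf.csv")
                beeswarm_written = True

        for kind, rank_list in per_kind_ranks.items():
            rankings[(mode, kind)] = ex.median_ranks(rank_list)
        for kind, mats in per_kind_matrices.items():
            het, het_sum = ex.feature_shap_heterogeneity(mats)
            het_frames.append(het)
            het_sum_frames.append(het_sum)

    have_n = any(m == "nomothetic" for m, _ in rankings)
    have_i = any(m == "idiographic" for m, _ in rankings)
    if have_n and have_i:
        table = ex.median_rank_table(rankings, top_k=cfg.explain_top_k)
        table.index.name = "feature"
        table.reset_index().to_csv(outdir / "importance_table.csv", index=False)
    if het_frames:
        _write_csv(pd.concat(het_frames, ignore_index=True), outdir / "heterogeneity.csv")
        _write_csv(
            pd.concat(het_sum_frames, ignore_index=True),
            outdir / "heterogeneity_summary.csv",
        )
    return rankings


def _scope_rows(cfg: RunConfig, matrix: pd.DataFrame, res, rec):
    """Held-out rows and training background for one fitted record."""
    if rec.mode == "nomothetic":
        folds = md.group_user_folds(matrix["person_id"], k=cfg.k_folds, seed=rec.seed)
        fold_of_row = matrix["person_id"].map(folds).to_numpy()
        rows = matrix[fold_of_row == rec.scope]
        background = matrix[fold_of_row != rec.scope]
        return rows, background
    obs = matrix[matrix["person_id"] == rec.scope].reset_index(drop=True)
    split = md.person_time_split(obs, train_frac=cfg.train_frac, min_obs=cfg.min_obs)
    if split is None:
        return None, None
    tr, te = split
    return obs.iloc[te], obs.iloc[tr]


def _manifest(outdir: Path, cfg: RunConfig, timings: dict) -> None:
    files = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(outdir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    import sklearn

    manifest = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "stochastic_stages": ["fit (rf, randomized search)", "explain (svr sampling)"],
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            out = fn(*args)
        except Exception as e:  # keep completed artifacts, name the stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        timings[name] = time.perf_counter() - t0
        log.info("stage %s done in %.2fs", name, timings[name])
        return out

    events, ema, truth, lockdown, syn = stage("ingest", _load_inputs, config, outdir)
    if lockdown is None:
        log.warning("no lockdown date given; the covid feature is 0 everywhere")
    matrix = stage("featurize", _featurize, config, events, ema, lockdown, outdir)
    if syn is not None:
        comp = compliance_report(ema, syn.n_persons, syn.prompts_per_day)
        _write_csv(comp, outdir / "compliance.csv")
    results = stage("fit", _fit, config, matrix)
    for mode, res in results.items():
        meta = [r.metadata() for r in res.records]
        (outdir / f"models_{mode}.json").write_text(json.dumps(meta, indent=1))
        if res.excluded_persons:
            log.info("%s: excluded persons below floor: %s", mode, res.excluded_persons)
    stage("evaluate", _evaluate, results, outdir)
    stage("explain", _explain, config, matrix, results, outdir)
    _manifest(outdir, config, timings)
    return outdir
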