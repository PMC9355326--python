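"""End-to-end orchestration: configuration handling, dataset generation,
feature extraction, screening, model fitting and the experiment summary.

Every stochastic element is seeded from one master seed through named
substreams, so an identical configuration reproduces identical outputs.
The experiment grid mirrors the study layout: estimator families x
{RGB, MS} image source x {with, without} shade variables, each evaluated
on a 3:1 modeling/test split.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import indices as vi
from . import models as md
from . import screen as sc
from . import synthscene as sy
from .errors import ConfigError, IOStageError

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {
        "n_per_level": 50,
        "sd_spad": 3.0,
        "noise_sd": 1.0,
        "shape": [96, 96],
        "render": True,
        "band_noise_cv": 0.20,
    },
    "segmentation": {"n_bins": 256},
    "indices": {"literature_formulas": False},
    "screening": {"alpha": 0.05, "k_folds": 10, "holm": False},
    "models": {
        "roster": ["olr", "lmm", "rf", "svr"],
        "rf_trees": 500,
        "svr_k_folds": 10,
        "svr_grid": "full",  # or "coarse" for desk-scale runs
    },
    "split": {"ratio": [3, 1], "stratified": False},
}

COARSE_SVR = {
    "c_grid": tuple(2.0 ** k for k in range(-1, 9, 2)),
    "gamma_grid": tuple(2.0 ** k for k in range(-7, 3, 2)),
    "epsilon_grid": (0.1, 0.5),
}


def merge_config(user: dict | None) -> dict:
    """Overlay a user configuration onto the defaults (one level deep)."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in (user or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def subseed(master: int, stream: str) -> int:
    """Stable per-purpose seed below 2^31 derived from the master seed."""
    import zlib

    return int(np.random.SeedSequence(
        [int(master), zlib.crc32(stream.encode())]).generate_state(1)[0]
        % (2 ** 31))


def shade_config(cfg: dict) -> sy.ShadeConfig:
    syn = cfg["synthetic"]
    sd = syn["sd_spad"]
    levels = tuple(syn.get("levels", sy.DEFAULT_SHADE_LEVELS))
    sds = tuple(sd for _ in levels) if np.isscalar(sd) else tuple(sd)
    return sy.ShadeConfig(
        levels=levels,
        mean_spad=tuple(syn.get("mean_spad", sy.DEFAULT_MEAN_SPAD)),
        sd_spad=sds,
        n_per_level=int(syn["n_per_level"]),
        illumination_scale=tuple(syn.get("illumination_scale",
                                         sy.DEFAULT_ILLUMINATION)))


def generate_dataset(cfg: dict, outdir: str | Path,
                     force: bool = False) -> dict:
    """Render the synthetic dataset to disk (scenes, records CSV, manifest)."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise IOStageError(f"output dir {outdir} is not empty (use force)")
    scfg = shade_config(cfg)
    seed = int(cfg["seed"])
    records = sy.sample_population(scfg, noise_sd=cfg["synthetic"]["noise_sd"],
                                   seed=subseed(seed, "population"))
    scenes = sy.render_population(records, sy.SpectralModel(), scfg,
                                  seed=subseed(seed, "scenes"),
                                  shape=tuple(cfg["synthetic"]["shape"]))
    manifest = sy.write_dataset(scenes, outdir)
    frame = sy.records_to_frame(records)
    for lvl, grp in frame.groupby("shade"):
        log.info("shade %.2f: n=%d, mean SPAD %.2f", lvl, len(grp),
                 grp["spad_measured"].mean())
    return manifest


def build_feature_table(cfg: dict, scenes=None) -> pd.DataFrame:
    """Feature table for the configured synthetic study.

    Renders scenes and runs segmentation + correction + indices when
    ``synthetic.render`` is true (or scenes are supplied); otherwise uses
    the analytic band-mean shortcut with canopy-scale noise.
    """
    scfg = shade_config(cfg)
    seed = int(cfg["seed"])
    lit = bool(cfg["indices"]["literature_formulas"])
    if scenes is None and cfg["synthetic"].get("render", True):
        records = sy.sample_population(
            scfg, noise_sd=cfg["synthetic"]["noise_sd"],
            seed=subseed(seed, "population"))
        scenes = sy.render_population(
            records, sy.SpectralModel(), scfg, seed=subseed(seed, "scenes"),
            shape=tuple(cfg["synthetic"]["shape"]))
    if scenes is not None:
        return vi.feature_table_from_scenes(
            scenes, n_bins=int(cfg["segmentation"]["n_bins"]),
            literature_formulas=lit)
    base = sy.simulate_feature_table(
        scfg, seed=subseed(seed, "population"),
        band_noise_cv=float(cfg["synthetic"].get("band_noise_cv", 0.20)),
        noise_sd=float(cfg["synthetic"]["noise_sd"]))
    return vi.feature_table_from_band_means(base, literature_formulas=lit)


def feature_columns(source: str) -> list[str]:
    names = vi.RGB_INDEX_NAMES if source == "rgb" else vi.MS_INDEX_NAMES
    return [f"{source}_{n}" for n in names]


def screen_source(table: pd.DataFrame, source: str, cfg: dict) -> sc.ScreenReport:
    """Screen one image source's indices on the given (modeling) rows."""
    scr = cfg["screening"]
    return sc.screen_features(
        table, feature_columns(source), y_col="spad_measured",
        alpha=float(scr["alpha"]), k_folds=int(scr["k_folds"]),
        seed=subseed(int(cfg["seed"]), f"lasso_{source}"),
        holm=bool(scr.get("holm", False)))


def _svr_grids(cfg: dict) -> dict:
    if cfg["models"].get("svr_grid") == "coarse":
        return dict(COARSE_SVR)
    return {}


def fit_family(family: str, X: pd.DataFrame, y: np.ndarray, shade,
               cfg: dict, with_shade: bool) -> md.ModelFitReport:
    seed = int(cfg["seed"])
    sh = list(shade) if with_shade else None
    if family == "olr":
        return md.fit_olr(X, y, shade=sh)
    if family == "lmm":
        groups = list(shade) if with_shade else [0.0] * len(y)
        return md.fit_lmm(X, groups, y)
    if family == "rf":
        return md.fit_rf(X, y, shade=sh,
                         n_trees=int(cfg["models"]["rf_trees"]),
                         seed=subseed(seed, f"rf_{with_shade}"))
    if family == "svr":
        return md.fit_svr(X, y, shade=sh, **_svr_grids(cfg),
                          k_folds=int(cfg["models"]["svr_k_folds"]),
                          seed=subseed(seed, f"svr_{with_shade}"))
    raise ConfigError(f"unknown model family {family!r}")


def run_experiment(cfg: dict | None = None, scenes=None,
                   outdir: str | Path | None = None) -> dict:
    """Execute the full study grid; returns artifacts keyed by stage.

    Stages: feature extraction -> per-source screening -> model fits over
    family x source x shade-mode -> metric summary. With ``outdir`` the
    feature table, screen reports, model reports, predictions and the
    summary CSV are written.
    """
    cfg = merge_config(cfg)
    table = build_feature_table(cfg, scenes=scenes)
    seed = int(cfg["seed"])

    plan = ev.split(table["id"].tolist(), ratio=tuple(cfg["split"]["ratio"]),
                    seed=subseed(seed, "split"),
                    stratify_by=(table["shade"].tolist()
                                 if cfg["split"]["stratified"] else None))
    is_model = table["id"].isin(plan.modeling_ids)

    screens: dict[str, sc.ScreenReport] = {}
    rows = []
    predictions = []
    reports: dict[tuple, md.ModelFitReport] = {}
    for source in ("rgb", "ms"):
        rep = screen_source(table[is_model], source, cfg)
        screens[source] = rep
        feats = rep.retained
        sub = table.dropna(subset=feats)
        n_drop = len(table) - len(sub)
        if n_drop:
            log.info("%s: dropped %d record(s) with invalid retained indices",
                     source, n_drop)
        mrows = sub[sub["id"].isin(plan.modeling_ids)]
        trows = sub[sub["id"].isin(plan.test_ids)]
        for family in cfg["models"]["roster"]:
            for with_shade in (False, True):
                fit = fit_family(family, mrows[feats],
                                 mrows["spad_measured"].to_numpy(),
                                 mrows["shade"].tolist(), cfg, with_shade)
                for split_name, part in (("modeling", mrows), ("test", trows)):
                    pred = fit.predict(part[feats],
                                       part["shade"].tolist()
                                       if with_shade or family == "lmm"
                                       else None)
                    fit.metrics[split_name] = ev.metrics(
                        part["spad_measured"].to_numpy(), pred)
                    predictions.append(pd.DataFrame({
                        "id": part["id"], "y_true": part["spad_measured"],
                        "y_pred": pred, "split": split_name,
                        "family": family, "source": source,
                        "shade_mode": "with" if with_shade else "without"}))
                reports[(family, source, with_shade)] = fit
                r2m, rmsem, mapem = fit.metrics["modeling"]
                r2t, rmset, mapet = fit.metrics["test"]
                rows.append({"family": family, "source": source,
                             "shade_mode": "with" if with_shade else "without",
                             "r2_modeling": r2m, "rmse_modeling": rmsem,
                             "mape_modeling": mapem, "r2_test": r2t,
                             "rmse_test": rmset, "mape_test": mapet})
    summary = pd.DataFrame(rows)

    artifacts = {"config": cfg, "features": table, "split": plan,
                 "screens": screens, "reports": reports, "summary": summary,
                 "predictions": pd.concat(predictions, ignore_index=True)}
    if outdir is not None:
        _write_artifacts(artifacts, Path(outdir))
    return artifacts


def _write_artifacts(art: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    art["features"].to_csv(outdir / "features.csv", index=False)
    for source, rep in art["screens"].items():
        rep.to_json(outdir / f"screen_{source}.json")
        rep.path_frame().to_csv(outdir / f"lasso_path_{source}.csv",
                                index=False)
    model_dump = {f"{fam}_{src}_{'with' if ws else 'without'}_shade":
                  fit.to_json_dict()
                  for (fam, src, ws), fit in art["reports"].items()}
    (outdir / "models.json").write_text(json.dumps(model_dump, indent=2,
                                                   sort_keys=True))
    art["predictions"].to_csv(outdir / "predictions.csv", index=False)
    summary = art["summary"].copy()
    for c in summary.columns:
        if c.startswith(("r2", "rmse")):
            summary[c] = summary[c].map(lambda v: ev.round_half_up(v, 4))
        elif c.startswith("mape"):
            summary[c] = summary[c].map(lambda v: ev.round_half_up(v, 2))
    summary.to_csv(outdir / "summary.csv", index=False)
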