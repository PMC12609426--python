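"""Per-(DOY, stratum) regressor fleet: training, registry, fallback, prediction.

For every requested day-of-year and sub-biome stratum a regressor is fitted
on the 16-day moving-window pool, with hyperparameters chosen by k-fold
cross-validation (mean R^2). Three algorithm families compete — gradient-
boosted trees, random forest, and a feed-forward network — and the winner
can be picked automatically from cross-validation scores on a sample of
pools. Pools at or below the minimum sample size are recorded as skipped; at
prediction time a skipped or missing key resolves to the same-stratum model
at the minimal circular DOY distance (ties toward the earlier DOY) and, past
a configurable search horizon, to the per-DOY universal model trained on the
combined window data of all strata.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .evaluate import EvalMetrics, regression_metrics
from .grids import GridGeometry, Raster
from .preprocess import FEATURE_COLUMNS
from .sampling import (
    UNIVERSAL,
    ModelKey,
    SamplerAudit,
    apply_sampling_rules,
    collect_window_samples,
    split_train_val,
)
from .stratify import ALL_STRATA, StratumMap
from .synthetic import doy_365

__all__ = [
    "ALGORITHMS",
    "DEFAULT_PARAM_GRIDS",
    "RegistryConfig",
    "FittedModel",
    "ModelRegistry",
    "train_model_cv",
    "select_algorithm",
    "train_registry",
    "resolve_model",
    "predict_rows",
    "predict_grid",
    "SifGrid",
    "circular_doy_distance",
]

ALGORITHMS = ("gbt", "rf", "nn")

DEFAULT_PARAM_GRIDS: dict[str, list[dict]] = {
    "gbt": [
        {"max_iter": 300, "learning_rate": 0.1, "max_leaf_nodes": 31},
        {"max_iter": 150, "learning_rate": 0.1, "max_leaf_nodes": 15},
    ],
    "rf": [
        {"n_estimators": 200, "min_samples_leaf": 1},
        {"n_estimators": 100, "min_samples_leaf": 5},
    ],
    "nn": [
        {"hidden_layer_sizes": (64, 64), "alpha": 1e-4},
        {"hidden_layer_sizes": (32,), "alpha": 1e-3},
    ],
}


def _build_nn(params: dict, seed: int):
    params = dict(params)
    hls = params.pop("hidden_layer_sizes", (64, 64))
    params.setdefault("max_iter", 800)
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("mlp", MLPRegressor(hidden_layer_sizes=tuple(hls), random_state=seed, **params)),
        ]
    )


class MultiStartRegressor:
    """Best-of-restarts wrapper: network training is non-convex, so the fit
    is repeated from ``n_restarts`` seeded initializations and the restart
    with the best training R^2 is kept (ties keep the earliest). The whole
    procedure is deterministic for a fixed seed."""

    def __init__(self, params: dict, seed: int, n_restarts: int):
        self.params = params
        self.seed = int(seed)
        self.n_restarts = int(n_restarts)
        self.best_ = None

    def fit(self, X, y):
        best_score = -np.inf
        for i in range(self.n_restarts):
            est = _build_nn(self.params, self.seed + i)
            est.fit(X, y)
            score = r2_score(y, est.predict(X))
            if score > best_score:
                best_score, self.best_ = score, est
        return self

    def predict(self, X):
        if self.best_ is None:
            raise RuntimeError("MultiStartRegressor is not fitted")
        return self.best_.predict(X)


def make_estimator(algorithm: str, params: dict, seed: int):
    """Estimator factory for the three candidate families."""
    if algorithm == "gbt":
        return HistGradientBoostingRegressor(random_state=seed, **params)
    if algorithm == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if algorithm == "nn":
        params = dict(params)
        n_restarts = int(params.pop("n_restarts", 1))
        if n_restarts > 1:
            return MultiStartRegressor(params, seed=seed, n_restarts=n_restarts)
        return _build_nn(params, seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass(frozen=True)
class RegistryConfig:
    """Training configuration for the model fleet."""

    algorithm: str = "auto"  # 'auto' | 'gbt' | 'rf' | 'nn'
    candidates: tuple[str, ...] = ALGORITHMS
    param_grid: list[dict] | None = None  # None -> DEFAULT_PARAM_GRIDS[algorithm]
    folds: int = 5
    cap: int = 5000
    min_n: int = 1000
    split_ratio: float | None = 0.7  # per-key internal split; None -> train on full pool
    seed: int = 0
    doys: tuple[int, ...] = ()
    strata: tuple[int, ...] = ALL_STRATA
    fallback_horizon: int = 182  # max circular DOY distance for nearest-date fallback
    selection_pools: int = 3  # pools sampled for automatic algorithm selection

    def grid_for(self, algorithm: str) -> list[dict]:
        return self.param_grid if self.param_grid is not None else DEFAULT_PARAM_GRIDS[algorithm]


@dataclass
class FittedModel:
    """One fitted regressor with its identity and selection metadata."""

    key: ModelKey
    algorithm: str
    params: dict
    cv_score: float
    n_train: int
    estimator: object
    train_metrics: dict | None = None
    val_metrics: dict | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(features, dtype=float)))

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        return self.predict(table[FEATURE_COLUMNS].to_numpy(float))


def _key_seed(seed: int, key: ModelKey) -> int:
    scode = 0 if key.stratum == UNIVERSAL else int(key.stratum)
    return int(np.random.SeedSequence((seed, key.doy, scode)).generate_state(1)[0] % (2**31))


def train_model_cv(
    table: pd.DataFrame,
    algorithm: str,
    param_grid: list[dict] | None = None,
    folds: int = 5,
    seed: int = 0,
    key: ModelKey | None = None,
) -> FittedModel:
    """Grid search over the hyperparameter configurations scored by mean
    k-fold CV R^2; the best configuration (ties to the first listed) is refit
    on the full table. Deterministic for a fixed seed."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    grid = param_grid if param_grid is not None else DEFAULT_PARAM_GRIDS[algorithm]
    if not grid:
        raise ValueError("empty parameter grid")
    X = table[FEATURE_COLUMNS].to_numpy(float)
    y = table["sif_smoothed"].to_numpy(float)
    if np.var(y) == 0.0:
        raise ValueError("degenerate target: zero variance")

    best_score, best_params = -np.inf, None
    if len(grid) == 1:
        # single candidate: CV still scores it for the record
        folds_eff = min(folds, len(y))
        scores = _cv_scores(X, y, algorithm, grid[0], folds_eff, seed)
        best_score, best_params = float(np.mean(scores)), grid[0]
    else:
        for params in grid:
            scores = _cv_scores(X, y, algorithm, params, min(folds, len(y)), seed)
            score = float(np.mean(scores))
            if score > best_score:  # strict: ties keep the earlier configuration
                best_score, best_params = score, params

    est = make_estimator(algorithm, best_params, seed)
    est.fit(X, y)
    fm = FittedModel(
        key=key if key is not None else ModelKey(1, UNIVERSAL),
        algorithm=algorithm,
        params=dict(best_params),
        cv_score=best_score,
        n_train=len(y),
        estimator=est,
    )
    pred = fm.predict(X)
    fm.train_metrics = regression_metrics(pred, y).as_dict()
    return fm


def _cv_scores(X, y, algorithm, params, folds, seed):
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in kf.split(X):
        est = make_estimator(algorithm, params, seed)
        est.fit(X[tr], y[tr])
        scores.append(r2_score(y[te], est.predict(X[te])))
    return scores


def select_algorithm(
    tables: list[pd.DataFrame],
    candidates: tuple[str, ...] = ALGORITHMS,
    param_grids: dict[str, list[dict]] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[str, pd.DataFrame]:
    """Pick the algorithm with the best mean CV score over sample pools.

    Every candidate is tuned with :func:`train_model_cv` on each table; the
    candidate with the highest mean selected-configuration CV R^2 wins, ties
    broken by the declared candidate order. Returns (tag, comparison table).
    """
    if not candidates:
        raise ValueError("need at least one candidate algorithm")
    if not tables:
        raise ValueError("need at least one sample pool")
    rows = []
    means = {}
    for tag in candidates:
        grid = param_grids.get(tag) if param_grids else None
        scores = []
        for i, tbl in enumerate(tables):
            fm = train_model_cv(tbl, tag, param_grid=grid, folds=folds, seed=seed)
            scores.append(fm.cv_score)
            rows.append({"algorithm": tag, "pool": i, "cv_r2": fm.cv_score, "n": len(tbl)})
        means[tag] = float(np.mean(scores))
    best = max(candidates, key=lambda t: means[t])  # max keeps the first on ties
    report = pd.DataFrame(rows)
    report["selected"] = report["algorithm"] == best
    return best, report


# ---------------------------------------------------------------------------
# registry


@dataclass
class ModelRegistry:
    """Store of fitted models, skip markers and provenance."""

    algorithm: str
    config: RegistryConfig
    models: dict[ModelKey, FittedModel] = field(default_factory=dict)
    skips: set[ModelKey] = field(default_factory=set)
    gaps: set[int] = field(default_factory=set)  # DOYs whose universal pool was too small
    audit: SamplerAudit = field(default_factory=SamplerAudit)
    selection_report: pd.DataFrame | None = None

    def add(self, fm: FittedModel) -> None:
        if fm.key in self.skips:
            raise ValueError(f"key {fm.key} already marked skipped")
        self.models[fm.key] = fm

    def mark_skip(self, key: ModelKey) -> None:
        if key in self.models:
            raise ValueError(f"key {key} already has a model")
        self.skips.add(key)

    def keys_for_stratum(self, stratum) -> list[ModelKey]:
        return [k for k in self.models if k.stratum == stratum]

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        (path / "blobs").mkdir(parents=True, exist_ok=True)
        entries = []
        for key in sorted(self.models, key=lambda k: (k.doy, str(k.stratum))):
            fm = self.models[key]
            blob = f"blobs/doy{key.doy:03d}_{key.stratum}.joblib"
            joblib.dump(fm.estimator, path / blob)
            entries.append(
                {
                    "doy": key.doy,
                    "stratum": key.stratum,
                    "algorithm": fm.algorithm,
                    "params": fm.params,
                    "cv_score": fm.cv_score,
                    "n_train": fm.n_train,
                    "train_metrics": fm.train_metrics,
                    "val_metrics": fm.val_metrics,
                    "blob": blob,
                }
            )
        manifest = {
            "algorithm": self.algorithm,
            "config": _config_dict(self.config),
            "models": entries,
            "skips": sorted([k.doy, k.stratum] for k in self.skips),
            "gaps": sorted(self.gaps),
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        self.audit.to_frame().to_csv(path / "audit.csv", index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ModelRegistry":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        cfgd = dict(manifest["config"])
        cfgd["candidates"] = tuple(cfgd["candidates"])
        cfgd["doys"] = tuple(cfgd["doys"])
        cfgd["strata"] = tuple(cfgd["strata"])
        reg = cls(algorithm=manifest["algorithm"], config=RegistryConfig(**cfgd))
        for e in manifest["models"]:
            key = ModelKey(e["doy"], e["stratum"])
            reg.models[key] = FittedModel(
                key=key,
                algorithm=e["algorithm"],
                params=e["params"],
                cv_score=e["cv_score"],
                n_train=e["n_train"],
                estimator=joblib.load(path / e["blob"]),
                train_metrics=e["train_metrics"],
                val_metrics=e["val_metrics"],
            )
        reg.skips = {ModelKey(d, s) for d, s in manifest["skips"]}
        reg.gaps = set(manifest["gaps"])
        return reg


def _config_dict(cfg: RegistryConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["candidates"] = list(cfg.candidates)
    d["doys"] = list(cfg.doys)
    d["strata"] = list(cfg.strata)
    return d


def train_registry(
    table: pd.DataFrame,
    config: RegistryConfig,
    doys: tuple[int, ...] | None = None,
    strata: tuple[int, ...] | None = None,
) -> ModelRegistry:
    """Train the fleet: per requested DOY, up to 19 stratum models plus one
    universal model on the combined window data; skip markers where the
    minimum-sample rule fails, a DOY-level gap where even the universal pool
    is too small."""
    doys = tuple(doys if doys is not None else config.doys)
    strata = tuple(strata if strata is not None else config.strata)
    if not doys:
        raise ValueError("no DOYs requested")

    algorithm = config.algorithm
    selection_report = None
    if algorithm == "auto":
        algorithm, selection_report = _auto_select(table, config, doys, strata)

    reg = ModelRegistry(algorithm=algorithm, config=config)
    reg.selection_report = selection_report

    for doy in doys:
        for stratum in (*strata, UNIVERSAL):
            key = ModelKey(doy, stratum)
            pool = collect_window_samples(table, key)
            kseed = _key_seed(config.seed, key)
            sub = apply_sampling_rules(pool, cap=config.cap, min_n=config.min_n, seed=kseed)
            if sub is None:
                if stratum == UNIVERSAL:
                    reg.gaps.add(doy)
                else:
                    reg.mark_skip(key)
                reg.audit.add(key, n_found=len(pool), n_used=0, skipped=True)
                continue
            if config.split_ratio is not None:
                train, val = split_train_val(sub, ratio=config.split_ratio, seed=kseed)
            else:
                train, val = sub, None
            fm = train_model_cv(
                train,
                algorithm,
                param_grid=config.grid_for(algorithm),
                folds=config.folds,
                seed=kseed,
                key=key,
            )
            if val is not None and len(val) >= 2 and val["sif_smoothed"].var() > 0:
                fm.val_metrics = regression_metrics(
                    fm.predict_table(val), val["sif_smoothed"].to_numpy(float)
                ).as_dict()
            reg.add(fm)
            reg.audit.add(key, n_found=len(pool), n_used=len(sub), skipped=False)
    return reg


def _auto_select(table, config, doys, strata):
    """Representative pools (largest first) feed the algorithm bake-off."""
    pools = []
    for doy in doys:
        for stratum in strata:
            key = ModelKey(doy, stratum)
            pool = collect_window_samples(table, key)
            if len(pool) > config.min_n:
                pools.append((len(pool), str(key), pool))
    if not pools:
        raise ValueError("no pool exceeds min_n; cannot select an algorithm")
    pools.sort(key=lambda t: (-t[0], t[1]))
    sample = [
        apply_sampling_rules(p, cap=config.cap, min_n=config.min_n, seed=config.seed)
        for _, _, p in pools[: config.selection_pools]
    ]
    grids = {tag: config.grid_for(tag) for tag in config.candidates}
    return select_algorithm(
        sample, candidates=config.candidates, param_grids=grids,
        folds=config.folds, seed=config.seed,
    )


# ---------------------------------------------------------------------------
# fallback resolution and prediction


def circular_doy_distance(a: int, b: int) -> int:
    d = abs(a - b) % 365
    return min(d, 365 - d)


def _nearest_key(keys: list[ModelKey], doy: int, horizon: int) -> ModelKey | None:
    """Minimal circular-DOY-distance key; ties resolved toward the key that
    precedes the query on the DOY circle."""
    best = None
    for k in keys:
        d = circular_doy_distance(k.doy, doy)
        if d > horizon:
            continue
        precedes = (doy - k.doy) % 365 <= 182  # k is on or before the query
        rank = (d, 0 if precedes else 1, k.doy)
        if best is None or rank < best[0]:
            best = (rank, k)
    return None if best is None else best[1]


def resolve_model(
    registry: ModelRegistry,
    doy: int,
    stratum,
    horizon: int | None = None,
    with_key: bool = False,
):
    """Resolve (doy, stratum) to a fitted model.

    Order: exact key; same-stratum model at minimal circular DOY distance
    within the horizon (ties toward the earlier DOY); the per-DOY universal
    model (exact, then nearest). Raises ``KeyError`` naming the key when
    nothing resolves.
    """
    if horizon is None:
        horizon = registry.config.fallback_horizon
    chain = [stratum] if stratum == UNIVERSAL else [stratum, UNIVERSAL]
    for strat in chain:
        exact = ModelKey(doy, strat)
        if exact in registry.models:
            return (registry.models[exact], exact) if with_key else registry.models[exact]
        near = _nearest_key(registry.keys_for_stratum(strat), doy, horizon)
        if near is not None:
            return (registry.models[near], near) if with_key else registry.models[near]
    raise KeyError(f"no model resolvable for doy={doy}, stratum={stratum}")


def predict_rows(registry: ModelRegistry, table: pd.DataFrame) -> np.ndarray:
    """Predict each labeled row with its resolved (doy, stratum) model."""
    out = np.full(len(table), np.nan)
    pos = {idx: i for i, idx in enumerate(table.index)}
    for (doy, stratum), grp in table.groupby(["doy", "stratum"]):
        fm = resolve_model(registry, int(doy), int(stratum))
        pred = fm.predict_table(grp)
        out[[pos[i] for i in grp.index]] = pred
    return out


@dataclass
class SifGrid:
    """Predicted daily SIF raster with nodata mask and per-cell provenance
    (which model key produced each cell; stratum -1 encodes universal)."""

    values: np.ndarray
    geom: GridGeometry
    date: dt.date
    source_doy: np.ndarray
    source_stratum: np.ndarray

    units = "W m-2 um-1 sr-1"

    def mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def to_raster(self) -> Raster:
        return Raster(values=self.values, geom=self.geom, nodata=-9999.0)


def predict_grid(
    registry: ModelRegistry,
    reflectance: Raster,
    strata: StratumMap,
    date: dt.date,
    horizon: int | None = None,
) -> SifGrid:
    """Gridded daily prediction: per vegetated cell, the cell's 7 bands go
    through the resolved (DOY, stratum) model; other cells are nodata."""
    if reflectance.geom != strata.geom:
        raise ValueError(
            f"raster geometry mismatch: reflectance {reflectance.geom} vs strata {strata.geom}"
        )
    if reflectance.values.ndim != 3 or reflectance.values.shape[0] != len(FEATURE_COLUMNS):
        raise ValueError("reflectance raster must have 7 bands")
    doy = doy_365(date)
    ids = strata.model_ids
    values = np.full(ids.shape, np.nan)
    src_doy = np.full(ids.shape, -1, dtype=int)
    src_strat = np.full(ids.shape, 0, dtype=int)

    for s in np.unique(ids):
        if s == 0:
            continue
        fm, key = resolve_model(registry, doy, int(s), horizon=horizon, with_key=True)
        sel = ids == s
        feats = reflectance.values[:, sel].T  # (ncells, 7)
        values[sel] = fm.predict(feats)
        src_doy[sel] = key.doy
        src_strat[sel] = -1 if key.stratum == UNIVERSAL else int(key.stratum)

    return SifGrid(
        values=values, geom=reflectance.geom, date=date,
        source_doy=src_doy, source_stratum=src_strat,
    )
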