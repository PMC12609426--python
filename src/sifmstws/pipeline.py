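"""End-to-end orchestration: simulate -> preprocess -> stratify -> train ->
predict -> evaluate (-> cross-sensor), with artifact-based stage caching.

Every run is a pure function of (config, seed): the configuration
serializes to YAML, its hash is stamped into the run manifest, and rerunning
an unchanged config skips stages whose artifacts already exist. Deleting a
mid-stage artifact regenerates that stage and everything downstream, never
upstream.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import io as tio
from .grids import Raster, read_raster, write_raster
from .models import (
    ModelRegistry,
    RegistryConfig,
    predict_grid,
    train_registry,
)
from .preprocess import (
    build_training_table,
    combine_bands,
    knn_smooth,
    match_reflectance,
    qc_filter,
)
from .sampling import doy_window
from .stratify import ALL_STRATA, BiomeGrid, StratumMap, assign_model_ids
from .synthetic import (
    SyntheticWorld,
    WorldConfig,
    doy_365,
    generate_world,
    sample_footprints,
    simulate_airborne,
    simulate_reflectance,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "stratify", "train", "predict", "evaluate", "cross-sensor")


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration; every random operation derives its seed
    from ``seed``. Serializes to a single YAML file whose hash is logged."""

    world: WorldConfig = field(default_factory=WorldConfig)
    out_dir: str = "pipeline_out"
    seed: int = 0
    qc_allowed: tuple[int, ...] = (0,)
    knn_k: int = 5
    knn_max_radius: float = 0.1
    refl_radius: float = 0.03
    cap: int = 5000
    min_n: int = 1000
    split_ratio: float = 0.7
    folds: int = 5
    algorithm: str = "gbt"
    candidates: tuple[str, ...] = ("gbt", "rf", "nn")
    param_grid: tuple | None = None
    fallback_horizon: int = 182
    doys: tuple[int, ...] = (200,)
    strata: tuple[int, ...] = ALL_STRATA
    predict_dates: tuple[str, ...] = ("2022-07-19",)
    airborne_region: tuple[float, float, float, float] | None = None

    def registry_config(self) -> RegistryConfig:
        return RegistryConfig(
            algorithm=self.algorithm,
            candidates=self.candidates,
            param_grid=list(self.param_grid) if self.param_grid else None,
            folds=self.folds,
            cap=self.cap,
            min_n=self.min_n,
            split_ratio=self.split_ratio,
            seed=self.seed,
            doys=self.doys,
            strata=self.strata,
            fallback_horizon=self.fallback_horizon,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # normalize tuples -> lists

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        wd = d.pop("world")
        for key in ("years", "a0_range", "a1_range"):
            wd[key] = tuple(wd[key])
        if isinstance(wd.get("sigma_band"), dict):
            wd["sigma_band"] = {int(k): float(v) for k, v in wd["sigma_band"].items()}
        world = WorldConfig(**wd)
        for key in ("qc_allowed", "candidates", "doys", "strata", "predict_dates"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("param_grid") is not None:
            d["param_grid"] = tuple(d["param_grid"])
        if d.get("airborne_region") is not None:
            d["airborne_region"] = tuple(d["airborne_region"])
        return cls(world=world, **d)

    def hash(self) -> str:
        """Hash of the scientific configuration (the output path is not
        part of the run's identity)."""
        d = self.to_dict()
        d.pop("out_dir")
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]

    def needed_dates(self) -> list[dt.date]:
        """All calendar dates whose DOY falls in some requested window."""
        wanted = set()
        for doy in self.doys:
            wanted.update(doy_window(doy))
        return [d for d in self.world.date_range() if doy_365(d) in wanted]


@dataclass
class PipelineResult:
    out_dir: Path
    config_hash: str
    stages_run: list[str]
    artifacts: dict[str, object]


def _stage_artifacts(cfg: PipelineConfig, out: Path) -> dict[str, list[Path]]:
    predict_files = []
    for ds in cfg.predict_dates:
        predict_files += [out / f"predict/sif_{ds}.asc", out / f"predict/sif_{ds}_src.json"]
    return {
        "simulate": [out / "footprints.csv", out / "biome.asc", out / "region.asc"],
        "preprocess": [out / "processed.csv"],
        "stratify": [out / "stratum_map.asc"],
        "train": [out / "training_table.csv", out / "registry/manifest.json",
                  out / "sampler_audit.csv"],
        "predict": predict_files,
        "evaluate": [out / "metrics.csv", out / "summary.txt"],
        "cross-sensor": [out / "cross_sensor_pairs.csv", out / "cross_sensor_metrics.csv"],
    }


def run_pipeline(
    config: PipelineConfig, force: bool = False, through: str = "cross-sensor"
) -> PipelineResult:
    """Execute the pipeline up to stage ``through``; see module docstring."""
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; stages are {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    config.to_yaml(out / "config.yaml")

    manifest_path = out / "run_manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") != chash:
            force = True
    artifacts = _stage_artifacts(config, out)
    world = generate_world(config.world, config.seed)
    refl = lambda date: simulate_reflectance(world, date)  # noqa: E731

    stages_run: list[str] = []
    ran_upstream = force
    results: dict[str, object] = {"world": world}
    n_through = STAGES.index(through)

    for stage in STAGES[: n_through + 1]:
        missing = any(not p.exists() for p in artifacts[stage])
        if not (ran_upstream or missing):
            continue
        ran_upstream = True
        stages_run.append(stage)
        try:
            _run_stage(stage, config, world, refl, out, results)
        except Exception as exc:  # surface the failing stage
            raise RuntimeError(f"pipeline stage '{stage}' failed (inputs under {out})") from exc

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "artifacts": {s: [str(p) for p in ps] for s, ps in artifacts.items()},
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(out_dir=out, config_hash=chash, stages_run=stages_run, artifacts=results)


def _run_stage(stage, config, world, refl, out, results):
    if stage == "simulate":
        frames = [
            sample_footprints(world, d, seed=config.seed) for d in config.needed_dates()
        ]
        fps = pd.concat(frames, ignore_index=True)
        tio.write_footprint_table(fps, out / "footprints.csv")
        write_raster(out / "biome", Raster(world.biome.classes.astype(float), world.geom))
        write_raster(out / "region", Raster(world.region.astype(float), world.geom))

    elif stage == "preprocess":
        fps, rejected = tio.read_footprint_table(out / "footprints.csv")
        fps = qc_filter(fps, config.qc_allowed)
        fps = fps.assign(sif_daily=combine_bands(fps["sif_757"], fps["sif_771"]))
        smoothed, _ = knn_smooth(fps, k=config.knn_k, max_radius=config.knn_max_radius)
        matched, _ = match_reflectance(smoothed, refl, radius=config.refl_radius)
        matched = matched.copy()
        matched["date"] = pd.to_datetime(matched["date"]).dt.strftime("%Y-%m-%d")
        matched.to_csv(out / "processed.csv", index=False, float_format="%.10g")

    elif stage == "stratify":
        biome = read_raster(out / "biome.asc")
        region = read_raster(out / "region.asc")
        bg = BiomeGrid(classes=biome.values.astype(int), geom=biome.geom)
        smap = assign_model_ids(bg, regions=region.values.astype(int))
        write_raster(out / "stratum_map", smap.to_raster())
        results["strata"] = smap

    elif stage == "train":
        strat = read_raster(out / "stratum_map.asc")
        smap = StratumMap(model_ids=np.nan_to_num(strat.values).astype(int), geom=strat.geom)
        processed = pd.read_csv(out / "processed.csv", parse_dates=["date"])
        table = build_training_table(processed, smap)
        table.to_csv(out / "training_table.csv", index=False, float_format="%.10g")
        registry = train_registry(table, config=config.registry_config())
        registry.save(out / "registry")
        registry.audit.write(out / "sampler_audit.csv")
        results["registry"] = registry
        results["training_table"] = table

    elif stage == "predict":
        registry = results.get("registry") or ModelRegistry.load(out / "registry")
        results["registry"] = registry
        strat = read_raster(out / "stratum_map.asc")
        smap = StratumMap(model_ids=np.nan_to_num(strat.values).astype(int), geom=strat.geom)
        (out / "predict").mkdir(exist_ok=True)
        grids = {}
        for ds in config.predict_dates:
            date = dt.date.fromisoformat(ds)
            grid = predict_grid(registry, refl(date), smap, date)
            write_raster(out / f"predict/sif_{ds}", grid.to_raster())
            (out / f"predict/sif_{ds}_src.json").write_text(
                json.dumps(
                    {
                        "units": grid.units,
                        "source_doy": grid.source_doy.tolist(),
                        "source_stratum": grid.source_stratum.tolist(),
                    }
                )
            )
            grids[date] = grid
        results["grids"] = grids

    elif stage == "evaluate":
        registry = results.get("registry") or ModelRegistry.load(out / "registry")
        results["registry"] = registry
        rows = []
        for key in sorted(registry.models, key=lambda k: (k.doy, str(k.stratum))):
            fm = registry.models[key]
            rec = {"doy": key.doy, "stratum": key.stratum, "algorithm": fm.algorithm,
                   "cv_r2": fm.cv_score, "n_train": fm.n_train}
            for scope, m in (("train", fm.train_metrics), ("val", fm.val_metrics)):
                for name in ("r2", "rmse", "slope", "n"):
                    rec[f"{scope}_{name}"] = (m or {}).get(name, np.nan)
            rows.append(rec)
        metrics = pd.DataFrame(rows)
        metrics.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
        lines = [
            f"config_hash: {config.hash()}",
            f"models: {len(registry.models)}  skipped: {len(registry.skips)}  "
            f"doy_gaps: {sorted(registry.gaps)}",
        ]
        if len(metrics):
            lines.append(
                f"median validation R2: {np.nanmedian(metrics['val_r2']):.4f}  "
                f"median validation RMSE: {np.nanmedian(metrics['val_rmse']):.4f}"
            )
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
        results["metrics"] = metrics

    elif stage == "cross-sensor":
        registry = results.get("registry") or ModelRegistry.load(out / "registry")
        strat = read_raster(out / "stratum_map.asc")
        smap = StratumMap(model_ids=np.nan_to_num(strat.values).astype(int), geom=strat.geom)
        region = config.airborne_region or (
            world.geom.lat_min, world.geom.lat_max, world.geom.lon_min, world.geom.lon_max
        )
        grids, air = {}, []
        for ds in config.predict_dates:
            date = dt.date.fromisoformat(ds)
            grids[date] = predict_grid(registry, refl(date), smap, date)
            air.append(simulate_airborne(world, region, date, seed=config.seed))
        metrics, paired = ev.cross_sensor_validate(
            grids, pd.concat(air, ignore_index=True), scale=config.world.airborne_scale
        )
        paired.to_csv(out / "cross_sensor_pairs.csv", index=False, float_format="%.10g")
        pd.DataFrame([metrics.as_dict()]).to_csv(
            out / "cross_sensor_metrics.csv", index=False, float_format="%.10g"
        )
        results["cross_sensor"] = metrics
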