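"""Configuration and the five-stage analysis pipeline.

Stages run in canonical order — ``simulate`` → ``features`` →
``classify`` → ``model`` → ``map`` — each reading its inputs from the
output directory (or from the in-memory results of earlier stages in the
same run) and writing its artifacts there.  A JSON manifest records
every artifact with a content hash, the root seed and the package
version, so a rerun with the same configuration can be verified
bit-for-bit on the deterministic stages.

All randomness derives from one root seed, split per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely import wkt as shapely_wkt

from . import __version__
from . import allometry, classify, features, mapping, models, synthetic
from .raster import Raster, read_multiband, read_raster, write_multiband, write_raster

log = logging.getLogger("mangrovecarbon")

STAGES = ("simulate", "features", "classify", "model", "map")

DEFAULT_FRACTIONS = {
    "A_marina": 0.28,
    "R_stylosa": 0.16,
    "A_corniculatum": 0.12,
    "B_gymnorrhiza": 0.09,
    "soil": 0.15,
    "water": 0.14,
    "shadow": 0.06,
}


@dataclass
class PipelineConfig:
    """All knobs of the synthetic study, schema-validated before running."""

    out_dir: str = "mangrove_run"
    seed: int = 0
    extent: tuple[int, int] = (200, 200)  # pixels (rows, cols)
    pixel_size: float = synthetic.DEFAULT_PIXEL_SIZE  # m
    patch_scale: float = 8.0  # px, patchiness of the species mosaic
    species_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    spectral_sd: float = 0.010  # per-band reflectance noise
    n_plots_per_species: int = 10
    plot_side: float = 5.0  # m
    n_gcps: int = 60
    idw_pixel_sizes: tuple[float, ...] = (3.5,)
    idw_powers: tuple[float, ...] = (1.0, 2.0, 3.0)
    idw_n_points: tuple[int, ...] = (3, 5)
    glcm_window: int = 3
    glcm_levels: int = 64
    combinations: tuple[str, ...] = tuple(classify.DEFAULT_COMBINATIONS)
    map_combination: str = "V15"
    max_pixels_per_class: int = 600
    train_fraction: float = 0.7
    vif_detect: float = 10.0
    vif_accept: float = 3.0
    p_threshold: float = 0.05
    max_terms: int = 3
    soil_carbon: dict = field(default_factory=lambda: dict(mapping.DEFAULT_SOIL_CARBON))
    transect_step_m: float = 2.0

    def validate(self) -> None:
        if self.extent[0] < 20 or self.extent[1] < 20:
            raise ValueError("extent too small to hold field plots")
        for name in ("pixel_size", "patch_scale", "plot_side", "p_threshold",
                     "vif_detect", "vif_accept", "transect_step_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.species_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("species_fractions must sum to 1")
        unknown = [c for c in self.combinations
                   if c not in classify.DEFAULT_COMBINATIONS]
        if unknown:
            raise ValueError(f"unknown combinations {unknown}")
        if self.map_combination not in self.combinations:
            raise ValueError("map_combination must be among combinations")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("extent", "idw_pixel_sizes", "idw_powers", "idw_n_points",
                    "combinations"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key, cast in (("extent", int), ("idw_pixel_sizes", float),
                          ("idw_powers", float), ("idw_n_points", int),
                          ("combinations", str)):
            if key in kwargs:
                kwargs[key] = tuple(cast(v) for v in kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(root_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([root_seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % 2**31)


class PipelineRun:
    """Executes stages against one output directory, tracking artifacts."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.artifacts: list[Path] = []
        self.state: dict = {}

    # ---------------- helpers

    def _record(self, *paths: Path) -> None:
        self.artifacts.extend(paths)

    def _need(self, stage: str, path: Path) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs missing input {path}; run the "
                "upstream stage first"
            )
        return path

    # ---------------- stages

    def simulate(self) -> None:
        cfg = self.config
        seed = _stage_seed(cfg.seed, "simulate")
        sigs = synthetic.default_signatures(cfg.spectral_sd)
        species_map = synthetic.generate_species_map(
            cfg.extent, cfg.species_fractions, cfg.patch_scale, seed,
            pixel_size=cfg.pixel_size,
        )
        scene = synthetic.generate_scene(species_map, sigs, noise_seed=seed + 1)
        plots = synthetic.sample_plots(
            scene, sigs, n_per_species=cfg.n_plots_per_species,
            plot_side=cfg.plot_side, seed=seed + 2,
        )
        write_multiband(self.out / "scene_bands.tif", dict(scene.bands))
        write_raster(self.out / "dsm.tif", scene.dsm)
        write_raster(self.out / "dtm_true.tif", scene.dtm_true)
        write_raster(self.out / "species_true.tif", scene.species_true)
        trees, plot_tbl = synthetic.plots_to_tables(plots)
        trees.to_csv(self.out / "trees.csv", index=False)
        plot_tbl.to_csv(self.out / "plots.csv", index=False)
        (self.out / "scene_meta.json").write_text(json.dumps(
            dict(seed=seed, pixel_size=cfg.pixel_size,
                 class_order=list(synthetic.CLASS_ORDER)), indent=1) + "\n")
        self._record(
            self.out / "scene_bands.tif", self.out / "dsm.tif",
            self.out / "dtm_true.tif", self.out / "species_true.tif",
            self.out / "trees.csv", self.out / "plots.csv",
            self.out / "scene_meta.json",
        )
        self.state.update(scene=scene, plots=plots)
        log.info("simulate: %d×%d scene, %d plots", *cfg.extent, len(plots))

    def _load_scene(self, stage: str = "features") -> synthetic.Scene:
        if "scene" in self.state:
            return self.state["scene"]
        bands = read_multiband(self._need(stage, self.out / "scene_bands.tif"))
        scene = synthetic.Scene(
            bands=bands,
            dsm=read_raster(self.out / "dsm.tif"),
            dtm_true=read_raster(self.out / "dtm_true.tif"),
            species_true=read_raster(self.out / "species_true.tif"),
            pixel_size=bands["B"].pixel_size,
        )
        self.state["scene"] = scene
        return scene

    def _load_plots(self) -> list[synthetic.PlotRecord]:
        if "plots" in self.state:
            return self.state["plots"]
        df = pd.read_csv(self._need("model", self.out / "plots.csv"))
        plots = [
            synthetic.PlotRecord(
                plot_id=row.plot_id, species_id=row.species,
                polygon=shapely_wkt.loads(row.wkt), trees=[],
                agc=row.agc_t_hm2, bgc=row.bgc_t_hm2,
            )
            for row in df.itertuples()
        ]
        self.state["plots"] = plots
        return plots

    def features(self) -> None:
        cfg = self.config
        seed = _stage_seed(cfg.seed, "features")
        scene = self._load_scene()
        # emulate the survey: GCPs sampled on the true terrain, IDW-selected DTM
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, scene.shape[0], cfg.n_gcps)
        cols = rng.integers(0, scene.shape[1], cfg.n_gcps)
        x, y = scene.dtm_true.transform.xy(rows, cols)
        gcps = features.GCPTable(pd.DataFrame(dict(
            x=x, y=y, z=scene.dtm_true.values[rows, cols],
        )).drop_duplicates(subset=["x", "y"]))
        best, rmse_table = features.select_idw_params(
            gcps, cfg.idw_pixel_sizes, cfg.idw_powers, cfg.idw_n_points,
        )
        rmse_table.to_csv(self.out / "idw_rmse.csv", index=False)
        xs, ys = scene.dtm_true.pixel_centers()
        z = features.idw_at_points(
            gcps, np.column_stack([xs.ravel(), ys.ravel()]),
            best["power"], best["n_points"],
        )
        dtm = scene.dtm_true.like(z.reshape(scene.shape))
        stack = features.build_feature_stack(
            scene, dtm=dtm, glcm_window=cfg.glcm_window,
            glcm_levels=cfg.glcm_levels,
        )
        write_raster(self.out / "dtm_idw.tif", dtm)
        write_multiband(self.out / "feature_stack.tif", stack.layers)
        (self.out / "idw_params.json").write_text(json.dumps(best, indent=1) + "\n")
        self._record(self.out / "idw_rmse.csv", self.out / "dtm_idw.tif",
                     self.out / "feature_stack.tif", self.out / "idw_params.json")
        self.state["stack"] = stack
        log.info("features: %d layers, IDW params %s", len(stack.names), best)

    def _load_stack(self, stage: str = "classify") -> features.FeatureStack:
        if "stack" in self.state:
            return self.state["stack"]
        layers = read_multiband(self._need(stage, self.out / "feature_stack.tif"))
        stack = features.FeatureStack(layers)
        self.state["stack"] = stack
        return stack

    def classify(self) -> None:
        cfg = self.config
        seed = _stage_seed(cfg.seed, "classify")
        scene = self._load_scene(stage="classify")
        stack = self._load_stack(stage="classify")
        table = classify.labeled_pixel_table(
            stack, scene.species_true,
            max_per_class=cfg.max_pixels_per_class, seed=seed,
        )
        combos = [classify.DEFAULT_COMBINATIONS[c] for c in cfg.combinations]
        names = {float(k): n for k, n in enumerate(synthetic.CLASS_ORDER)}
        ranking = classify.evaluate_combinations(
            table, combos, seed=seed, train_fraction=cfg.train_fraction,
            class_names=names,
        )
        ranking.to_csv(self.out / "combination_ranking.csv", index=False)
        train, _ = classify.split_samples(table, cfg.train_fraction, seed)
        model = classify.fit_mlc(
            train, classify.DEFAULT_COMBINATIONS[cfg.map_combination]
        )
        label_raster = classify.classify(model, stack)
        write_raster(self.out / "species_classified.tif", label_raster)
        (self.out / "class_legend.json").write_text(json.dumps(
            {str(float(k)): n for k, n in enumerate(synthetic.CLASS_ORDER)},
            indent=1) + "\n")
        self._record(self.out / "combination_ranking.csv",
                     self.out / "species_classified.tif",
                     self.out / "class_legend.json")
        self.state["classified"] = label_raster
        log.info("classify: best OA %.4f (%s)", ranking.OA.iloc[0],
                 ranking.combination.iloc[0])

    def model(self) -> None:
        cfg = self.config
        stack = self._load_stack(stage="model")
        plots = self._load_plots()
        plot_table = features.aggregate_to_plots(stack, plots)
        plot_table.to_csv(self.out / "plot_features.csv", index=False)
        registry, report = models.select_models(
            plot_table,
            vif_detect=cfg.vif_detect, vif_accept=cfg.vif_accept,
            p_threshold=cfg.p_threshold, max_terms=cfg.max_terms,
        )
        registry.to_file(self.out / "carbon_models.json")
        report.to_csv(self.out / "model_candidates.csv", index=False)
        self._record(self.out / "plot_features.csv",
                     self.out / "carbon_models.json",
                     self.out / "model_candidates.csv")
        self.state["registry"] = registry
        log.info("model: %d models selected", len(registry.models))

    def map(self) -> None:
        cfg = self.config
        stack = self._load_stack(stage="map")
        if "registry" in self.state:
            registry = self.state["registry"]
        else:
            registry = models.ModelRegistry.from_file(
                self._need("map", self.out / "carbon_models.json")
            )
        if "classified" in self.state:
            classified = self.state["classified"]
        else:
            classified = read_raster(
                self._need("map", self.out / "species_classified.tif")
            )
        maps = mapping.apply_models(classified, stack, registry, cfg.soil_carbon)
        write_raster(self.out / "agc.tif", maps.agc)
        write_raster(self.out / "bgc.tif", maps.bgc)
        write_raster(self.out / "tgc.tif", maps.tgc)
        summary, _ = mapping.species_summary(maps, classified)
        summary.to_csv(self.out / "species_summary.csv", index=False)
        # two standard transects: main diagonal and mid-height horizontal
        tr = classified.transform
        rows_n, cols_n = classified.shape
        x0, y0 = tr.xy(0, 0)
        x1, y1 = tr.xy(rows_n - 1, cols_n - 1)
        xm, ym = tr.xy(rows_n // 2, 0)
        _, ym2 = tr.xy(rows_n // 2, cols_n - 1)
        transects = {
            "A": [(float(x0), float(y0)), (float(x1), float(y1))],
            "B": [(float(xm), float(ym)), (float(x1), float(ym2))],
        }
        frames = []
        for name, line in transects.items():
            for resp, raster in (("agc", maps.agc), ("bgc", maps.bgc),
                                 ("tgc", maps.tgc)):
                prof = mapping.transect_profile(raster, line, cfg.transect_step_m)
                prof["transect"] = name
                prof["layer"] = resp
                frames.append(prof)
        pd.concat(frames).to_csv(self.out / "transects.csv", index=False)
        (self.out / "clamp_count.json").write_text(
            json.dumps(dict(clamp_count=maps.clamp_count)) + "\n")
        self._record(self.out / "agc.tif", self.out / "bgc.tif",
                     self.out / "tgc.tif", self.out / "species_summary.csv",
                     self.out / "transects.csv", self.out / "clamp_count.json")
        self.state["maps"] = maps
        self.state["summary"] = summary
        log.info("map: clamped %d negative predictions", maps.clamp_count)


def run_pipeline(
    config: PipelineConfig, stages=STAGES, manifest_name: str = "manifest.json"
) -> dict:
    """Run the requested stages in canonical order; write and return the manifest."""
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages {bad}")
    run = PipelineRun(config)
    for stage in STAGES:
        if stage in stages:
            getattr(run, stage)()
    manifest = dict(
        version=__version__,
        seed=config.seed,
        stages=[s for s in STAGES if s in stages],
        config=config.to_dict(),
        artifacts={
            str(p.relative_to(run.out)): _sha256(p) for p in run.artifacts
        },
    )
    (run.out / manifest_name).write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
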