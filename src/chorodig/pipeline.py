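"""Stage orchestration: configuration, artifacts and run manifests.

Each stage reads its upstream artifacts from the output directory, writes
its own, and records a JSON manifest (inputs, parameters, seed, package
version, wall time) so every artifact is reproducible from its manifest.
Stages: simulate, georef, segment, train, classify, cleanup, zonal,
demography, compare, all.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (ClassifiedMap, TrainingSet, load_model, predict_classes,
                       save_model, train_classifier)
from .cleanup import CleanupParams, OverrideList, absorb_black_objects, apply_overrides
from .demography import (CalibrationSpec, calibrate_free_class,
                         compare_estimates, summarize_states)
from .geo import (Affine, read_gcps, read_labels, read_raster, read_zones,
                  warp_image, write_labels, write_raster,
                  fit_polynomial_transform)
from .legend import Legend, deer_density_legend
from .segmentation import SegmentationParams, SegmentMap, multiresolution_segment
from .synth import (SyntheticMapSpec, evaluate_recovery, make_synthetic_map,
                    sample_training_set, GroundTruth)
from .threshold import color_threshold_segment
from .zonal import ZonalParams, ZonalTable, assign_majority, zonal_class_areas

log = logging.getLogger(__name__)

STAGES = ("simulate", "georef", "segment", "train", "classify", "cleanup",
          "zonal", "demography", "compare", "all")


class MissingArtifactError(FileNotFoundError):
    """An upstream artifact is absent; the message names the stage to run."""


class ArtifactExistsError(FileExistsError):
    """Stage outputs already exist and overwrite was not requested."""


@dataclass
class RunConfig:
    """All paths and stage parameters of a digitization run.

    Built from a YAML config file and/or keyword overrides; command-line
    flags win over file values.
    """

    out_dir: Path = Path("chorodig_run")
    image: Path | None = None
    gcps: Path | None = None
    zones: Path | None = None
    legend: Path | None = None
    training: Path | None = None
    overrides: Path | None = None
    reported: Path | None = None

    backend: str = "obia"  # or "color-threshold"
    seed: int = 0
    scale: float = 10.0
    band_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    connectivity: int = 4
    tolerance: float = 30.0
    train_fraction: float = 0.1
    n_trees: int = 500
    black_max_channel: int = 60
    small_object_max_px: int = 5
    max_absorption_passes: int = 100
    majority_margin: float = 25.0
    min_coverage: float = 0.25
    target_total: float | None = None
    free_class: int | None = None
    georef_order: int = 3
    overwrite: bool = False
    synth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.backend not in ("obia", "color-threshold"):
            raise ValueError(f"unknown backend {self.backend!r}")
        for name in ("out_dir", "image", "gcps", "zones", "legend", "training",
                     "overrides", "reported"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    # ------------------------------------------------------------- artifacts
    def path(self, name: str) -> Path:
        return self.out_dir / name

    def load_legend(self) -> Legend:
        if self.legend and self.legend.exists():
            return Legend.from_json(self.legend)
        if self.path("legend.json").exists():
            return Legend.from_json(self.path("legend.json"))
        return deer_density_legend()


def _require(cfg: RunConfig, name: str, producer: str) -> Path:
    p = cfg.path(name)
    if not p.exists():
        raise MissingArtifactError(
            f"missing artifact {name!r}; run stage {producer!r} first")
    return p


def _fresh(cfg: RunConfig, name: str) -> Path:
    p = cfg.path(name)
    if p.exists() and not cfg.overwrite:
        raise ArtifactExistsError(
            f"{p} exists; pass overwrite=True / --overwrite to replace it")
    return p


def _manifest(cfg: RunConfig, stage: str, inputs: list[str], outputs: list[str],
              params: dict[str, Any], t0: float) -> None:
    payload = {
        "stage": stage,
        "inputs": inputs,
        "outputs": outputs,
        "parameters": params,
        "seed": cfg.seed,
        "version": __version__,
        "wall_time_s": round(time.time() - t0, 3),
    }
    cfg.path(f"manifest_{stage}.json").write_text(json.dumps(payload, indent=2))


def save_classified(cmap: ClassifiedMap, cfg: RunConfig, prefix: str) -> list[str]:
    write_labels(cmap.classes, cmap.transform, cfg.path(f"{prefix}_classes.tif"),
                 cmap.crs)
    write_labels(cmap.labels, cmap.transform, cfg.path(f"{prefix}_labels.tif"),
                 cmap.crs)
    df = pd.DataFrame({"class_id": cmap.object_classes,
                       "provenance": cmap.provenance})
    df.index.name = "object_id"
    df.to_csv(cfg.path(f"{prefix}_objects.csv"))
    return [f"{prefix}_classes.tif", f"{prefix}_labels.tif", f"{prefix}_objects.csv"]


def load_classified(cfg: RunConfig, prefix: str, nodata_class: int) -> ClassifiedMap:
    classes, transform, crs = read_labels(cfg.path(f"{prefix}_classes.tif"))
    labels, _, _ = read_labels(cfg.path(f"{prefix}_labels.tif"))
    df = pd.read_csv(cfg.path(f"{prefix}_objects.csv"), index_col="object_id")
    return ClassifiedMap(classes.astype(np.int16), labels, df["class_id"],
                         df["provenance"], transform, crs, nodata_class)


# ----------------------------------------------------------------- stages
def stage_simulate(cfg: RunConfig) -> list[str]:
    t0 = time.time()
    spec = SyntheticMapSpec(seed=cfg.seed, **cfg.synth)
    img, gt, zones = make_synthetic_map(spec)
    _fresh(cfg, "image.tif")
    write_raster(img, cfg.path("image.tif"))
    from .geo import write_vector

    write_vector(zones, cfg.path("zones.geojson"))
    spec.legend.to_json(cfg.path("legend.json"))
    write_labels(gt.classes, gt.transform, cfg.path("truth_classes.tif"), gt.crs)
    write_labels(gt.rendered, gt.transform, cfg.path("truth_rendered.tif"), gt.crs)
    write_labels(gt.unit_raster, gt.transform, cfg.path("truth_units.tif"), gt.crs)
    gt.unit_classes.rename("class_id").to_csv(cfg.path("truth_unit_classes.csv"))
    outputs = ["image.tif", "zones.geojson", "legend.json", "truth_classes.tif",
               "truth_rendered.tif", "truth_units.tif", "truth_unit_classes.csv"]
    _manifest(cfg, "simulate", [], outputs, {"synth": {**cfg.synth}}, t0)
    return outputs


def stage_georef(cfg: RunConfig) -> list[str]:
    t0 = time.time()
    if cfg.image is None or not cfg.image.exists():
        raise MissingArtifactError("georef needs an input image (config: image)")
    if cfg.gcps is None or not cfg.gcps.exists():
        raise MissingArtifactError("georef needs a GCP table (config: gcps)")
    img = read_raster(cfg.image)
    gcps = read_gcps(cfg.gcps)
    t = fit_polynomial_transform(gcps, cfg.georef_order)
    # output grid: bounding box of transformed corners, square pixels at the
    # mean GCP-implied scale rounded to whole meters
    corners_c = [0, img.width, 0, img.width]
    corners_r = [0, 0, img.height, img.height]
    X, Y = t.forward(np.asarray(corners_c, float), np.asarray(corners_r, float))
    span = max((X.max() - X.min()) / img.width, (Y.max() - Y.min()) / img.height)
    res = max(1.0, round(span))
    w = int(np.ceil((X.max() - X.min()) / res))
    h = int(np.ceil((Y.max() - Y.min()) / res))
    grid = Affine.from_origin(float(X.min()), float(Y.max()), res, res)
    out = warp_image(img, t, grid, (h, w))
    _fresh(cfg, "georeferenced.tif")
    write_raster(out, cfg.path("georeferenced.tif"))
    _manifest(cfg, "georef", [str(cfg.image), str(cfg.gcps)],
              ["georeferenced.tif"],
              {"order": cfg.georef_order, "rms_residual": t.rms_residual,
               "resolution": res}, t0)
    return ["georeferenced.tif"]


def _input_image(cfg: RunConfig):
    for name in ("georeferenced.tif", "image.tif"):
        if cfg.path(name).exists():
            return read_raster(cfg.path(name)), name
    if cfg.image is not None and cfg.image.exists():
        return read_raster(cfg.image), str(cfg.image)
    raise MissingArtifactError(
        "no input image found; run stage 'simulate' or 'georef' first, or set "
        "config key 'image'")


def stage_segment(cfg: RunConfig) -> list[str]:
    t0 = time.time()
    img, src = _input_image(cfg)
    params = SegmentationParams(cfg.scale, tuple(cfg.band_weights),
                                cfg.connectivity)
    seg = multiresolution_segment(img, params)
    _fresh(cfg, "segments.tif")
    write_labels(seg.labels, seg.transform, cfg.path("segments.tif"), seg.crs)
    seg.objects.to_csv(cfg.path("objects.csv"))
    _manifest(cfg, "segment", [src], ["segments.tif", "objects.csv"],
              {"scale": cfg.scale, "band_weights": list(cfg.band_weights),
               "connectivity": cfg.connectivity, "n_objects": seg.n_objects}, t0)
    return ["segments.tif", "objects.csv"]


def _load_segments(cfg: RunConfig) -> SegmentMap:
    _require(cfg, "segments.tif", "segment")
    labels, transform, crs = read_labels(cfg.path("segments.tif"))
    img, _ = _input_image(cfg)
    from .segmentation import compute_object_stats

    objects, adjacency = compute_object_stats(img.pixels, labels)
    return SegmentMap(labels, objects, adjacency, transform, crs)


def _training_set(cfg: RunConfig, seg: SegmentMap) -> tuple[TrainingSet, str]:
    if cfg.training is not None and cfg.training.exists():
        return TrainingSet.from_csv(cfg.training), str(cfg.training)
    if cfg.path("training.csv").exists():
        return TrainingSet.from_csv(cfg.path("training.csv")), "training.csv"
    if cfg.path("truth_rendered.tif").exists():
        # synthetic run: label a sample of objects from the rendered truth
        rendered, transform, crs = read_labels(cfg.path("truth_rendered.tif"))
        classes, _, _ = read_labels(cfg.path("truth_classes.tif"))
        units, _, _ = read_labels(cfg.path("truth_units.tif"))
        zones = read_zones(cfg.path("zones.geojson"))
        uc = pd.read_csv(cfg.path("truth_unit_classes.csv"), index_col=0)["class_id"]
        gt = GroundTruth(classes.astype(np.int16), rendered.astype(np.int16),
                         units, uc, zones, transform, crs)
        ts = sample_training_set(seg, gt, cfg.train_fraction, cfg.seed)
        ts.to_csv(cfg.path("training.csv"))
        return ts, "truth_rendered.tif"
    raise MissingArtifactError(
        "no training set; provide config key 'training' or run 'simulate'")


def stage_train(cfg: RunConfig) -> list[str]:
    t0 = time.time()
    seg = _load_segments(cfg)
    ts, src = _training_set(cfg, seg)
    model = train_classifier(seg.objects, ts, n_trees=cfg.n_trees, seed=cfg.seed)
    _fresh(cfg, "model.joblib")
    save_model(model, cfg.path("model.joblib"), cfg.load_legend())
    _manifest(cfg, "train", ["segments.tif", src], ["model.joblib"],
              {"n_trees": cfg.n_trees, "oob_score": model.oob_score_,
               "n_training": len(ts)}, t0)
    return ["model.joblib"]


def stage_classify(cfg: RunConfig) -> list[str]:
    t0 = time.time()
    legend = cfg.load_legend()
    if cfg.backend == "color-threshold":
        img, src = _input_image(cfg)
        cmap = color_threshold_segment(img, legend, cfg.tolerance)
        inputs = [src]
        params = {"backend": cfg.backend, "tolerance": cfg.tolerance}
    else:
        _require(cfg, "model.joblib", "train")
        seg = _load_segments(cfg)
        model = load_model(cfg.path("model.joblib"))
        cmap = predict_classes(model, seg, legend)
        inputs = ["model.joblib", "segments.tif"]
        params = {"backend": cfg.backend}
    _fresh(cfg, "classified_classes.tif")
    outputs = save_classified(cmap, cfg, "classified")
    _manifest(cfg, "classify", inputs, outputs, params, t0)
    return outputs


def stage_cleanup(cfg: RunConfig) -> list[str]:
    t0 = time.time()
    legend = cfg.load_legend()
    _require(cfg, "classified_classes.tif", "classify")
    cmap = load_classified(cfg, "classified", legend.nodata_id)
    seg = _load_segments(cfg) if cfg.path("segments.tif").exists() else None
    params = CleanupParams(cfg.black_max_channel, cfg.small_object_max_px,
                           cfg.max_absorption_passes)
    clean = absorb_black_objects(cmap, seg, params, legend)
    inputs = ["classified_classes.tif"]
    if cfg.overrides is not None and cfg.overrides.exists():
        clean = apply_overrides(clean, OverrideList.from_csv(cfg.overrides), legend)
        inputs.append(str(cfg.overrides))
    _fresh(cfg, "cleaned_classes.tif")
    outputs = save_classified(clean, cfg, "cleaned")
    _manifest(cfg, "cleanup", inputs, outputs,
              {"black_max_channel": cfg.black_max_channel,
               "small_object_max_px": cfg.small_object_max_px}, t0)
    return outputs


def _load_zones(cfg: RunConfig):
    if cfg.zones is not None and cfg.zones.exists():
        return read_zones(cfg.zones), str(cfg.zones)
    if cfg.path("zones.geojson").exists():
        return read_zones(cfg.path("zones.geojson")), "zones.geojson"
    raise MissingArtifactError("no zone layer; set config key 'zones' or run "
                               "'simulate' first")


def stage_zonal(cfg: RunConfig) -> list[str]:
    t0 = time.time()
    legend = cfg.load_legend()
    _require(cfg, "cleaned_classes.tif", "cleanup")
    cmap = load_classified(cfg, "cleaned", legend.nodata_id)
    zones, zsrc = _load_zones(cfg)
    zt = zonal_class_areas(cmap, zones, legend)
    zt = assign_majority(zt, ZonalParams(cfg.majority_margin, cfg.min_coverage))
    _fresh(cfg, "zonal.csv")
    zt.to_csv(cfg.path("zonal.csv"))
    zt.units.to_csv(cfg.path("units.csv"), index=False)
    _manifest(cfg, "zonal", ["cleaned_classes.tif", zsrc],
              ["zonal.csv", "units.csv"],
              {"majority_margin": cfg.majority_margin,
               "min_coverage": cfg.min_coverage}, t0)
    return ["zonal.csv", "units.csv"]


def _load_zonal(cfg: RunConfig, legend: Legend) -> ZonalTable:
    _require(cfg, "zonal.csv", "zonal")
    merged = pd.read_csv(cfg.path("zonal.csv"), dtype={"unit_id": str,
                                                       "state_id": str})
    table = merged[["unit_id", "class_id", "area_km2", "percent"]]
    units = (merged[["unit_id", "state_id", "coverage", "majority", "margin",
                     "valid"]]
             .drop_duplicates("unit_id").reset_index(drop=True))
    zones, _ = _load_zones(cfg)
    units = units.merge(
        zones.units[["unit_id", "official_area_km2"]], on="unit_id")
    return ZonalTable(table, units, legend)


def stage_demography(cfg: RunConfig) -> list[str]:
    t0 = time.time()
    legend = cfg.load_legend()
    zt = _load_zonal(cfg, legend)
    zones, _ = _load_zones(cfg)
    params: dict[str, Any] = {}
    if cfg.target_total is not None and cfg.free_class is not None:
        v = calibrate_free_class(zt.national_class_areas(), legend,
                                 CalibrationSpec(cfg.target_total,
                                                 cfg.free_class))
        legend = legend.with_density(cfg.free_class, v)
        legend.to_json(cfg.path("legend_calibrated.json"))
        params["calibrated_density"] = v
    states = summarize_states(zt, legend, zones)
    _fresh(cfg, "states.csv")
    states.to_csv(cfg.path("states.csv"))
    _manifest(cfg, "demography", ["zonal.csv"], ["states.csv"], params, t0)
    return ["states.csv"]


def stage_compare(cfg: RunConfig) -> list[str]:
    t0 = time.time()
    if cfg.reported is None or not cfg.reported.exists():
        raise MissingArtifactError("compare needs a reported-estimates CSV "
                                   "(config: reported; columns state,estimate)")
    _require(cfg, "states.csv", "demography")
    states = pd.read_csv(cfg.path("states.csv"), index_col=0)
    reported = pd.read_csv(cfg.reported)
    ct = compare_estimates(pd.Series(reported["estimate"].values,
                                     index=reported["state"].values),
                           states["population"])
    _fresh(cfg, "comparison.csv")
    ct.table.to_csv(cfg.path("comparison.csv"))
    summary = {"total_reported": ct.total_reported, "total_map": ct.total_map,
               "total_difference": ct.total_difference, "mae": ct.mae,
               "unmatched": ct.unmatched}
    cfg.path("comparison_summary.json").write_text(json.dumps(summary, indent=2))
    _manifest(cfg, "compare", [str(cfg.reported), "states.csv"],
              ["comparison.csv", "comparison_summary.json"], {}, t0)
    return ["comparison.csv", "comparison_summary.json"]


def _stage_recovery(cfg: RunConfig) -> list[str]:
    legend = cfg.load_legend()
    classes, transform, crs = read_labels(cfg.path("truth_classes.tif"))
    rendered, _, _ = read_labels(cfg.path("truth_rendered.tif"))
    units, _, _ = read_labels(cfg.path("truth_units.tif"))
    zones = read_zones(cfg.path("zones.geojson"))
    uc = pd.read_csv(cfg.path("truth_unit_classes.csv"), index_col=0)["class_id"]
    gt = GroundTruth(classes.astype(np.int16), rendered.astype(np.int16),
                     units, uc, zones, transform, crs)
    cmap = load_classified(cfg, "cleaned", legend.nodata_id)
    rep = evaluate_recovery(gt, cmap)
    payload = {
        "pixel_accuracy": rep.pixel_accuracy,
        "unit_majority_accuracy": rep.unit_majority_accuracy,
        "producer_accuracy": {int(k): (None if v != v else v)
                              for k, v in rep.producer_accuracy.items()},
        "user_accuracy": {int(k): (None if v != v else v)
                          for k, v in rep.user_accuracy.items()},
    }
    cfg.path("recovery.json").write_text(json.dumps(payload, indent=2))
    return ["recovery.json"]


def run_stage(name: str, cfg: RunConfig) -> list[str]:
    """Run one pipeline stage (or 'all'); returns the artifact names written."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    if name == "simulate":
        return stage_simulate(cfg)
    if name == "georef":
        return stage_georef(cfg)
    if name == "segment":
        return stage_segment(cfg)
    if name == "train":
        return stage_train(cfg)
    if name == "classify":
        return stage_classify(cfg)
    if name == "cleanup":
        return stage_cleanup(cfg)
    if name == "zonal":
        return stage_zonal(cfg)
    if name == "demography":
        return stage_demography(cfg)
    if name == "compare":
        return stage_compare(cfg)
    # all: everything downstream of the available image
    outputs: list[str] = []
    if cfg.backend == "obia":
        outputs += stage_segment(cfg)
        outputs += stage_train(cfg)
    outputs += stage_classify(cfg)
    outputs += stage_cleanup(cfg)
    outputs += stage_zonal(cfg)
    outputs += stage_demography(cfg)
    if cfg.reported is not None and cfg.reported.exists():
        outputs += stage_compare(cfg)
    if cfg.path("truth_classes.tif").exists():
        outputs += _stage_recovery(cfg)
    return outputs
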