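"""End-to-end orchestration: simulate -> segment -> features -> classify ->
hazard indices -> panel models, from a single validated YAML config.

Every run writes its artifacts plus a manifest (input hashes, seed,
package versions) and a log file into the output directory; stages never
mutate one another's outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .boosting import (
    GBTConfig,
    classify,
    fit_gbt,
    predict_logodds,
    select_top_features,
    stratified_split,
    variable_importance,
)
from .core import Scene, SegmentMap
from .features import (
    aggregate_objects,
    compute_geometric_features,
    compute_glcm_features,
    compute_pca,
    compute_spectral_indices,
    compute_terrain_features,
    label_objects,
)
from .core import BAND_NAMES
from .hazards import (
    compute_spi,
    fire_severity,
    hazard_index,
    monthly_anomalies,
    yearly_dimensions,
)
from .metrics import confusion_metrics, roc_auc
from .panel import (
    chow_test,
    fit_fixed_effects,
    fit_pooled,
    fit_random_effects,
    hausman_test,
    summarize_fits,
)
from .segmentation import SegmentationConfig, segment
from .synthetic import (
    PanelSpec,
    SceneSpec,
    generate_climate_panel,
    generate_dem,
    generate_fire_records,
    generate_scene,
)

logger = logging.getLogger("geodefol.pipeline")

_SCHEMA: dict[str, set[str] | None] = {
    "version": None,
    "seed": None,
    "output_dir": None,
    "simulate": {"scene", "panel", "fire_rate", "dem_roughness"},
    "paths": {"scene", "dem", "labels", "climate", "fire_records", "panel"},
    "segmentation": {"scale", "shape_weight", "compactness_weight", "band_weights"},
    "classifier": {
        "n_trees",
        "max_leaves",
        "learning_rate",
        "subsample",
        "test_fraction",
        "importance_threshold_pct",
    },
    "hazard": {"threshold", "gamma", "year_basis", "spi_timescale", "baseline"},
    "panel": {"spec"},
}


def validate_config(cfg: dict) -> dict:
    """Fail fast on unknown keys; silent typos corrupt long pipelines."""
    unknown = set(cfg) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key, allowed in _SCHEMA.items():
        if allowed is None or key not in cfg:
            continue
        sub = cfg[key]
        if not isinstance(sub, dict):
            raise ValueError(f"config block {key!r} must be a mapping")
        bad = set(sub) - allowed
        if bad:
            raise ValueError(f"unknown key(s) in {key!r}: {sorted(bad)}")
    if "segmentation" in cfg and "scale" not in cfg["segmentation"]:
        raise ValueError("segmentation.scale is required (no fidelity default)")
    return cfg


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    return validate_config(cfg or {})


@dataclass
class StageTimer:
    timings: dict

    def __init__(self) -> None:
        self.timings = {}

    def record(self, stage: str, t0: float) -> None:
        self.timings[stage] = round(time.time() - t0, 3)
        logger.info("stage %s finished in %.2fs", stage, self.timings[stage])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, output_dir=None) -> dict:
    """Execute all stages; returns the report dict.

    Artifacts written: segments.tif, features.csv, model.json,
    metrics.csv, hazard_indices.csv, panel_fits.csv, report.json
    (plus panel_fits.txt, manifest.json and run.log).
    """
    validate_config(config)
    out = Path(output_dir or config.get("output_dir", "geodefol_out"))
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logging.getLogger("geodefol").addHandler(handler)
    seed = int(config.get("seed", 0))
    timer = StageTimer()
    report: dict = {"seed": seed, "stages": {}}

    try:
        # ------------------------------------------------ inputs
        t0 = time.time()
        if "simulate" in config:
            sim = config["simulate"]
            scene_spec = SceneSpec(**{**{"seed": seed}, **sim.get("scene", {})})
            scene, label_raster, forest_type = generate_scene(scene_spec)
            dem = generate_dem(
                scene_spec.width,
                scene_spec.height,
                float(sim.get("dem_roughness", 25.0)),
                seed + 1,
            )
            panel_spec = PanelSpec(**{**{"seed": seed + 2}, **sim.get("panel", {})})
            climate, panel, beta_true = generate_climate_panel(panel_spec)
            fires = generate_fire_records(
                panel_spec.n_objects,
                panel_spec.panel_years,
                float(sim.get("fire_rate", 0.6)),
                seed + 3,
            )
            report["stages"]["simulate"] = {
                "n_patches": scene_spec.n_patches,
                "n_panel_objects": panel_spec.n_objects,
                "beta_true": list(map(float, beta_true)),
            }
        else:
            paths = config["paths"]
            scene = gio.read_scene(paths["scene"])
            dem = gio.read_raster(paths["dem"]) if "dem" in paths else None
            label_raster = (
                gio.read_raster(paths["labels"]) if "labels" in paths else None
            )
            forest_type = None
            climate = pd.read_csv(paths["climate"]) if "climate" in paths else None
            fires = (
                gio.read_fire_geojson(paths["fire_records"])
                if "fire_records" in paths
                else None
            )
            panel = pd.read_csv(paths["panel"]) if "panel" in paths else None
        timer.record("inputs", t0)

        # ------------------------------------------------ segmentation
        t0 = time.time()
        seg_cfg = SegmentationConfig(**config["segmentation"])
        seg = segment(scene, seg_cfg)
        gio.write_segment_map(out / "segments.tif", seg, scene.transform)
        report["stages"]["segment"] = {"n_objects": seg.n_objects}
        timer.record("segment", t0)

        # ------------------------------------------------ features
        t0 = time.time()
        stack = compute_spectral_indices(scene)
        stack.pc_scores, stack.pc_loadings, stack.pc_variance_fraction = compute_pca(
            scene
        )
        texture = {
            b: compute_glcm_features(scene.bands[b], seg) for b in BAND_NAMES
        }
        geometric = compute_geometric_features(seg)
        terrain = compute_terrain_features(dem) if dem is not None else None
        table = aggregate_objects(
            scene, stack, texture, geometric, terrain, forest_type, seg
        )
        if label_raster is not None:
            table["label"] = label_objects(seg, label_raster)
        gio.write_feature_table(out / "features.csv", table)
        report["stages"]["features"] = {"n_features": table.shape[1] - ("label" in table)}
        timer.record("features", t0)

        # ------------------------------------------------ classification
        t0 = time.time()
        if "label" in table:
            cls_cfg = dict(config.get("classifier", {}))
            test_fraction = float(cls_cfg.pop("test_fraction", 1.0 / 3.0))
            thr = float(cls_cfg.pop("importance_threshold_pct", 15.0))
            gbt_cfg = GBTConfig(**{**{"seed": seed}, **cls_cfg})
            train, test = stratified_split(table, test_fraction, seed)
            model = fit_gbt(train, test, gbt_cfg)
            importance = variable_importance(model)
            top = select_top_features(importance, thr)
            # rebuild on the top influential features only
            keep = top + ["label"]
            model = fit_gbt(train[keep], test[keep], gbt_cfg)
            pred = classify(model, test)
            m = confusion_metrics(test["label"], pred)
            auc = roc_auc(test["label"], predict_logodds(model, test))
            gio.write_model(out / "model.json", model)
            metrics_df = pd.DataFrame(
                {
                    "measure": [
                        "overall", "specificity", "sensitivity", "precision", "f1",
                        "roc_auc", "n_trees_optimal", "n_top_features",
                    ],
                    "value": [
                        m.overall, m.specificity, m.sensitivity, m.precision, m.f1,
                        100 * auc, model.n_trees_optimal, len(top),
                    ],
                }
            )
            metrics_df.to_csv(out / "metrics.csv", index=False)
            importance.to_csv(out / "importance.csv", index=False)
            report["stages"]["classify"] = {
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "precision": m.precision,
                "overall": m.overall,
                "f1": m.f1,
                "roc_auc": auc,
                "n_trees_optimal": model.n_trees_optimal,
                "top_features": top[:10],
            }
        timer.record("classify", t0)

        # ------------------------------------------------ hazard indices
        t0 = time.time()
        hz = config.get("hazard", {})
        gamma = float(hz.get("gamma", 0.9))
        threshold = float(hz.get("threshold", 1.0))
        basis = hz.get("year_basis", "hydrological")
        if climate is not None:
            years = sorted(climate["year"].unique())
            baseline = tuple(hz.get("baseline", (years[0], years[min(19, len(years) - 1)])))
            pieces = []
            for var, direction, use_spi in (
                ("precip", "deficit", True),
                ("tmax", "excess", False),
                ("soilm", "deficit", False),
            ):
                cube = climate[climate["variable"] == var][
                    ["object_id", "year", "month", "value"]
                ]
                if use_spi:
                    z = compute_spi(
                        cube, int(hz.get("spi_timescale", 12)), baseline
                    )
                else:
                    z = monthly_anomalies(cube, baseline)
                dims = yearly_dimensions(z, direction, threshold, basis)
                idx = hazard_index(dims, gamma=gamma)
                idx.insert(0, "variable", {"precip": "drought", "tmax": "tmax", "soilm": "soilm"}[var])
                pieces.append(idx)
            if fires is not None and panel is not None:
                fs = fire_severity(
                    fires,
                    sorted(panel["object_id"].unique()),
                    sorted(panel["year"].unique()),
                    gamma=gamma,
                )
                fs.insert(0, "variable", "fire")
                pieces.append(fs)
            hazard_df = pd.concat(pieces, ignore_index=True)
            hazard_df.to_csv(out / "hazard_indices.csv", index=False)
            report["stages"]["hazard"] = {
                "variables": sorted(hazard_df["variable"].unique()),
                "gamma": gamma,
            }
        timer.record("hazard", t0)

        # ------------------------------------------------ panel models
        t0 = time.time()
        if panel is not None:
            response = (
                "infestation" if "infestation" in panel.columns else "fire"
            )
            po = fit_pooled(panel, response)
            fe = fit_fixed_effects(panel, response)
            re = fit_random_effects(panel, response)
            ch = chow_test(po, fe, panel)
            ha = hausman_test(fe, re)
            rows = []
            for fit in (po, fe, re):
                for name, b in fit.beta.items():
                    rows.append(
                        (fit.model, name, b, fit.std_errors[name], fit.p_values()[name])
                    )
                rows.append((fit.model, "R2", fit.r2, np.nan, np.nan))
            pd.DataFrame(
                rows, columns=["model", "term", "estimate", "std_error", "p_value"]
            ).to_csv(out / "panel_fits.csv", index=False)
            (out / "panel_fits.txt").write_text(
                summarize_fits([po, fe, re], response).to_string()
                + f"\n\nChow X2={ch.statistic:.2f} df={ch.df} p={ch.p_value:.3f}"
                + f" (F={ch.statistic_f:.2f}, p={ch.p_value_f:.3f})"
                + f"\nHausman X2={ha.statistic:.2f} df={ha.df} p={ha.p_value:.3f}\n"
            )
            report["stages"]["panel"] = {
                "response": response,
                "chow": {"statistic": ch.statistic, "df": ch.df, "p": ch.p_value},
                "hausman": {"statistic": ha.statistic, "df": ha.df, "p": ha.p_value},
                "re_beta": {k: float(v) for k, v in re.beta.items()},
                "re_r2": re.r2,
            }
        timer.record("panel", t0)

    except Exception as exc:  # annotate the failing stage, keep partial outputs
        stage = max(timer.timings, default="inputs")
        logger.error("pipeline aborted after stage %r: %s", stage, exc)
        raise

    report["timings"] = timer.timings
    (out / "report.json").write_text(json.dumps(report, indent=1))

    import geodefol

    manifest = {
        "seed": seed,
        "config": config,
        "versions": {
            "geodefol": getattr(geodefol, "__version__", "0"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in (".csv", ".json", ".tif", ".txt") and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logging.getLogger("geodefol").removeHandler(handler)
    handler.close()
    return report
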