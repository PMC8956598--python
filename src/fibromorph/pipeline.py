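"""End-to-end orchestration: simulate -> preprocess -> embed/features ->
profiles -> tasks -> importance -> qc.

Two entry styles are provided.  The in-memory helpers (:func:`embed_study`,
:func:`well_embedding_table`, :func:`cell_feature_table`) render tiles on
demand and return pandas tables; they are the fast path used for multi-seed
experiments.  :func:`run_pipeline` is the disk-based staged runner behind the
CLI: each stage persists its artifacts under the output directory and checks
that its upstream artifacts exist, naming the producing stage when they do
not.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import tifffile

from . import qc as qc_mod
from .cohort import CohortSpec
from .embeddings import (PoolingBackbone, ProjectionSpec, embed_multichannel,
                         embedding_columns, make_projection)
from .features import extract_cell_features, feature_value_columns, image_stats, segment_cells
from .preprocess import PreprocessConfig, extract_crops, preprocess_plate
from .profiles import (center_by_batch_layout, l2_scale_columns, save_table,
                       value_columns, well_aggregate)
from .simulate import ExperimentPlan, SyntheticStudy, micro_plan

META_FROM_MANIFEST = ["batch", "plate", "layout", "well", "tile", "line_id",
                      "donor_id", "biopsy_index", "disease_state",
                      "mutation_group", "age", "sex", "pair_id"]


def micro_preprocess_config() -> PreprocessConfig:
    """Pre-processing constants rescaled to the micro tile size (96 px)."""
    return PreprocessConfig(background_sigma=8.0, detect_sigma=1.5,
                            min_object_area=30, crop_side=32)


def _row_meta(row) -> dict:
    get = row.get if hasattr(row, "get") else lambda k: getattr(row, k)
    return {k: get(k) for k in META_FROM_MANIFEST}


def iter_processed(study: SyntheticStudy,
                   config: PreprocessConfig | None = None):
    """Yield (manifest row, processed 8-bit tile, nucleus centers) per tile,
    plate by plate (backgrounds are per batch+plate)."""
    config = config or micro_preprocess_config()
    plates = study.manifest[["batch", "plate"]].drop_duplicates()
    for b, p in plates.itertuples(index=False):
        group = list(study.iter_plate(int(b), int(p)))
        yield from preprocess_plate(group, config)


def embed_study(study: SyntheticStudy, backbone=None,
                projection: ProjectionSpec | None = None,
                config: PreprocessConfig | None = None,
                level: str = "tile") -> pd.DataFrame:
    """Tile- or cell-level deep-embedding table for a whole synthetic study."""
    backbone = backbone or PoolingBackbone()
    projection = projection or make_projection(backbone.output_dim, seed=study.seed)
    config = config or micro_preprocess_config()
    rows = []
    ecols = embedding_columns()
    for row, processed, centers in iter_processed(study, config):
        meta = _row_meta(row)
        if level == "tile":
            vec = embed_multichannel(processed, backbone, projection)
            rows.append({**meta, **dict(zip(ecols, vec))})
        elif level == "cell":
            crops, kept, _ = extract_crops(processed, centers, config.crop_side)
            for ci, crop in enumerate(crops):
                vec = embed_multichannel(crop, backbone, projection)
                rows.append({**meta, "object": ci + 1, **dict(zip(ecols, vec))})
        else:
            raise ValueError(f"unknown level {level!r}")
    return pd.DataFrame(rows)


def well_embedding_table(study: SyntheticStudy, backbone=None,
                         projection: ProjectionSpec | None = None,
                         config: PreprocessConfig | None = None,
                         level: str = "tile") -> pd.DataFrame:
    """Batch/layout-centered, well-mean embedding profiles (the model input)."""
    tile_table = embed_study(study, backbone, projection, config, level)
    centered, _ = center_by_batch_layout(tile_table)
    return well_aggregate(centered)


def cell_feature_table(study: SyntheticStudy,
                       config: PreprocessConfig | None = None) -> pd.DataFrame:
    """Per-cell engineered-feature table for a whole synthetic study."""
    rows = []
    for row, processed, centers in iter_processed(study, config):
        seg = segment_cells(processed, centers)
        feats = extract_cell_features(processed, seg)
        if feats.empty:
            continue
        meta = _row_meta(row)
        for k, v in meta.items():
            feats[k] = v
        rows.append(feats)
    if not rows:
        return pd.DataFrame()
    return pd.concat(rows, ignore_index=True)


def well_feature_table(study: SyntheticStudy,
                       config: PreprocessConfig | None = None) -> pd.DataFrame:
    """Centered + L2-scaled, well-mean engineered-feature profiles."""
    cells = cell_feature_table(study, config)
    centered, _ = center_by_batch_layout(cells)
    scaled, _ = l2_scale_columns(centered)
    return well_aggregate(scaled)


def image_stats_table(study: SyntheticStudy,
                      config: PreprocessConfig | None = None) -> pd.DataFrame:
    """Per-tile image statistics (one row per tile, wide per channel)."""
    rows = []
    for row, processed, _centers in iter_processed(study, config):
        stats = image_stats(processed)
        meta = _row_meta(row)
        flat = dict(meta)
        for r in stats.itertuples(index=False):
            for fieldname in ("focus_score", "fg_mean", "fg_std", "bg_mean",
                              "bg_std", "fg_fraction"):
                flat[f"Image_Intensity_{r.channel}_{fieldname}"] = getattr(r, fieldname)
        rows.append(flat)
    return pd.DataFrame(rows)


def disease_auc_experiment(seeds, disease_effect_scale: float,
                           line_effect_scale: float = 0.6,
                           donor_effect_scale: float = 0.5,
                           plan: ExperimentPlan | None = None,
                           model: str = "logistic_regression_cv",
                           subgroup: str = "all_PD") -> list[float]:
    """Mean line-level disease AUC (across the 5 matched-pair folds) for each
    seed, recomputed through the full image pipeline: render the synthetic
    study, flat-field correct, embed tiles, center per batch+layout,
    well-aggregate, and run the matched-pair disease task."""
    from .cohort import CohortSpec
    from .tasks import DiseaseClassification

    plan = plan or micro_plan()
    out = []
    for seed in seeds:
        spec = CohortSpec(disease_effect_scale=disease_effect_scale,
                          line_effect_scale=line_effect_scale,
                          donor_effect_scale=donor_effect_scale, seed=int(seed))
        study = SyntheticStudy(spec, plan, seed=int(seed))
        wells = well_embedding_table(study)
        res = DiseaseClassification(wells, study.pairs, model,
                                    seed=int(seed)).fit()
        out.append(res.mean_auc(subgroup))
    return out


# ---------------------------------------------------------------------------
# disk-based staged runner

STAGE_ORDER = ["simulate", "preprocess", "embed", "features", "profiles",
               "tasks", "importance", "qc"]


class PipelineDependencyError(RuntimeError):
    pass


def _require(path: str, producer: str) -> None:
    if not os.path.exists(path):
        raise PipelineDependencyError(
            f"missing artifact {path!r}; run the '{producer}' stage first")


def run_pipeline(config, stages=None, log=print) -> dict:
    """Execute the requested stages in dependency order.

    ``config`` is a :class:`fibromorph.config.PipelineConfig`.  Returns a run
    manifest dict (per-stage row counts and artifact paths); the resolved
    config and seed are persisted alongside the outputs.
    """
    from .config import PipelineConfig  # deferred: avoid import cycle

    if not isinstance(config, PipelineConfig):
        raise TypeError("run_pipeline expects a PipelineConfig")
    stages = list(stages or STAGE_ORDER)
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    out = config.paths.out_dir
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "config_resolved.json"), "w") as fh:
        fh.write(config.model_dump_json(indent=2))
    manifest_path = os.path.join(out, "manifest.csv")
    run: dict = {"stages": {}}

    study = SyntheticStudy(config.cohort_spec(), config.plan(), config.study.seed)
    pconfig = config.preprocess_config()

    for stage in sorted(stages, key=STAGE_ORDER.index):
        if stage == "simulate":
            study.manifest.to_csv(manifest_path, index=False)
            if config.study.write_images:
                img_dir = os.path.join(out, "images")
                for row in study.manifest.itertuples(index=False):
                    path = os.path.join(img_dir, row.path)
                    os.makedirs(os.path.dirname(path), exist_ok=True)
                    tifffile.imwrite(path, np.moveaxis(study.tile(row), -1, 0),
                                     photometric="minisblack")
            run["stages"]["simulate"] = {"rows": len(study.manifest)}
            log(f"[simulate] {len(study.manifest)} tiles in manifest")
        elif stage == "preprocess":
            _require(manifest_path, "simulate")
            proc_dir = os.path.join(out, "processed")
            centers_rows = []
            for row, processed, centers in iter_processed(study, pconfig):
                path = os.path.join(proc_dir, row.path)
                os.makedirs(os.path.dirname(path), exist_ok=True)
                tifffile.imwrite(path, np.moveaxis(processed, -1, 0),
                                 photometric="minisblack")
                for (r, c) in centers:
                    centers_rows.append({**_row_meta(row), "row": r, "col": c})
            pd.DataFrame(centers_rows).to_csv(
                os.path.join(out, "nucleus_centers.csv"), index=False)
            run["stages"]["preprocess"] = {"nuclei": len(centers_rows)}
            log(f"[preprocess] {len(centers_rows)} nuclei detected")
        elif stage == "embed":
            _require(manifest_path, "simulate")
            backbone = PoolingBackbone()
            projection = make_projection(backbone.output_dim,
                                         config.embedding.projection_seed)
            table = embed_study(study, backbone, projection, pconfig,
                                level=config.embedding.level)
            save_table(table, os.path.join(out, "embeddings.parquet"))
            with open(os.path.join(out, "projection.json"), "w") as fh:
                fh.write(projection.to_json())
            run["stages"]["embed"] = {"rows": len(table)}
            log(f"[embed] {len(table)} {config.embedding.level}-level embeddings")
        elif stage == "features":
            _require(manifest_path, "simulate")
            cells = cell_feature_table(study, pconfig)
            save_table(cells, os.path.join(out, "features_cell.parquet"))
            stats = image_stats_table(study, pconfig)
            save_table(stats, os.path.join(out, "imagestats.parquet"))
            run["stages"]["features"] = {"cells": len(cells)}
            log(f"[features] {len(cells)} cells featurized")
        elif stage == "profiles":
            src = os.path.join(out, "embeddings.parquet")
            _require(src, "embed")
            table = pd.read_parquet(src)
            centered, _ = center_by_batch_layout(table)
            wells = well_aggregate(centered)
            save_table(wells, os.path.join(out, "profiles_well_embedding.parquet"))
            fsrc = os.path.join(out, "features_cell.parquet")
            if os.path.exists(fsrc):
                feats = pd.read_parquet(fsrc)
                if len(feats):
                    centered, _ = center_by_batch_layout(feats)
                    scaled, _ = l2_scale_columns(centered)
                    save_table(well_aggregate(scaled),
                               os.path.join(out, "profiles_well_engineered.parquet"))
            run["stages"]["profiles"] = {"wells": len(wells)}
            log(f"[profiles] {len(wells)} well profiles")
        elif stage == "tasks":
            src = os.path.join(out, "profiles_well_embedding.parquet")
            _require(src, "profiles")
            from .tasks import (DiseaseClassification, DonorIdentification,
                                LineIdentification, channel_ablation)
            wells = pd.read_parquet(src)
            if config.tasks.ablate_channel:
                wells = channel_ablation(wells, "omit", config.tasks.ablate_channel)
            metrics: dict = {}
            if config.tasks.task == "line":
                res = LineIdentification(wells, config.tasks.model,
                                         config.tasks.seed).fit()
                metrics = {
                    "line_accuracy_mean": float(res.line_accuracies.mean()),
                    "line_accuracy_sd": float(res.line_accuracies.std()),
                    "well_accuracy_mean": float(res.well_accuracies.mean()),
                    "rank_histogram": res.rank_histogram.tolist(),
                }
            elif config.tasks.task == "donor":
                res = DonorIdentification(wells, config.tasks.model,
                                          config.tasks.seed).fit()
                metrics = {
                    "line_accuracy_mean": float(res.line_accuracies.mean()),
                    "heldout_mean_rank": float(res.heldout_ranks.mean()),
                    "heldout_ranks": res.heldout_ranks.tolist(),
                }
            elif config.tasks.task == "disease":
                res = DiseaseClassification(wells, study.pairs,
                                            config.tasks.model,
                                            seed=config.tasks.seed).fit()
                metrics = {sg: {"mean": res.mean_auc(sg), "sd": res.sd_auc(sg)}
                           for sg in res.fold_aucs.columns}
            else:
                raise ValueError(f"unknown task {config.tasks.task!r}")
            metrics["summary"] = res.summary()
            with open(os.path.join(out, f"metrics_{config.tasks.task}.json"),
                      "w") as fh:
                json.dump(metrics, fh, indent=2)
            run["stages"]["tasks"] = metrics
            log(res.summary())
        elif stage == "importance":
            src = os.path.join(out, "profiles_well_engineered.parquet")
            _require(src, "profiles")
            from .importance import importance_report, rank_features
            from .tasks import ModelSpec, disease_folds, fit_predict
            wells = pd.read_parquet(src)
            fcols = feature_value_columns(wells)
            folds = disease_folds(study.pairs, wells, seed=config.tasks.seed)
            lists = []
            for kind in ("logistic_regression_cv", "ridge_cv", "random_forest"):
                for fi, sp in enumerate(folds):
                    _, est = fit_predict(sp, ModelSpec(kind, config.tasks.seed),
                                         wells[["batch", "plate", "layout", "well",
                                                "line_id", "disease_state",
                                                "mutation_group", "biopsy_index",
                                                "donor_id"] + fcols],
                                         return_model=True)
                    lists.append(rank_features(est, fcols, kind, fi))
            line_vals = wells.groupby("line_id")[fcols].mean().reset_index()
            k = min(config.importance.top_k, len(fcols))
            report = importance_report(lists, k, line_vals,
                                       threshold=config.importance.correlation_threshold)
            with open(os.path.join(out, "importance.json"), "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            run["stages"]["importance"] = {"n_common": len(report.common),
                                           "n_kept": len(report.kept)}
            log(f"[importance] {len(report.common)} common, {len(report.kept)} kept")
        elif stage == "qc":
            _require(manifest_path, "simulate")
            montage, stats = qc_mod.qc_montage(study, plate=1,
                                               crops_per_well=config.qc.crops_per_well,
                                               crop_side=config.qc.crop_side,
                                               seed=config.qc.seed,
                                               preprocess_config=pconfig)
            import imageio.v3 as iio
            iio.imwrite(os.path.join(out, "qc_montage.png"), montage)
            stats.to_csv(os.path.join(out, "qc_stats.csv"), index=False)
            report = qc_mod.qc_plate_report(stats)
            with open(os.path.join(out, "qc_report.json"), "w") as fh:
                json.dump(report, fh, indent=2)
            run["stages"]["qc"] = {"stats_rows": len(stats)}
            log(f"[qc] montage + {len(stats)} stat rows")
    with open(os.path.join(out, "run_manifest.json"), "w") as fh:
        json.dump(run, fh, indent=2, default=str)
    return run
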