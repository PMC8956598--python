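"""Validated pipeline configuration.

All scalar constants of the pipeline live here with their defaults (background
percentile 10 and blur sigma 50, 8-bit clip percentiles, crop side, 64-D
projection, 4 radial rings, 0.75 correlation threshold, top-K step 20, forest
size 100, MLP hidden width 200, seeds).  Unknown keys are rejected; every run
persists the resolved config next to its outputs.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict

from .cohort import CohortSpec
from .preprocess import PreprocessConfig
from .simulate import ExperimentPlan


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StudySettings(_Model):
    n_batches: int = 2
    plates_per_layout_per_batch: int = 1
    tiles_per_well: int = 2
    image_height: int = 96
    image_width: int = 96
    cells_per_tile_mean: float = 6.0
    disease_effect_scale: float = 0.0
    donor_effect_scale: float = 1.0
    line_effect_scale: float = 0.5
    seed: int = 0
    write_images: bool = False


class PreprocessSettings(_Model):
    background_percentile: float = 10.0
    background_sigma: float = 8.0
    clip_lo_percentile: float = 0.001
    clip_hi_percentile: float = 1.0
    detect_sigma: float = 1.5
    min_object_area: int = 30
    crop_side: int = 32


class EmbeddingSettings(_Model):
    projection_dim: Literal[64] = 64
    projection_seed: int = 0
    level: Literal["tile", "cell"] = "tile"


class TaskSettings(_Model):
    task: Literal["line", "donor", "disease"] = "disease"
    source: Literal["embedding", "engineered", "imagestats"] = "embedding"
    model: Literal["logistic_regression_cv", "ridge_cv",
                   "random_forest", "mlp"] = "logistic_regression_cv"
    ablate_channel: Optional[Literal["DAPI", "ER", "RNA", "AGP", "MITO"]] = None
    seed: int = 0


class ImportanceSettings(_Model):
    top_k: int = 40
    top_k_step: int = 20
    correlation_threshold: float = 0.75


class QCSettings(_Model):
    crops_per_well: int = 1
    crop_side: int = 32
    seed: int = 0


class PathSettings(_Model):
    out_dir: str = "fibromorph_out"


class PipelineConfig(_Model):
    study: StudySettings = StudySettings()
    preprocess: PreprocessSettings = PreprocessSettings()
    embedding: EmbeddingSettings = EmbeddingSettings()
    tasks: TaskSettings = TaskSettings()
    importance: ImportanceSettings = ImportanceSettings()
    qc: QCSettings = QCSettings()
    paths: PathSettings = PathSettings()

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            disease_effect_scale=self.study.disease_effect_scale,
            donor_effect_scale=self.study.donor_effect_scale,
            line_effect_scale=self.study.line_effect_scale,
            seed=self.study.seed,
        )

    def plan(self) -> ExperimentPlan:
        return ExperimentPlan(
            n_batches=self.study.n_batches,
            plates_per_layout_per_batch=self.study.plates_per_layout_per_batch,
            tiles_per_well=self.study.tiles_per_well,
            image_height=self.study.image_height,
            image_width=self.study.image_width,
            cells_per_tile_mean=self.study.cells_per_tile_mean,
        )

    def preprocess_config(self) -> PreprocessConfig:
        p = self.preprocess
        return PreprocessConfig(
            background_percentile=p.background_percentile,
            background_sigma=p.background_sigma,
            clip_lo_percentile=p.clip_lo_percentile,
            clip_hi_percentile=p.clip_hi_percentile,
            detect_sigma=p.detect_sigma,
            min_object_area=p.min_object_area,
            crop_side=p.crop_side,
        )
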