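"""Synthetic Cell Painting tile renderer and experiment generator.

Tiles are rendered as fields of elliptical cells: a nucleus visible in DAPI and
a larger cytoplasm visible in the ER/RNA/AGP/MITO channels, each modulated by a
per-line granular texture and radial intensity profile.  Batch artifacts
(per-channel gain, a multiplicative vignette-style illumination field, photon
and read noise) are applied on top, emulating the microscope/batch variation
that flat-field correction later removes.  Rendering is a pure function of
(cohort spec, plan, seed): every tile's random stream is derived from the
master seed and its (batch, plate, well, tile) address.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .cohort import (
    CHANNELS,
    CohortSpec,
    LineProfile,
    PlateLayout,
    build_cohort,
    build_layouts,
    well_name,
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ExperimentPlan:
    """Geometry of one synthetic experiment."""

    n_batches: int = 4
    plates_per_layout_per_batch: int = 6
    tiles_per_well: int = 76
    image_height: int = 2960
    image_width: int = 5056
    cells_per_tile_mean: float = 40.0
    background_level: float = 400.0
    bit_depth: int = 16
    channels: tuple = CHANNELS

    def validate(self) -> None:
        if tuple(self.channels) != CHANNELS:
            raise ConfigurationError(f"channels must be {CHANNELS} in order")
        if self.tiles_per_well < 1:
            raise ConfigurationError("tiles_per_well must be >= 1")

    @property
    def plates_per_batch(self) -> int:
        return 2 * self.plates_per_layout_per_batch

    @property
    def n_tiles(self) -> int:
        return self.n_batches * self.plates_per_batch * 96 * self.tiles_per_well


def full_plan() -> ExperimentPlan:
    """The full-scale design: 4 batches x 12 plates x 96 wells x 76 tiles."""
    return ExperimentPlan()


def desk_plan() -> ExperimentPlan:
    """Desk-scale design that keeps the whole pipeline tractable on one CPU."""
    return ExperimentPlan(
        n_batches=2, plates_per_layout_per_batch=1, tiles_per_well=4,
        image_height=512, image_width=512, cells_per_tile_mean=12.0,
    )


def micro_plan() -> ExperimentPlan:
    """Minimal design for multi-seed experiments and fast tests."""
    return ExperimentPlan(
        n_batches=2, plates_per_layout_per_batch=1, tiles_per_well=2,
        image_height=96, image_width=96, cells_per_tile_mean=6.0,
    )


@dataclass(frozen=True)
class BatchEffect:
    """Multiplicative/additive acquisition artifacts of one batch."""

    batch_id: int
    gain: np.ndarray  # (5,) per-channel gain > 0
    vignette_strength: float  # illumination field = 1 - s*(r/rmax)^2
    additive_noise_sd: float = 30.0
    photon_noise: bool = True

    def __post_init__(self):
        g = np.asarray(self.gain, dtype=float)
        if np.any(g <= 0):
            raise ConfigurationError("gain must be positive")
        object.__setattr__(self, "gain", g)

    def illumination_field(self, shape: tuple[int, int]) -> np.ndarray:
        """Smooth multiplicative field with values in (0, 1]."""
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2)
        r2max = cy ** 2 + cx ** 2
        field = 1.0 - self.vignette_strength * r2 / max(r2max, 1.0)
        return np.clip(field, 1e-3, 1.0)


def batch_effect_for(batch: int, seed: int, *, noiseless: bool = False) -> BatchEffect:
    """Deterministically draw the artifact parameters of one batch."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(999, batch)))
    gain = np.exp(rng.normal(0.0, 0.15, size=len(CHANNELS)))
    strength = rng.uniform(0.1, 0.3)
    if noiseless:
        return BatchEffect(batch, gain, strength, additive_noise_sd=0.0, photon_noise=False)
    return BatchEffect(batch, gain, strength)


def _ellipse_axes(area: float, eccentricity: float) -> tuple[float, float]:
    """Semi-axes (a >= b) of an ellipse with given area and eccentricity."""
    ratio = np.sqrt(max(1.0 - eccentricity ** 2, 1e-4))  # b/a
    a = np.sqrt(area / (np.pi * ratio))
    return a, a * ratio


def render_tile(
    line: LineProfile,
    batch_effect: BatchEffect,
    plan: ExperimentPlan,
    well: str,
    tile_idx: int,
    seed: int,
    *,
    plate: int = 0,
    with_masks: bool = False,
):
    """Render one 16-bit 5-channel tile for a cell line.

    Returns the (H, W, 5) uint16 image; with ``with_masks=True`` also returns
    the noiseless per-cell nucleus and cell label images (ground truth used by
    tests and by the segmentation oracle).
    """
    plan.validate()
    h, w = plan.image_height, plan.image_width
    p = line.morphology_params
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(batch_effect.batch_id, plate,
                                                line.line_id, tile_idx))
    )

    cell_a_max, _ = _ellipse_axes(p["cell_area_mean"] + 4 * p["cell_area_sd"],
                                  p["eccentricity"])
    if 2 * cell_a_max >= min(h, w):
        raise ConfigurationError(
            f"cell diameter {2 * cell_a_max:.0f}px exceeds image bounds {min(h, w)}px"
        )

    signal = np.full((h, w, 5), plan.background_level, dtype=np.float64)
    nuc_labels = np.zeros((h, w), dtype=np.int32)
    cell_labels = np.zeros((h, w), dtype=np.int32)

    n_cells = rng.poisson(plan.cells_per_tile_mean)
    margin = int(np.ceil(cell_a_max)) + 1
    intens = np.array([p[f"intensity_{c}"] for c in CHANNELS])
    grain = np.array([p[f"grain_radius_{c}"] for c in CHANNELS])
    skew = np.array([p[f"radial_skew_{c}"] for c in CHANNELS])

    # nuclei practically never overlap in a monolayer: reject candidate
    # centers closer than one nucleus diameter to an existing cell
    min_sep = 2.0 * np.sqrt(p["nucleus_area_mean"] / np.pi)
    centers: list[tuple[float, float]] = []

    def draw_center():
        for _ in range(25):
            y = rng.uniform(margin, h - margin) if h > 2 * margin else h / 2
            x = rng.uniform(margin, w - margin) if w > 2 * margin else w / 2
            if all((y - cy0) ** 2 + (x - cx0) ** 2 >= min_sep ** 2
                   for cy0, cx0 in centers):
                return y, x
        return None

    for ci in range(1, n_cells + 1):
        drawn = draw_center()
        if drawn is None:
            continue  # tile is saturated with cells
        cy, cx = drawn
        centers.append((cy, cx))
        theta = rng.uniform(0, np.pi)
        nuc_area = max(20.0, rng.normal(p["nucleus_area_mean"], p["nucleus_area_sd"]))
        cell_area = max(nuc_area * 1.6,
                        rng.normal(p["cell_area_mean"], p["cell_area_sd"]))
        ecc = p["eccentricity"]
        ca, cb = _ellipse_axes(cell_area, ecc)
        na, nb = _ellipse_axes(nuc_area, ecc)

        half = int(np.ceil(ca)) + 2
        r0, r1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        c0, c1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        rho_cell = np.sqrt((u / ca) ** 2 + (v / cb) ** 2)
        rho_nuc = np.sqrt((u / na) ** 2 + (v / nb) ** 2)
        in_cell = rho_cell <= 1.0
        in_nuc = rho_nuc <= 1.0

        nuc_labels[r0:r1, c0:c1][in_nuc] = ci
        cell_labels[r0:r1, c0:c1][in_cell] = ci

        for ch in range(5):
            if ch == 0:
                mask, rho = in_nuc, rho_nuc
            else:
                mask, rho = in_cell, rho_cell
            if not mask.any():
                continue
            radial = np.clip(1.0 + skew[ch] * (rho - 0.5), 0.1, None)
            tex = gaussian_filter(rng.standard_normal(mask.shape), grain[ch])
            tstd = tex.std()
            tex = tex / tstd if tstd > 0 else tex
            fieldv = intens[ch] * radial * np.clip(1.0 + 0.35 * tex, 0.1, None)
            if ch != 0:
                fieldv = np.where(in_nuc, 0.4 * fieldv, fieldv)
            signal[r0:r1, c0:c1, ch][mask] += fieldv[mask]

    illum = batch_effect.illumination_field((h, w))
    out = signal * illum[:, :, None] * batch_effect.gain[None, None, :]
    if batch_effect.photon_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    if batch_effect.additive_noise_sd > 0:
        out = out + rng.normal(0.0, batch_effect.additive_noise_sd, size=out.shape)
    img = np.clip(np.rint(out), 0, 2 ** plan.bit_depth - 1).astype(np.uint16)
    if with_masks:
        return img, nuc_labels, cell_labels
    return img


MANIFEST_COLUMNS = [
    "batch", "plate", "layout", "well", "tile", "line_id", "donor_id",
    "biopsy_index", "disease_state", "mutation_group", "age", "sex",
    "pair_id", "path",
]


class SyntheticStudy:
    """A fully-specified synthetic study rendering tiles on demand.

    Plates are numbered globally 1..(n_batches*plates_per_batch); within each
    batch the first half use layout 1 and the second half layout 2.
    """

    def __init__(self, cohort_spec: CohortSpec, plan: ExperimentPlan,
                 seed: int = 0, *, noiseless: bool = False):
        plan.validate()
        cohort_spec.validate()
        self.cohort_spec = cohort_spec
        self.plan = plan
        self.seed = int(seed)
        self.noiseless = noiseless
        self.lines, self.pairs = build_cohort(cohort_spec)
        if len(self.lines) != 96:
            raise ConfigurationError(
                f"plate-based study needs 96 lines, cohort produced {len(self.lines)}"
            )
        self.layouts = build_layouts(self.lines, seed)
        self._by_id = {ln.line_id: ln for ln in self.lines}
        self.batch_effects = {
            b: batch_effect_for(b, seed, noiseless=noiseless)
            for b in range(1, plan.n_batches + 1)
        }
        self.manifest = self._build_manifest()

    def _build_manifest(self) -> pd.DataFrame:
        plan = self.plan
        rows = []
        plate = 0
        for b in range(1, plan.n_batches + 1):
            for half, layout in enumerate(self.layouts):
                for _ in range(plan.plates_per_layout_per_batch):
                    plate += 1
                    frame = layout.to_frame()
                    for wrow in frame.itertuples(index=False):
                        ln = self._by_id[wrow.line_id]
                        for t in range(plan.tiles_per_well):
                            rows.append({
                                "batch": b, "plate": plate,
                                "layout": layout.layout_id, "well": wrow.well,
                                "tile": t, "line_id": ln.line_id,
                                "donor_id": ln.donor_id,
                                "biopsy_index": ln.biopsy_index,
                                "disease_state": ln.disease_state,
                                "mutation_group": ln.mutation_group,
                                "age": ln.age, "sex": ln.sex,
                                "pair_id": -1 if ln.pair_id is None else ln.pair_id,
                                "path": f"b{b:02d}/p{plate:02d}/"
                                        f"{wrow.well}_t{t:02d}.tiff",
                            })
        return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    def tile(self, row, *, with_masks: bool = False):
        """Render the tile for one manifest row (namedtuple/Series/dict)."""
        get = row.get if hasattr(row, "get") else lambda k: getattr(row, k)
        line = self._by_id[int(get("line_id"))]
        return render_tile(
            line, self.batch_effects[int(get("batch"))], self.plan,
            get("well"), int(get("tile")), self.seed,
            plate=int(get("plate")), with_masks=with_masks,
        )

    def iter_plate(self, batch: int, plate: int):
        """Yield (manifest row, rendered tile) for one plate."""
        sub = self.manifest[(self.manifest.batch == batch)
                            & (self.manifest.plate == plate)]
        for row in sub.itertuples(index=False):
            yield row, self.tile(row)


def generate_experiment(
    plan: ExperimentPlan,
    cohort_spec: CohortSpec,
    out_dir: str,
    seed: int = 0,
    *,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Render every tile to a multi-page TIFF under ``out_dir`` and write the
    manifest CSV.  Refuses to clobber an existing manifest unless
    ``overwrite=True``."""
    study = SyntheticStudy(cohort_spec, plan, seed)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    if os.path.exists(manifest_path) and not overwrite:
        raise FileExistsError(
            f"manifest already exists at {manifest_path}; pass overwrite=True"
        )
    os.makedirs(out_dir, exist_ok=True)
    for row in study.manifest.itertuples(index=False):
        img = study.tile(row)
        path = os.path.join(out_dir, row.path)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        # pages in channel order DAPI, ER, RNA, AGP, MITO
        tifffile.imwrite(path, np.moveaxis(img, -1, 0), photometric="minisblack")
    study.manifest.to_csv(manifest_path, index=False)
    return study.manifest


def read_tile(path: str) -> np.ndarray:
    """Read a study TIFF back as (H, W, 5) uint16."""
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != 5:
        raise ValueError(f"expected a 5-page tile TIFF, got shape {arr.shape}")
    return np.moveaxis(arr, 0, -1)
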