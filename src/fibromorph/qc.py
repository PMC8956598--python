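"""Near-real-time plate quality control: montage and summary report.

The montage samples a seeded random crop from each well of a plate, one column
per Cell Painting channel, so a whole plate can be eyeballed at a glance; the
accompanying statistics table carries the focus proxy and foreground/background
intensity statistics per (well, channel).  The plate report condenses the
statistics into box-plot components (median, quartiles, 1.5 x IQR whiskers,
outliers) per plate and channel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CHANNELS
from .features import image_stats
from .preprocess import PreprocessConfig, preprocess_plate


def _sample_crop(tile: np.ndarray, side: int, rng) -> np.ndarray:
    h, w = tile.shape[:2]
    r0 = int(rng.integers(0, max(h - side, 0) + 1))
    c0 = int(rng.integers(0, max(w - side, 0) + 1))
    return tile[r0:r0 + side, c0:c0 + side]


def qc_montage(study, plate: int, crops_per_well: int = 1, crop_side: int = 32,
               seed: int = 0, preprocess_config: PreprocessConfig | None = None):
    """Montage image + stats table for one plate of a synthetic study.

    Grid: one row per well (96), ``5 * crops_per_well`` columns (channel-major).
    Missing wells yield blank cells and a ``missing`` flag in the stats table.
    Returns ``(uint8 montage, DataFrame)``.
    """
    sub = study.manifest[study.manifest.plate == plate]
    if sub.empty:
        raise ValueError(f"plate {plate} not in study manifest")
    batch = int(sub.batch.iloc[0])
    config = preprocess_config or PreprocessConfig()
    processed = {}
    group = list(study.iter_plate(batch, plate))
    for row, ptile, _centers in preprocess_plate(group, config):
        processed.setdefault(row.well, []).append(ptile)

    wells = sorted(sub.well.unique())
    n_cols = len(CHANNELS) * crops_per_well
    montage = np.zeros((len(wells) * crop_side, n_cols * crop_side), dtype=np.uint8)
    rows = []
    rng = np.random.default_rng(seed)
    for wi, well in enumerate(wells):
        tiles = processed.get(well, [])
        if not tiles:
            rows.extend({"well": well, "channel": ch, "missing": True}
                        for ch in CHANNELS)
            continue
        for k in range(crops_per_well):
            tile = tiles[int(rng.integers(0, len(tiles)))]
            crop = _sample_crop(tile, crop_side, rng)
            stats = image_stats(crop)
            for ci, srow in enumerate(stats.itertuples(index=False)):
                col = ci * crops_per_well + k
                montage[wi * crop_side:(wi + 1) * crop_side,
                        col * crop_side:(col + 1) * crop_side] = crop[:, :, ci]
                rows.append({
                    "well": well, "channel": srow.channel, "missing": False,
                    "focus_score": srow.focus_score, "fg_mean": srow.fg_mean,
                    "fg_std": srow.fg_std, "bg_mean": srow.bg_mean,
                    "bg_std": srow.bg_std, "fg_fraction": srow.fg_fraction,
                })
    stats_table = pd.DataFrame(rows)
    stats_table.insert(0, "plate", plate)
    return montage, stats_table


def box_stats(values) -> dict:
    """Box-plot components: median, quartiles, 1.5 x IQR whiskers, outliers."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {"n": 0}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "n": int(v.size), "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_lo": float(inside.min()), "whisker_hi": float(inside.max()),
        "outliers": sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]),
    }


def qc_plate_report(stats_table: pd.DataFrame,
                    cell_counts: pd.DataFrame | None = None) -> dict:
    """Per-(plate, channel) box-plot summaries of focus and foreground
    intensity, plus per-plate well cell counts when provided."""
    report: dict = {"plates": {}}
    present = stats_table[~stats_table.get("missing", False).astype(bool)] \
        if "missing" in stats_table.columns else stats_table
    for (plate, channel), grp in present.groupby(["plate", "channel"]):
        rec = report["plates"].setdefault(str(plate), {})
        rec[channel] = {
            "focus": box_stats(grp["focus_score"]),
            "fg_mean": box_stats(grp["fg_mean"]),
            "fg_fraction": box_stats(grp["fg_fraction"]),
        }
    if cell_counts is not None:
        for plate, grp in cell_counts.groupby("plate"):
            rec = report["plates"].setdefault(str(plate), {})
            rec["cell_count"] = box_stats(grp["n_cells"])
    return report
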