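"""Image pre-processing: flat-field correction, nucleus detection, 8-bit
conversion and boundary-safe crop extraction.

The background of each (batch, plate, channel) is estimated as the per-pixel
10th-percentile image over all tiles of that plate, blurred with a Gaussian of
sigma 50; dividing by it removes vignetting and gain.  Nuclei are detected in
the corrected DAPI channel with Otsu's threshold and connected components.
Corrected tiles are converted to 8 bits per channel by percentile clipping, a
log transform and linear rescaling to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops


@dataclass(frozen=True)
class PreprocessConfig:
    background_percentile: float = 10.0
    background_sigma: float = 50.0
    clip_lo_percentile: float = 0.001   # from the bottom
    clip_hi_percentile: float = 1.0     # from the top (i.e. the 99.0th)
    detect_sigma: float = 2.0
    min_object_area: int = 80
    crop_side: int = 512


def estimate_background(tiles, percentile: float = 10.0,
                        blur_sigma: float = 50.0,
                        eps: float = 1e-6) -> np.ndarray:
    """Per-pixel ``percentile`` image of a single-channel tile stack, blurred.

    ``tiles`` is an iterable of equally-shaped 2-D arrays (one channel of every
    tile of one batch+plate).  Uses linear-interpolation percentiles; the
    result is floored at ``eps`` so it can safely divide.
    """
    stack = np.stack([np.asarray(t, dtype=np.float64) for t in tiles])
    if stack.ndim != 3:
        raise ValueError("estimate_background expects 2-D single-channel tiles")
    if stack.shape[0] == 0:
        raise ValueError("empty tile stack")
    field = np.percentile(stack, percentile, axis=0)
    field = gaussian_filter(field, blur_sigma)
    return np.maximum(field, eps)


def flatfield_correct(raw: np.ndarray, fields: np.ndarray) -> np.ndarray:
    """Divide each channel of ``raw`` (H, W, C) by its background field.

    ``fields`` is (H, W, C) or, for a single channel, (H, W).
    """
    raw = np.asarray(raw, dtype=np.float64)
    fields = np.asarray(fields, dtype=np.float64)
    if fields.ndim == 2:
        fields = fields[:, :, None]
        raw2 = raw[:, :, None] if raw.ndim == 2 else raw
    else:
        raw2 = raw
    if raw2.shape != fields.shape:
        raise ValueError(f"shape mismatch: raw {raw2.shape} vs fields {fields.shape}")
    if np.any(fields <= 0):
        raise ValueError("background field has non-positive entries")
    out = raw2 / fields
    return out[:, :, 0] if raw.ndim == 2 else out


def detect_nuclei(dapi: np.ndarray, min_object_area: int = 80,
                  smoothing_sigma: float = 2.0) -> list[tuple[float, float]]:
    """Detect nucleus centers in a 2-D DAPI image.

    Gaussian smoothing, Otsu threshold, 8-connected components, area filter;
    returns 0-based (row, col) centroids.  Degenerate images yield an empty
    list rather than an error.
    """
    img = np.asarray(dapi, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("detect_nuclei expects a 2-D image")
    if img.max() == img.min():
        return []
    if smoothing_sigma > 0:
        img = gaussian_filter(img, smoothing_sigma)
        if img.max() == img.min():
            return []
    thr = threshold_otsu(img)
    mask = img > thr
    lab = label(mask, connectivity=2)
    centers = []
    for rp in regionprops(lab):
        if rp.area >= min_object_area:
            centers.append((float(rp.centroid[0]), float(rp.centroid[1])))
    return centers


def to_8bit(corrected: np.ndarray, clip_lo_percentile: float = 0.001,
            clip_hi_percentile: float = 1.0) -> np.ndarray:
    """Convert a float (H, W, C) tile to 8 bits per channel.

    Per channel: clip to the ``clip_lo_percentile``-th percentile from the
    bottom and the ``clip_hi_percentile``-th from the top, apply a fixed log
    curve ``log1p(255 * d) / log1p(255)`` to the normalized clipped values
    ``d`` and rescale to [0, 255].  Normalizing before the log makes the
    conversion invariant to positive rescaling of the input; a channel with
    zero dynamic range after clipping maps to all zeros.
    """
    arr = np.asarray(corrected, dtype=np.float64)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    if not np.all(np.isfinite(arr)):
        raise ValueError("to_8bit requires finite values")
    out = np.zeros(arr.shape, dtype=np.uint8)
    for c in range(arr.shape[2]):
        ch = arr[:, :, c]
        lo = np.percentile(ch, clip_lo_percentile)
        hi = np.percentile(ch, 100.0 - clip_hi_percentile)
        if hi <= lo:
            continue  # degenerate channel stays zero
        d = (np.clip(ch, lo, hi) - lo) / (hi - lo)
        curve = np.log1p(255.0 * d) / np.log1p(255.0)
        out[:, :, c] = np.rint(255.0 * curve).astype(np.uint8)
    return out[:, :, 0] if squeeze else out


def extract_crops(tile: np.ndarray, centers, side: int = 512):
    """Extract ``side`` x ``side`` crops centered on nuclei.

    The nucleus center lands on pixel index ``side // 2`` of the crop
    (0-based).  Crops that would cross the tile boundary are skipped; returns
    ``(crops, kept_centers, n_excluded)``.
    """
    tile = np.asarray(tile)
    h, w = tile.shape[:2]
    if side > h or side > w:
        raise ValueError(f"crop side {side} exceeds tile dimensions {(h, w)}")
    half = side // 2
    crops, kept, excluded = [], [], 0
    for (r, c) in centers:
        r0 = int(round(r)) - half
        c0 = int(round(c)) - half
        if r0 < 0 or c0 < 0 or r0 + side > h or c0 + side > w:
            excluded += 1
            continue
        crops.append(tile[r0:r0 + side, c0:c0 + side])
        kept.append((r, c))
    return crops, kept, excluded


def preprocess_plate(tiles_and_rows, config: PreprocessConfig = PreprocessConfig()):
    """Run the full pre-processing chain on one plate.

    ``tiles_and_rows`` is a list of (manifest row, raw (H, W, 5) tile).
    Returns a list of (row, processed 8-bit tile, nucleus centers).
    """
    rows = [r for r, _ in tiles_and_rows]
    raws = [t for _, t in tiles_and_rows]
    if not raws:
        raise ValueError("empty plate")
    nch = raws[0].shape[2]
    fields = np.stack(
        [estimate_background((t[:, :, c] for t in raws),
                             config.background_percentile,
                             config.background_sigma)
         for c in range(nch)], axis=-1)
    out = []
    for row, raw in zip(rows, raws):
        corrected = flatfield_correct(raw, fields)
        centers = detect_nuclei(corrected[:, :, 0], config.min_object_area,
                                config.detect_sigma)
        processed = to_8bit(corrected, config.clip_lo_percentile,
                            config.clip_hi_percentile)
        out.append((row, processed, centers))
    return out
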