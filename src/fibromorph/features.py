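"""Engineered single-cell features: segmentation, area/shape, intensity,
radial distribution, granularity, texture, and tile-level image statistics.

These re-create the feature families that make image-based profiles
interpretable (the counterpart of a CellProfiler-style pipeline, reduced to a
representative set rather than the full several-thousand-feature catalogue):
Nuclei are segmented in the DAPI channel, Cells in the RNA channel by seeded
watershed, and Cytoplasm is the per-object set difference Cells minus Nuclei.
Feature names follow the ``Compartment_Family_Channel_Parameter`` convention
so they can be grouped by measurement type and compartment/channel downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk, opening
from skimage.segmentation import watershed

from .cohort import CHANNELS

COMPARTMENTS = ("Cells", "Nuclei", "Cytoplasm", "Image")
FAMILIES = ("AreaShape", "Intensity", "RadialDistribution", "Granularity", "Texture")


@dataclass(frozen=True)
class FeatureName:
    """Structured feature name rendering to ``Compartment_Family[_Channel]_Parameter``."""

    compartment: str
    family: str
    channel: str  # one of CHANNELS or "none"
    parameter: str

    def render(self) -> str:
        if self.channel == "none":
            return f"{self.compartment}_{self.family}_{self.parameter}"
        return f"{self.compartment}_{self.family}_{self.channel}_{self.parameter}"

    @classmethod
    def parse(cls, name: str) -> "FeatureName":
        parts = name.split("_")
        if len(parts) < 3:
            raise ValueError(f"unparseable feature name {name!r}")
        comp, family = parts[0], parts[1]
        if comp not in COMPARTMENTS or family not in FAMILIES:
            raise ValueError(f"unparseable feature name {name!r}")
        if parts[2] in CHANNELS:
            if len(parts) < 4:
                raise ValueError(f"unparseable feature name {name!r}")
            return cls(comp, family, parts[2], "_".join(parts[3:]))
        return cls(comp, family, "none", "_".join(parts[2:]))


@dataclass
class SegmentationResult:
    nuclei_labels: np.ndarray
    cell_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    n_objects: int


def segment_cells(tile8: np.ndarray, centers) -> SegmentationResult:
    """Segment Nuclei (DAPI, Otsu components at the detected centers), Cells
    (seeded watershed on the thresholded RNA channel, constrained to contain
    their nucleus) and Cytoplasm (cell minus nucleus); labels are consistent
    across the three images."""
    tile8 = np.asarray(tile8)
    dapi = tile8[:, :, 0].astype(float)
    rna = tile8[:, :, 2].astype(float)
    h, w = dapi.shape
    if not centers or dapi.max() == dapi.min():
        z = np.zeros((h, w), dtype=np.int32)
        return SegmentationResult(z, z.copy(), z.copy(), 0)

    nuc_mask = dapi > threshold_otsu(dapi)
    comp = label(nuc_mask, connectivity=2)
    # keep only components holding a detected center; relabel 1..n in center order
    nuclei = np.zeros((h, w), dtype=np.int32)
    markers = np.zeros((h, w), dtype=np.int32)
    nid = 0
    used = set()
    for (r, c) in centers:
        ri, ci = int(round(r)), int(round(c))
        ri = min(max(ri, 0), h - 1)
        ci = min(max(ci, 0), w - 1)
        comp_id = comp[ri, ci]
        if comp_id == 0 or comp_id in used:
            continue
        used.add(comp_id)
        nid += 1
        nuclei[comp == comp_id] = nid
        markers[comp == comp_id] = nid
    if nid == 0:
        z = np.zeros((h, w), dtype=np.int32)
        return SegmentationResult(z, z.copy(), z.copy(), 0)

    if rna.max() > rna.min():
        cell_fg = rna > threshold_otsu(rna)
    else:
        cell_fg = np.zeros((h, w), dtype=bool)
    mask = cell_fg | (nuclei > 0)
    cells = watershed(-rna, markers=markers, mask=mask)
    cells = np.where(nuclei > 0, nuclei, cells).astype(np.int32)
    cytoplasm = np.where(nuclei > 0, 0, cells).astype(np.int32)
    return SegmentationResult(nuclei, cells, cytoplasm, nid)


# ---------------------------------------------------------------------------
# per-object feature families


def shape_features(labels: np.ndarray) -> pd.DataFrame:
    """Area, perimeter, eccentricity, form factor 4*pi*A/P^2, solidity and
    equivalent diameter per labeled object."""
    rows = []
    for rp in regionprops(np.asarray(labels)):
        per = rp.perimeter
        rows.append({
            "object": rp.label,
            "Area": float(rp.area),
            "Perimeter": float(per),
            "Eccentricity": float(rp.eccentricity),
            "FormFactor": float(4 * np.pi * rp.area / per ** 2) if per > 0 else 0.0,
            "Solidity": float(rp.solidity),
            "EquivalentDiameter": float(rp.equivalent_diameter_area),
        })
    return pd.DataFrame(rows, columns=["object", "Area", "Perimeter", "Eccentricity",
                                       "FormFactor", "Solidity", "EquivalentDiameter"])


def intensity_features(labels: np.ndarray, image: np.ndarray) -> pd.DataFrame:
    """Mean/integrated/SD/min/max intensity and mass displacement (distance
    between the binary and the intensity-weighted centroid) per object."""
    labels = np.asarray(labels)
    image = np.asarray(image, dtype=np.float64)
    if labels.shape != image.shape:
        raise ValueError("label and intensity images must share a shape")
    rows = []
    for rp in regionprops(labels, intensity_image=image):
        vals = rp.image_intensity[rp.image]
        total = float(vals.sum())
        if total > 0:
            wc = rp.centroid_weighted
            md = float(np.hypot(wc[0] - rp.centroid[0], wc[1] - rp.centroid[1]))
        else:
            md = 0.0
        rows.append({
            "object": rp.label,
            "MeanIntensity": float(vals.mean()),
            "IntegratedIntensity": total,
            "StdIntensity": float(vals.std()),
            "MinIntensity": float(vals.min()),
            "MaxIntensity": float(vals.max()),
            "MassDisplacement": md,
        })
    return pd.DataFrame(rows, columns=["object", "MeanIntensity", "IntegratedIntensity",
                                       "StdIntensity", "MinIntensity", "MaxIntensity",
                                       "MassDisplacement"])


def _normalized_distance(mask: np.ndarray, centroid: tuple[float, float]) -> np.ndarray:
    """Normalized centroid-to-boundary distance in [0, 1] for each object pixel:
    d_centroid / (d_centroid + d_edge), with d_edge the Euclidean distance to
    the object boundary."""
    yy, xx = np.nonzero(mask)
    d_cent = np.hypot(yy - centroid[0], xx - centroid[1])
    edt = ndimage.distance_transform_edt(mask)
    d_edge = edt[yy, xx] - 0.5  # pixel-center offset to the boundary
    d_edge = np.clip(d_edge, 0.0, None)
    denom = d_cent + d_edge
    frac = np.where(denom > 0, d_cent / np.maximum(denom, 1e-12), 0.0)
    return np.clip(frac, 0.0, 1.0)


def radial_distribution(labels: np.ndarray, image: np.ndarray,
                        n_rings: int = 4) -> pd.DataFrame:
    """FracAtD per object: fraction of total object intensity in each of
    ``n_rings`` equal-width normalized-distance rings from centroid to
    boundary.  Zero-intensity objects get a uniform fill and a QC flag."""
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    labels = np.asarray(labels)
    image = np.asarray(image, dtype=np.float64)
    rows = []
    for rp in regionprops(labels):
        sl = rp.slice
        mask = labels[sl] == rp.label
        vals = image[sl][mask]
        cy = rp.centroid[0] - sl[0].start
        cx = rp.centroid[1] - sl[1].start
        frac_d = _normalized_distance(mask, (cy, cx))
        ring = np.minimum((frac_d * n_rings).astype(int), n_rings - 1)
        total = vals.sum()
        row = {"object": rp.label, "DegenerateIntensity": total <= 0}
        if total <= 0:
            for k in range(n_rings):
                row[f"FracAtD{k + 1}"] = 1.0 / n_rings
        else:
            for k in range(n_rings):
                row[f"FracAtD{k + 1}"] = float(vals[ring == k].sum() / total)
        rows.append(row)
    cols = ["object"] + [f"FracAtD{k + 1}" for k in range(n_rings)] + ["DegenerateIntensity"]
    return pd.DataFrame(rows, columns=cols)


def granularity(image: np.ndarray, scales=range(1, 17)) -> np.ndarray:
    """Granular spectrum of a grayscale image by successive grayscale openings
    with disk structuring elements.

    ``g_k = 100 * (I(open at k-1) - I(open at k)) / I(original)`` where I is
    the total intensity; scale 0 means the original image.  A zero-intensity
    image yields an all-zero spectrum.
    """
    img = np.asarray(image, dtype=np.float64)
    scales = list(scales)
    if any(b <= a for a, b in zip(scales, scales[1:])) or any(s < 1 for s in scales):
        raise ValueError("scales must be increasing positive integers")
    total = img.sum()
    if total <= 0:
        return np.zeros(len(scales))
    spectrum = np.zeros(len(scales))
    prev = img.sum()
    for i, s in enumerate(scales):
        opened = opening(img, disk(s))
        cur = opened.sum()
        spectrum[i] = 100.0 * (prev - cur) / total
        prev = cur
    return spectrum


def _cooccurrence(quantized: np.ndarray, valid: np.ndarray, offset: int,
                  n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence matrix over horizontal+vertical pixel pairs
    whose both members lie inside the object mask."""
    P = np.zeros((n_levels, n_levels), dtype=np.float64)
    for (dy, dx) in ((0, offset), (offset, 0)):
        a = quantized[: quantized.shape[0] - dy, : quantized.shape[1] - dx]
        b = quantized[dy:, dx:]
        va = valid[: valid.shape[0] - dy, : valid.shape[1] - dx]
        vb = valid[dy:, dx:]
        ok = va & vb
        np.add.at(P, (a[ok], b[ok]), 1.0)
    P = P + P.T
    s = P.sum()
    return P / s if s > 0 else P


def texture_features(labels: np.ndarray, image: np.ndarray,
                     offsets=(1, 3), n_levels: int = 8,
                     min_pixels: int = 9) -> pd.DataFrame:
    """Gray-level co-occurrence contrast, correlation and entropy per object at
    the given pixel offsets.  Levels are re-binned per object between its min
    and max gray value (so the features are offset-invariant); degenerate
    single-level objects get contrast 0, correlation 0, entropy 0."""
    labels = np.asarray(labels)
    image = np.asarray(image, dtype=np.float64)
    rows = []
    lv = np.arange(n_levels, dtype=np.float64)
    for rp in regionprops(labels):
        sl = rp.slice
        mask = labels[sl] == rp.label
        patch = image[sl]
        row = {"object": rp.label}
        vals = patch[mask]
        lo, hi = vals.min(), vals.max()
        degenerate = rp.area < min_pixels or hi <= lo
        for off in offsets:
            suffix = f"Offset{off}"
            if degenerate:
                row[f"Contrast_{suffix}"] = 0.0
                row[f"Correlation_{suffix}"] = 0.0
                row[f"Entropy_{suffix}"] = 0.0
                continue
            q = np.clip(((patch - lo) / (hi - lo) * n_levels).astype(int),
                        0, n_levels - 1)
            P = _cooccurrence(q, mask, off, n_levels)
            if P.sum() == 0:
                row[f"Contrast_{suffix}"] = 0.0
                row[f"Correlation_{suffix}"] = 0.0
                row[f"Entropy_{suffix}"] = 0.0
                continue
            ii, jj = np.meshgrid(lv, lv, indexing="ij")
            contrast = float(((ii - jj) ** 2 * P).sum())
            mu_i = float((ii * P).sum())
            mu_j = float((jj * P).sum())
            var_i = float(((ii - mu_i) ** 2 * P).sum())
            var_j = float(((jj - mu_j) ** 2 * P).sum())
            if var_i > 0 and var_j > 0:
                corr = float((((ii - mu_i) * (jj - mu_j) * P).sum())
                             / np.sqrt(var_i * var_j))
            else:
                corr = 0.0
            nz = P[P > 0]
            entropy = float(-(nz * np.log2(nz)).sum())
            row[f"Contrast_{suffix}"] = contrast
            row[f"Correlation_{suffix}"] = corr
            row[f"Entropy_{suffix}"] = entropy
        rows.append(row)
    cols = ["object"] + [f"{p}_Offset{o}" for o in offsets
                         for p in ("Contrast", "Correlation", "Entropy")]
    return pd.DataFrame(rows, columns=["object"] + sorted(set(cols) - {"object"}))


# ---------------------------------------------------------------------------
# tile-level statistics


def focus_score(channel: np.ndarray) -> float:
    """Sharpness proxy in [0, 1]: saturating transform of the variance of the
    Laplacian of the [0, 1]-normalized image.  Blurring strictly reduces it;
    a constant image scores 0."""
    img = np.asarray(channel, dtype=np.float64)
    if img.max() == img.min():
        return 0.0
    img = (img - img.min()) / (img.max() - img.min())
    lap = ndimage.laplace(img)
    v = float(lap.var())
    return v / (v + 0.01)


def image_stats(tile8: np.ndarray) -> pd.DataFrame:
    """Per-channel tile statistics: focus proxy, Otsu foreground/background
    mean and SD, and foreground fraction."""
    tile8 = np.asarray(tile8)
    rows = []
    for ci, ch_name in enumerate(CHANNELS):
        ch = tile8[:, :, ci].astype(np.float64)
        row = {"channel": ch_name, "focus_score": focus_score(ch)}
        if ch.max() == ch.min():
            row.update(fg_mean=0.0, fg_std=0.0, bg_mean=float(ch.mean()),
                       bg_std=0.0, fg_fraction=0.0)
        else:
            thr = threshold_otsu(ch)
            fg = ch > thr
            bg = ~fg
            row.update(
                fg_mean=float(ch[fg].mean()) if fg.any() else 0.0,
                fg_std=float(ch[fg].std()) if fg.any() else 0.0,
                bg_mean=float(ch[bg].mean()) if bg.any() else 0.0,
                bg_std=float(ch[bg].std()) if bg.any() else 0.0,
                fg_fraction=float(fg.mean()),
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assembly: per-cell feature vectors for one tile

GRANULARITY_SCALES = (1, 2, 3, 4, 6, 8)


def extract_cell_features(tile8: np.ndarray, seg: SegmentationResult,
                          granularity_scales=GRANULARITY_SCALES,
                          radial_rings: int = 4) -> pd.DataFrame:
    """Per-cell feature table for one processed tile.

    Columns follow the ``Compartment_Family[_Channel]_Parameter`` convention:
    AreaShape per compartment, Intensity per compartment x channel, radial
    distribution of the RNA and AGP channels within Cells, per-object texture
    in every channel, and the tile-level granularity spectrum per channel
    (replicated onto each cell, as image-scoped measurements).  Undefined
    values for degenerate objects are 0 with the ``QC_DegenerateObject`` flag.
    """
    tile8 = np.asarray(tile8)
    if seg.n_objects == 0:
        return pd.DataFrame()
    comp_labels = {"Cells": seg.cell_labels, "Nuclei": seg.nuclei_labels,
                   "Cytoplasm": seg.cytoplasm_labels}
    objects = np.arange(1, seg.n_objects + 1)
    data: dict = {"object": objects}
    degenerate = np.zeros(len(objects), dtype=bool)

    for comp, lab in comp_labels.items():
        sf = shape_features(lab).set_index("object")
        sf = sf.reindex(objects)
        missing = sf["Area"].isna()
        degenerate |= missing.to_numpy()
        sf = sf.fillna(0.0)
        for col in sf.columns:
            data[f"{comp}_AreaShape_{col}"] = sf[col].to_numpy()
        for ci, ch_name in enumerate(CHANNELS):
            itf = intensity_features(lab, tile8[:, :, ci]).set_index("object")
            itf = itf.reindex(objects).fillna(0.0)
            for col in itf.columns:
                data[f"{comp}_Intensity_{ch_name}_{col}"] = itf[col].to_numpy()

    for ch_name in ("RNA", "AGP"):
        ci = CHANNELS.index(ch_name)
        rd = radial_distribution(seg.cell_labels, tile8[:, :, ci],
                                 n_rings=radial_rings).set_index("object")
        rd = rd.reindex(objects)
        degenerate |= rd["DegenerateIntensity"].fillna(True).astype(bool).to_numpy()
        rd = rd.drop(columns="DegenerateIntensity").fillna(0.0)
        for col in rd.columns:
            data[f"Cells_RadialDistribution_{ch_name}_{col}"] = rd[col].to_numpy()

    for ci, ch_name in enumerate(CHANNELS):
        tf = texture_features(seg.cell_labels, tile8[:, :, ci]).set_index("object")
        tf = tf.reindex(objects).fillna(0.0)
        for col in tf.columns:
            data[f"Cells_Texture_{ch_name}_{col}"] = tf[col].to_numpy()

    for ci, ch_name in enumerate(CHANNELS):
        spec = granularity(tile8[:, :, ci].astype(float), granularity_scales)
        for k, s in enumerate(granularity_scales):
            data[f"Image_Granularity_{ch_name}_G{s}"] = np.full(len(objects), spec[k])

    data["QC_DegenerateObject"] = degenerate
    return pd.DataFrame(data)


def feature_value_columns(df: pd.DataFrame) -> list[str]:
    """Columns of ``df`` that parse as feature names."""
    cols = []
    for c in df.columns:
        try:
            FeatureName.parse(c)
            cols.append(c)
        except ValueError:
            continue
    return cols
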