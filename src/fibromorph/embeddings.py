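"""Fixed-backbone deep image embeddings with seeded random projection.

Each channel of an 8-bit crop or tile is replicated to three channels, resized
to the backbone's input side and pushed through a fixed (never trained here)
backbone network; the activations are randomly projected to 64 dimensions and
the five channel vectors concatenated into a 320-dimensional embedding in the
fixed block order [DAPI | ER | RNA | AGP | MITO].

The backbone is a pluggable contract.  The in-repo :class:`PoolingBackbone` is
a deterministic multiscale mean/max/gradient pooling featurizer (D = 256) so
the whole pipeline runs offline and bit-reproducibly; any ImageNet-pretrained
Inception-style network exposing the same contract can be slotted in instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from .cohort import CHANNELS

EMBED_DIM = 64
N_CHANNELS = 5


@dataclass(frozen=True)
class ProjectionSpec:
    """A D x 64 Gaussian random projection, exactly regenerable from its seed."""

    matrix: np.ndarray
    seed: int
    rule: str = "gaussian-iid/sqrt64"

    @property
    def in_dim(self) -> int:
        return self.matrix.shape[0]

    def to_json(self) -> str:
        return json.dumps({"in_dim": self.in_dim, "seed": self.seed, "rule": self.rule})

    @classmethod
    def from_json(cls, s: str) -> "ProjectionSpec":
        d = json.loads(s)
        if d["rule"] != "gaussian-iid/sqrt64":
            raise ValueError(f"unknown projection rule {d['rule']!r}")
        return make_projection(d["in_dim"], d["seed"])


def make_projection(D: int, seed: int) -> ProjectionSpec:
    """i.i.d. N(0, 1) entries scaled by 1/sqrt(64): norm-preserving in
    expectation (Johnson-Lindenstrauss style)."""
    if D < EMBED_DIM:
        raise ValueError(f"backbone output dim {D} must be >= {EMBED_DIM}")
    rng = np.random.default_rng(seed)
    mat = rng.standard_normal((D, EMBED_DIM)) / np.sqrt(EMBED_DIM)
    return ProjectionSpec(matrix=mat, seed=int(seed))


class PoolingBackbone:
    """Deterministic multiscale featurizer (the offline stand-in backbone).

    Feature map over the grayscale of the 3-channel input: mean pools on
    2x2/4x4/8x8 grids, max pools on 2x2/4x4, gradient-magnitude mean pools on
    the same grids, intensity and gradient quantiles, band-pass
    (difference-of-Gaussians) texture energies, Laplacian energies, and
    foreground fractions at fixed thresholds; D = 256.  It is not a trained
    network, but it is sensitive to the same image attributes a pretrained
    backbone's activations respond to — brightness layout, texture scale,
    edge density, object area — while being exactly reproducible offline.
    """

    identifier = "pool-v1"
    input_side = 64
    output_dim = 256

    def evaluate(self, image3: np.ndarray) -> np.ndarray:
        from scipy.ndimage import gaussian_filter, laplace

        img = np.asarray(image3, dtype=np.float64)
        if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] != img.shape[1]:
            raise ValueError("backbone expects a square 3-channel image")
        if img.shape[0] != self.input_side:
            raise ValueError(f"backbone input side must be {self.input_side}")
        gray = img.mean(axis=2)
        gy, gx = np.gradient(gray)
        grad = np.hypot(gy, gx)
        n = self.input_side
        feats = []
        for s in (2, 4, 8):
            blocks = gray.reshape(s, n // s, s, n // s)
            feats.append(blocks.mean(axis=(1, 3)).ravel())
        for s in (2, 4):
            blocks = gray.reshape(s, n // s, s, n // s)
            feats.append(blocks.max(axis=(1, 3)).ravel())
        for s in (2, 4, 8):
            gblocks = grad.reshape(s, n // s, s, n // s)
            feats.append(gblocks.mean(axis=(1, 3)).ravel())
        qs = np.linspace(2, 98, 21)
        feats.append(np.percentile(gray, qs))
        feats.append(np.percentile(grad, qs))
        smoothed = [gaussian_filter(gray, sig) for sig in (0.0, 1.0, 2.0, 4.0, 8.0)]
        feats.append(np.array([  # band-pass texture energy per octave
            np.sqrt(((a - b) ** 2).mean()) for a, b in zip(smoothed, smoothed[1:])
        ]))
        feats.append(np.array([np.abs(laplace(s_)).mean() for s_ in smoothed[:3]]))
        thresholds = np.linspace(0.1, 0.9, 15)
        span = gray.max() - gray.min()
        rel = (gray - gray.min()) / span if span > 0 else np.zeros_like(gray)
        feats.append(np.array([(rel > t).mean() for t in thresholds]))
        feats.append(np.array([gray.mean(), gray.std(), gray.min(), gray.max()]))
        out = np.concatenate(feats)
        assert out.shape[0] == self.output_dim, out.shape
        return out


class MeanPoolBackbone:
    """Purely linear backbone (mean-pooled 8x8 patches); used to exercise
    linearity-sensitive contracts."""

    identifier = "meanpool-v1"
    input_side = 64
    output_dim = 64

    def evaluate(self, image3: np.ndarray) -> np.ndarray:
        img = np.asarray(image3, dtype=np.float64)
        gray = img.mean(axis=2)
        return gray.reshape(8, 8, 8, 8).mean(axis=(1, 3)).ravel()


def _prepare_channel(image2d: np.ndarray, side: int) -> np.ndarray:
    """Scale 8-bit pixels to [0, 1] and bilinearly resize to the backbone side."""
    img = np.asarray(image2d, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("embed_channel expects a single-channel 2-D image")
    img = img / 255.0
    if img.shape != (side, side):
        img = resize(img, (side, side), order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True)
    return img


def embed_channel(image2d: np.ndarray, backbone, projection: ProjectionSpec) -> np.ndarray:
    """64-vector for one channel: projection^T . backbone(replicate3(image))."""
    if projection.in_dim != backbone.output_dim:
        raise ValueError(
            f"projection input dim {projection.in_dim} != backbone output dim "
            f"{backbone.output_dim}")
    img = _prepare_channel(image2d, backbone.input_side)
    acts = backbone.evaluate(np.repeat(img[:, :, None], 3, axis=2))
    return projection.matrix.T @ acts


def embed_multichannel(image5: np.ndarray, backbone, projection: ProjectionSpec) -> np.ndarray:
    """320-vector: concatenation of the five per-channel embeddings in the
    fixed order DAPI, ER, RNA, AGP, MITO."""
    image5 = np.asarray(image5)
    if image5.ndim != 3 or image5.shape[2] != N_CHANNELS:
        raise ValueError(f"expected an (H, W, {N_CHANNELS}) image, got {image5.shape}")
    return np.concatenate([
        embed_channel(image5[:, :, c], backbone, projection)
        for c in range(N_CHANNELS)
    ])


def embedding_columns() -> list[str]:
    return [f"e{i:03d}" for i in range(N_CHANNELS * EMBED_DIM)]


def channel_block(channel: str) -> slice:
    """Column slice of one channel's 64-block within the 320-vector."""
    idx = CHANNELS.index(channel)
    return slice(idx * EMBED_DIM, (idx + 1) * EMBED_DIM)


def embed_table(items, backbone, projection: ProjectionSpec,
                meta_cols=None) -> pd.DataFrame:
    """Embed an iterable of (metadata dict, 5-channel image) into a columnar
    table with provenance keys + e000..e319."""
    rows = []
    for meta, img in items:
        vec = embed_multichannel(img, backbone, projection)
        row = dict(meta)
        row.update(zip(embedding_columns(), vec))
        rows.append(row)
    return pd.DataFrame(rows)
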