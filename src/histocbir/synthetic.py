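"""Synthetic fixtures: labeled patch images and class-structured feature banks.

These generators exist to validate the retrieval machinery offline with
analytically known expectations, not to imitate histology.  Two regimes
matter:

* ``separation = 0``: items are exchangeable isotropic Gaussian noise, so
  for balanced classes of size m in a bank of N the expected P@k of
  leave-one-out retrieval is exactly (m − 1)/(N − 1) for every k.
* ``separation ≫ noise_sd``: each class collapses onto its own orthogonal
  centroid, so MAP@k = 1 exactly whenever k ≤ m − 1.

One seed in the spec governs every random draw; the same spec always
reproduces the identical bank, image bytes and manifest.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .bank import FeatureBank, build_bank
from .errors import HistoCBIRError
from .features import FeatureVector
from .registry import Reduction

__all__ = [
    "SyntheticSpec",
    "DEFAULT_CLASS_NAMES",
    "class_names",
    "chance_level",
    "generate_feature_bank",
    "generate_patch_dataset",
]

# the four-class breast-histology benchmark layout this emulates
DEFAULT_CLASS_NAMES = ("benign", "insitu", "invasive", "normal")

# pixel-domain scale factors turning the dimensionless separation / noise_sd
# knobs into 8-bit intensity amplitudes
_BASE_GRAY = 120.0
_DC_AMPLITUDE = 10.0
_TEXTURE_AMPLITUDE = 15.0
_NOISE_AMPLITUDE = 12.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic collection; same spec ⇒ identical output.

    ``separation`` is the distance of each class centroid from the origin in
    units of the per-coordinate noise scale ``noise_sd``; 0 removes all class
    structure.  ``dim`` sizes feature banks, ``patch_size`` sizes images.
    """

    n_classes: int = 4
    per_class: int = 100
    dim: int = 64
    patch_size: int = 64
    separation: float = 4.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.per_class < 2:
            raise ValueError("need at least two items per class")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def n_items(self) -> int:
        return self.n_classes * self.per_class


def class_names(spec: SyntheticSpec) -> list[str]:
    if spec.n_classes == len(DEFAULT_CLASS_NAMES):
        return list(DEFAULT_CLASS_NAMES)
    return [f"class_{c}" for c in range(spec.n_classes)]


def chance_level(spec: SyntheticSpec) -> float:
    """Expected P@k under exchangeability: (m − 1)/(N − 1) for balanced classes."""
    return (spec.per_class - 1) / (spec.n_items - 1)


def _orthonormal_centroids(rng: np.random.Generator, n_classes: int, dim: int) -> np.ndarray:
    if n_classes > dim:
        raise HistoCBIRError(
            f"cannot build {n_classes} orthogonal centroids in {dim} dimensions; "
            "increase dim"
        )
    q, _ = np.linalg.qr(rng.standard_normal((dim, n_classes)))
    return q.T  # rows are orthonormal unit vectors


def generate_feature_bank(spec: SyntheticSpec) -> FeatureBank:
    """Gaussian class-blob feature bank: item = separation·μ_c + noise.

    Centroids are mutually orthogonal unit vectors, so the chance-level and
    perfect-separability limits are exactly analyzable.
    """
    rng = np.random.default_rng(spec.seed)
    centroids = _orthonormal_centroids(rng, spec.n_classes, spec.dim)
    names = class_names(spec)
    vectors: list[FeatureVector] = []
    for c, label in enumerate(names):
        noise = rng.standard_normal((spec.per_class, spec.dim)) * spec.noise_sd
        block = spec.separation * centroids[c] + noise
        for i in range(spec.per_class):
            vectors.append(
                FeatureVector(
                    values=block[i],
                    backbone="synthetic",
                    layer=f"gaussian_dim{spec.dim}",
                    reduction=Reduction.GAP,
                    item_id=f"{label}/{i:03d}",
                    label=label,
                )
            )
    return build_bank(vectors, preprocess="identity", backend=f"synthetic:{spec.seed}")


def _class_color(c: int, n_classes: int) -> np.ndarray:
    # equally spaced hues, centered so the shift changes chroma, not brightness
    rgb = np.array(colorsys.hsv_to_rgb(c / n_classes, 1.0, 1.0))
    return rgb - rgb.mean()


def generate_patch_dataset(spec: SyntheticSpec, out_dir: "str | Path") -> Path:
    """Write labeled RGB PNG patches with class-distinctive color and texture.

    Each class carries a distinct mean-hue shift and a distinct periodic
    texture frequency, both scaled by ``separation``, on top of per-pixel
    Gaussian noise scaled by ``noise_sd``.  Layout: one subdirectory per
    class plus a ``manifest.csv`` (path, label, item_id).  Returns the
    manifest path.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise HistoCBIRError(f"cannot create dataset directory {out_dir}: {exc}") from exc
    rng = np.random.default_rng(spec.seed)
    size = spec.patch_size
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    names = class_names(spec)
    rows = []
    for c, label in enumerate(names):
        color = _class_color(c, spec.n_classes)
        freq = c + 2
        class_dir = out_dir / label
        class_dir.mkdir(exist_ok=True)
        for i in range(spec.per_class):
            phase = rng.uniform(0, 2 * np.pi)
            shifted = np.sin(2 * np.pi * freq * xx / size + phase) * np.cos(
                2 * np.pi * freq * yy / size
            )
            signal = (
                _BASE_GRAY
                + spec.separation * _DC_AMPLITUDE * color[None, None, :]
                + spec.separation * _TEXTURE_AMPLITUDE * color[None, None, :] * shifted[:, :, None]
            )
            noise = rng.standard_normal((size, size, 3)) * spec.noise_sd * _NOISE_AMPLITUDE
            pixels = np.clip(signal + noise, 0, 255).astype(np.uint8)
            filename = f"{label}_{i:03d}.png"
            Image.fromarray(pixels, mode="RGB").save(class_dir / filename)
            rows.append(
                {
                    "path": f"{label}/{filename}",
                    "label": label,
                    "item_id": f"{label}/{label}_{i:03d}",
                }
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
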