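"""Extractor backends: pluggable forward passes to a named backbone layer.

The retrieval method is weight-agnostic plumbing around *some* convolutional
feature extractor, so the backend is an injected interface rather than a hard
dependency.  Two implementations ship:

* :class:`SeededRandomBackend` — a deterministic, architecture-shaped random
  feature extractor: the input is spatially pooled to the layer's H×W grid
  and its three colour channels are mixed into C channels by a fixed,
  seed-derived random projection.  It needs no deep-learning framework and no
  weight download, runs anywhere, and preserves chromatic/texture structure
  well enough for end-to-end pipeline validation.
* :class:`KerasBackend` — forwards through the real ImageNet-pretrained
  network via ``tensorflow.keras`` (optional extra ``histocbir[pretrained]``).

Any object with the same ``extract_batch`` signature can be substituted.
"""

from __future__ import annotations

import zlib
from typing import Protocol, runtime_checkable

import numpy as np
from PIL import Image

from .errors import ConfigurationError
from .registry import get_backbone, get_layer

__all__ = ["ExtractorBackend", "SeededRandomBackend", "KerasBackend", "make_backend"]


@runtime_checkable
class ExtractorBackend(Protocol):
    """Forward-pass contract: a batch of S×S×3 inputs → batch of H×W×C maps."""

    name: str

    def extract_batch(
        self, backbone: str, layer: str, batch: np.ndarray
    ) -> np.ndarray: ...


def _spatial_resize(plane: np.ndarray, height: int, width: int) -> np.ndarray:
    """Bilinear resample of one float channel plane to an exact (height, width)."""
    img = Image.fromarray(plane.astype(np.float32), mode="F")
    return np.asarray(img.resize((width, height), Image.Resampling.BILINEAR), dtype=np.float64)


class SeededRandomBackend:
    """Deterministic random-projection feature extractor shaped like the registry.

    For layer (H, W, C) the input image is bilinearly pooled onto the H×W
    grid and the 3 colour channels are mixed into C output channels with a
    fixed Gaussian matrix drawn from a seed derived per (seed, backbone,
    layer).  Same seed ⇒ bit-identical features; different layers see
    different projections.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self.name = f"seeded-random:{self.seed}"
        self._projections: dict[tuple[str, str], np.ndarray] = {}

    def _projection(self, backbone: str, layer: str, channels: int) -> np.ndarray:
        key = (backbone, layer)
        if key not in self._projections:
            derived = zlib.crc32(f"{self.seed}:{backbone}:{layer}".encode()) & 0x7FFFFFFF
            rng = np.random.default_rng(derived)
            self._projections[key] = rng.standard_normal((3, channels)) / np.sqrt(3.0)
        return self._projections[key]

    def extract_batch(self, backbone: str, layer: str, batch: np.ndarray) -> np.ndarray:
        spec = get_layer(backbone, layer)
        size = get_backbone(backbone).input_size
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim == 3:
            batch = batch[None]
        if batch.shape[1:] != (size, size, 3):
            raise ConfigurationError(
                f"backend expects inputs of shape ({size}, {size}, 3) for "
                f"{backbone}, got {batch.shape[1:]}"
            )
        proj = self._projection(backbone, layer, spec.channels)
        out = np.empty((batch.shape[0],) + spec.shape, dtype=np.float64)
        for i, img in enumerate(batch):
            pooled = np.stack(
                [_spatial_resize(img[:, :, ch], spec.height, spec.width) for ch in range(3)],
                axis=-1,
            )
            out[i] = pooled @ proj
        return out


class KerasBackend:
    """Forward pass through the real pretrained network via tensorflow.keras.

    Requires the optional ``tensorflow`` dependency and (on first use) a
    download of the ImageNet weights.  Models are built lazily and cached per
    (backbone, layer).
    """

    _CONSTRUCTORS = {
        "VGG16": ("vgg16", "VGG16"),
        "InceptionV3": ("inception_v3", "InceptionV3"),
        "ResNet152V2": ("resnet_v2", "ResNet152V2"),
        "InceptionResNetV2": ("inception_resnet_v2", "InceptionResNetV2"),
        "MobileNetV2": ("mobilenet_v2", "MobileNetV2"),
        "DenseNet201": ("densenet", "DenseNet201"),
        "Xception": ("xception", "Xception"),
        "NASNetLarge": ("nasnet", "NASNetLarge"),
        "EfficientNetV2L": ("efficientnet_v2", "EfficientNetV2L"),
    }

    def __init__(self) -> None:
        try:
            import tensorflow  # noqa: F401
        except ImportError as exc:
            raise ConfigurationError(
                "the pretrained backend requires tensorflow "
                "(pip install 'histocbir[pretrained]'); the seeded-random "
                "backend works without it"
            ) from exc
        self.name = "keras-imagenet"
        self._models: dict[tuple[str, str], object] = {}

    def _model(self, backbone: str, layer: str):
        key = (backbone, layer)
        if key not in self._models:
            import importlib

            from tensorflow import keras

            module_name, class_name = self._CONSTRUCTORS[backbone]
            module = importlib.import_module(f"tensorflow.keras.applications.{module_name}")
            base = getattr(module, class_name)(include_top=False, weights="imagenet")
            self._models[key] = keras.Model(
                inputs=base.input, outputs=base.get_layer(layer).output
            )
        return self._models[key]

    def extract_batch(self, backbone: str, layer: str, batch: np.ndarray) -> np.ndarray:
        get_layer(backbone, layer)  # validate names before building a model
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim == 3:
            batch = batch[None]
        return np.asarray(self._model(backbone, layer).predict(batch, verbose=0), dtype=np.float64)


def make_backend(kind: str, seed: int = 0) -> ExtractorBackend:
    """Backend factory for the CLI: ``seeded`` or ``pretrained``."""
    if kind == "seeded":
        return SeededRandomBackend(seed=seed)
    if kind == "pretrained":
        return KerasBackend()
    raise ConfigurationError(f"unknown backend {kind!r}; choose 'seeded' or 'pretrained'")
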