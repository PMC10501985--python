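"""Deep-feature extraction: 3-D layer activations and their 1-D reductions.

A "deep feature" here is the activation of an intermediate CNN layer, used as
a generic image descriptor.  The 3-D map (H×W×C) is collapsed to a 1-D
vector by global average pooling (per-channel spatial mean), global max
pooling (per-channel spatial max) or flattening (row-major linearisation,
channels fastest-varying).  No L2 normalisation is applied at extraction
time: cosine similarity downstream is scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backends import ExtractorBackend
from .errors import ShapeMismatchError
from .preprocess import PreparedInput, RawPatch, prepare
from .registry import LayerSpec, Reduction, get_backbone, get_layer, reduced_size

__all__ = ["FeatureMap", "FeatureVector", "extract_feature_map", "reduce_feature_map", "extract_vector"]


@dataclass
class FeatureMap:
    """One layer activation (H×W×C) with its backbone/layer provenance."""

    values: np.ndarray
    layer: LayerSpec
    backbone: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.layer.shape:
            raise ShapeMismatchError(
                f"feature map for {self.backbone}/{self.layer.name}: expected "
                f"shape {self.layer.shape}, got {self.values.shape}"
            )


@dataclass
class FeatureVector:
    """A 1-D deep feature with full extraction provenance and item identity."""

    values: np.ndarray
    backbone: str
    layer: str
    reduction: Reduction
    item_id: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"feature vector for item {self.item_id!r} contains non-finite values"
            )


def extract_feature_map(
    prepared: PreparedInput,
    backbone: str,
    layer: str,
    backend: ExtractorBackend,
) -> FeatureMap:
    """Run the backend forward pass and validate the result against the registry.

    A backend returning a shape that contradicts the catalogue is a hard
    error, not a warning: shape drift silently corrupts every stored bank.
    """
    spec = get_layer(backbone, layer)
    raw = np.asarray(backend.extract_batch(backbone, layer, prepared.pixels[None]))
    if raw.ndim == 4:
        raw = raw[0]
    if raw.shape != spec.shape:
        raise ShapeMismatchError(
            f"backend {getattr(backend, 'name', backend)!r} returned shape "
            f"{raw.shape} for {backbone}/{layer}, registry expects {spec.shape}"
        )
    return FeatureMap(values=raw, layer=spec, backbone=backbone)


def reduce_feature_map(
    fm: FeatureMap,
    reduction: "Reduction | str",
    item_id: str = "",
    label: str = "",
) -> FeatureVector:
    """Collapse an H×W×C map to 1-D: GAP (mean), GMP (max) or FLATTEN.

    Flattening is row-major with channels fastest-varying; any fixed order
    would do for cosine ranking, but this one is frozen for reproducibility.
    """
    reduction = Reduction.parse(reduction)
    if reduction is Reduction.GAP:
        values = fm.values.mean(axis=(0, 1))
    elif reduction is Reduction.GMP:
        values = fm.values.max(axis=(0, 1))
    else:
        values = fm.values.reshape(-1)
    vec = FeatureVector(
        values=values,
        backbone=fm.backbone,
        layer=fm.layer.name,
        reduction=reduction,
        item_id=item_id,
        label=label,
    )
    assert vec.values.size == reduced_size(fm.layer, reduction)
    return vec


def extract_vector(
    patch: RawPatch,
    backbone: str,
    layer: str,
    reduction: "Reduction | str",
    backend: ExtractorBackend,
    channel_stats: dict | None = None,
    interpolation: str = "bilinear",
) -> FeatureVector:
    """Full per-patch pipeline: resize → normalise → forward pass → reduce."""
    spec = get_backbone(backbone)
    prepared = prepare(patch, spec, channel_stats=channel_stats, interpolation=interpolation)
    fm = extract_feature_map(prepared, backbone, layer, backend)
    return reduce_feature_map(fm, reduction, item_id=patch.item_id, label=patch.label)
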