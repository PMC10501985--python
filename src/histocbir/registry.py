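"""Catalogue of CNN backbones and the intermediate layers used as deep features.

The registry is *data*, not code: a versioned JSON catalogue shipped with the
package records, for each of the nine supported ImageNet-pretrained backbones,
its square input size, its pixel-normalisation mode and the ordered list of
extraction layers with their feature-map output shapes ``(H, W, C)``.  The
feature-extraction layer validates whatever a backend returns against these
shapes, so silent shape drift between framework versions becomes a hard error.

The registry only *describes* networks; it never builds them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources

from .errors import UnknownBackboneError, UnknownLayerError

__all__ = [
    "Reduction",
    "PreprocessMode",
    "LayerSpec",
    "BackboneSpec",
    "catalogue_version",
    "list_backbones",
    "get_backbone",
    "layer_specs",
    "get_layer",
    "reduced_size",
]


class Reduction(str, Enum):
    """Feature-map reduction collapsing an H×W×C activation to one dimension.

    GAP and GMP are global average / max pooling over the spatial grid
    (output length C); FLATTEN is the row-major linearisation (length H·W·C).
    """

    GAP = "gap"
    GMP = "gmp"
    FLATTEN = "flatten"

    @classmethod
    def parse(cls, value: "str | Reduction") -> "Reduction":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown reduction {value!r}; choose from "
                f"{[m.value for m in cls]}"
            ) from None


class PreprocessMode(str, Enum):
    """Pixel-normalisation regime a backbone expects.

    BGR_ZERO_CENTER: RGB→BGR channel swap, subtract per-channel ImageNet
    means, no scaling.  SCALE_SYMMETRIC: scale 0–255 pixels into [-1, 1].
    SCALE_UNIT_IMAGENET: scale into [0, 1] then standardise with ImageNet
    per-channel mean/std.  IDENTITY: pass raw pixel values through.
    """

    BGR_ZERO_CENTER = "bgr_zero_center"
    SCALE_SYMMETRIC = "scale_symmetric"
    SCALE_UNIT_IMAGENET = "scale_unit_imagenet"
    IDENTITY = "identity"


@dataclass(frozen=True)
class LayerSpec:
    """Shape contract for one extraction layer: feature grid H×W with C channels."""

    name: str
    height: int
    width: int
    channels: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.height, self.width, self.channels)


@dataclass(frozen=True)
class BackboneSpec:
    """One catalogue entry: backbone name, input side, preprocessing, layers.

    ``layers`` holds the curated extraction layers in catalogue order;
    ``extended_layers`` holds optional additional layers (currently the seven
    extra Xception middle-flow outputs) enabled via ``extended=True``.
    """

    name: str
    input_size: int
    preprocess: PreprocessMode
    layers: tuple[LayerSpec, ...]
    extended_layers: tuple[LayerSpec, ...] = ()

    def all_layers(self, extended: bool = False) -> tuple[LayerSpec, ...]:
        return self.layers + self.extended_layers if extended else self.layers

    def layer(self, name: str) -> LayerSpec:
        for spec in self.layers + self.extended_layers:
            if spec.name == name:
                return spec
        raise UnknownLayerError(
            f"backbone {self.name!r} has no layer {name!r}; registered layers: "
            f"{[s.name for s in self.layers + self.extended_layers]}"
        )


@lru_cache(maxsize=1)
def _catalogue() -> dict:
    with resources.files("histocbir.data").joinpath("catalogue.json").open() as fh:
        return json.load(fh)


@lru_cache(maxsize=1)
def _backbones() -> dict[str, BackboneSpec]:
    out: dict[str, BackboneSpec] = {}
    for name, entry in _catalogue()["backbones"].items():
        out[name] = BackboneSpec(
            name=name,
            input_size=int(entry["input_size"]),
            preprocess=PreprocessMode(entry["preprocess"]),
            layers=tuple(
                LayerSpec(d["name"], d["h"], d["w"], d["c"]) for d in entry["layers"]
            ),
            extended_layers=tuple(
                LayerSpec(d["name"], d["h"], d["w"], d["c"])
                for d in entry.get("extended_layers", [])
            ),
        )
    return out


def catalogue_version() -> str:
    """Schema version string of the bundled catalogue."""
    return str(_catalogue()["schema_version"])


def list_backbones() -> list[BackboneSpec]:
    """All registered backbones, in stable catalogue order."""
    return list(_backbones().values())


def get_backbone(name: str) -> BackboneSpec:
    """Look up one backbone by name; raises :class:`UnknownBackboneError`."""
    try:
        return _backbones()[name]
    except KeyError:
        raise UnknownBackboneError(
            f"unknown backbone {name!r}; registered backbones: "
            f"{sorted(_backbones())}"
        ) from None


def layer_specs(backbone_name: str, extended: bool = False) -> list[LayerSpec]:
    """The extraction layers of one backbone, in catalogue (table) order."""
    return list(get_backbone(backbone_name).all_layers(extended=extended))


def get_layer(backbone_name: str, layer_name: str) -> LayerSpec:
    """Look up one layer of one backbone (extended layers included)."""
    return get_backbone(backbone_name).layer(layer_name)


def reduced_size(layer: LayerSpec, reduction: "Reduction | str") -> int:
    """Length of the 1-D feature vector a reduction produces from this layer.

    Global poolings keep one value per channel; flattening keeps every cell.
    """
    reduction = Reduction.parse(reduction)
    if reduction is Reduction.FLATTEN:
        return layer.height * layer.width * layer.channels
    return layer.channels
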