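"""Patch loading, resizing and pixel normalisation.

Converts a raw RGB patch (8-bit, any size) into the floating-point input
tensor a backbone expects: resize to the backbone's square input side, then
apply its pixel-normalisation mode (see :class:`~histocbir.registry.PreprocessMode`).

Channel statistics for the ImageNet-based modes are configurable values
shipped as package data (``data/channel_stats.json``), not hard-coded
constants; pass ``channel_stats`` to :func:`normalize` to override them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import ConfigurationError, HistoCBIRError
from .registry import BackboneSpec, PreprocessMode

__all__ = [
    "RawPatch",
    "PreparedInput",
    "default_channel_stats",
    "load_patch",
    "resize",
    "normalize",
    "prepare",
    "discover_dataset",
]

_INTERPOLATIONS = {
    "nearest": Image.Resampling.NEAREST,
    "bilinear": Image.Resampling.BILINEAR,
    "bicubic": Image.Resampling.BICUBIC,
    "lanczos": Image.Resampling.LANCZOS,
}

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


@dataclass
class RawPatch:
    """An 8-bit RGB patch with identity and label.

    ``pixels`` is H×W×3 uint8 in RGB channel order; ``item_id`` must be unique
    within a collection.
    """

    pixels: np.ndarray
    item_id: str
    label: str
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"patch pixels must be H×W×3, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("patch pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)


@dataclass
class PreparedInput:
    """A resized, normalised floating-point input tensor (S×S×3)."""

    pixels: np.ndarray
    mode: PreprocessMode


def default_channel_stats() -> dict:
    """The bundled ImageNet channel statistics (means/stds), as a dict."""
    with resources.files("histocbir.data").joinpath("channel_stats.json").open() as fh:
        return json.load(fh)


def load_patch(path: "str | Path", label: str, item_id: str | None = None) -> RawPatch:
    """Decode a PNG/TIFF/JPEG file into an RGB :class:`RawPatch`.

    Grayscale inputs are replicated to three channels and alpha channels are
    dropped (both via conversion to RGB).  ``item_id`` defaults to the file
    stem prefixed with the label.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            rgb = img.convert("RGB")
            pixels = np.asarray(rgb, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise HistoCBIRError(f"not a recognised image format: {path}") from exc
    except OSError as exc:
        raise HistoCBIRError(f"cannot read image file {path}: {exc}") from exc
    if item_id is None:
        item_id = f"{label}/{path.stem}"
    return RawPatch(pixels=pixels, item_id=item_id, label=label, source_path=str(path))


def resize(patch: RawPatch, target_side: int, interpolation: str = "bilinear") -> RawPatch:
    """Resize a patch to ``target_side`` × ``target_side`` (aspect not preserved).

    Bilinear by default; a no-op (pixel-identical) when the patch is already
    at the target side.
    """
    if target_side < 1:
        raise ValueError("target_side must be >= 1")
    h, w = patch.pixels.shape[:2]
    if (h, w) == (target_side, target_side):
        return patch
    try:
        resample = _INTERPOLATIONS[interpolation]
    except KeyError:
        raise ConfigurationError(
            f"unknown interpolation {interpolation!r}; choose from {sorted(_INTERPOLATIONS)}"
        ) from None
    img = Image.fromarray(patch.pixels, mode="RGB")
    resized = np.asarray(img.resize((target_side, target_side), resample), dtype=np.uint8)
    return RawPatch(
        pixels=resized,
        item_id=patch.item_id,
        label=patch.label,
        source_path=patch.source_path,
    )


def normalize(
    patch: RawPatch,
    mode: "PreprocessMode | str",
    channel_stats: dict | None = None,
) -> PreparedInput:
    """Apply a backbone's pixel-normalisation mode to an (already resized) patch.

    SCALE_SYMMETRIC maps 0–255 onto [-1, 1] via ``x / 127.5 - 1``.
    SCALE_UNIT_IMAGENET maps onto [0, 1] then standardises each channel with
    ImageNet mean/std.  BGR_ZERO_CENTER swaps RGB→BGR and subtracts the
    per-channel ImageNet means without scaling.  IDENTITY casts to float
    unchanged.
    """
    mode = PreprocessMode(mode)
    x = patch.pixels.astype(np.float64)
    if mode is PreprocessMode.IDENTITY:
        out = x
    elif mode is PreprocessMode.SCALE_SYMMETRIC:
        out = x / 127.5 - 1.0
    elif mode is PreprocessMode.SCALE_UNIT_IMAGENET:
        stats = default_channel_stats() if channel_stats is None else channel_stats
        try:
            mean = np.asarray(stats["imagenet_unit_mean"], dtype=np.float64)
            std = np.asarray(stats["imagenet_unit_std"], dtype=np.float64)
        except KeyError as exc:
            raise ConfigurationError(
                f"channel_stats missing key {exc} required by mode {mode.value}"
            ) from None
        out = (x / 255.0 - mean) / std
    elif mode is PreprocessMode.BGR_ZERO_CENTER:
        stats = default_channel_stats() if channel_stats is None else channel_stats
        try:
            bgr_mean = np.asarray(stats["imagenet_bgr_mean"], dtype=np.float64)
        except KeyError as exc:
            raise ConfigurationError(
                f"channel_stats missing key {exc} required by mode {mode.value}"
            ) from None
        out = x[:, :, ::-1] - bgr_mean
    else:  # pragma: no cover - exhaustive enum
        raise ConfigurationError(f"unhandled preprocess mode {mode!r}")
    return PreparedInput(pixels=out, mode=mode)


def prepare(
    patch: RawPatch,
    backbone: BackboneSpec,
    channel_stats: dict | None = None,
    interpolation: str = "bilinear",
) -> PreparedInput:
    """Resize + normalise a patch for one backbone in a single call."""
    return normalize(
        resize(patch, backbone.input_size, interpolation=interpolation),
        backbone.preprocess,
        channel_stats=channel_stats,
    )


def discover_dataset(path: "str | Path") -> pd.DataFrame:
    """Enumerate a labeled patch collection as a (path, label, item_id) frame.

    Two layouts are supported: a directory with one subdirectory per class
    label (item ids are ``label/stem``), or a CSV manifest with columns
    ``path``, ``label`` and optionally ``item_id`` (relative paths resolved
    against the manifest's directory).  A directory containing a
    ``manifest.csv`` is read through the manifest.
    """
    path = Path(path)
    if path.is_dir() and (path / "manifest.csv").is_file():
        path = path / "manifest.csv"
    if path.is_file():
        frame = pd.read_csv(path)
        missing = {"path", "label"} - set(frame.columns)
        if missing:
            raise HistoCBIRError(f"manifest {path} missing columns {sorted(missing)}")
        root = path.parent
        frame["path"] = [str((root / p)) if not Path(p).is_absolute() else str(p) for p in frame["path"]]
        if "item_id" not in frame.columns:
            frame["item_id"] = [
                f"{lab}/{Path(p).stem}" for p, lab in zip(frame["path"], frame["label"])
            ]
        return frame[["path", "label", "item_id"]].reset_index(drop=True)
    if not path.is_dir():
        raise HistoCBIRError(f"dataset path {path} is neither a directory nor a CSV manifest")
    rows = []
    for class_dir in sorted(p for p in path.iterdir() if p.is_dir()):
        for img in sorted(class_dir.iterdir()):
            if img.suffix.lower() in IMAGE_EXTENSIONS:
                rows.append(
                    {
                        "path": str(img),
                        "label": class_dir.name,
                        "item_id": f"{class_dir.name}/{img.stem}",
                    }
                )
    if not rows:
        raise HistoCBIRError(f"no images found under {path}")
    return pd.DataFrame(rows)
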