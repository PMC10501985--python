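"""The offline feature store: N stored vectors + labels + ids + provenance.

Banks are persisted as a single HDF5 file: dataset ``/features`` (float32,
chunked) plus a JSON-encoded metadata attribute carrying labels, ids,
provenance and a schema version.  Feature matrices are stored in 32-bit
floating point — similarity downstream is always accumulated in 64-bit — so
even a 400 × 1.8M flattened bank stays chunkable and memory-mappable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import BankFormatError, ConsistencyError
from .features import FeatureVector
from .registry import Reduction

__all__ = ["Provenance", "FeatureBank", "build_bank", "save_bank", "load_bank", "export_labels_csv"]

SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class Provenance:
    """How a bank's vectors were extracted; queries must match it exactly."""

    backbone: str
    layer: str
    reduction: str
    preprocess: str = ""
    backend: str = ""

    @classmethod
    def of_vector(cls, vec: FeatureVector, preprocess: str = "", backend: str = "") -> "Provenance":
        return cls(
            backbone=vec.backbone,
            layer=vec.layer,
            reduction=Reduction.parse(vec.reduction).value,
            preprocess=preprocess,
            backend=backend,
        )


@dataclass
class FeatureBank:
    """N×D feature matrix with aligned labels, unique ids and provenance."""

    matrix: np.ndarray
    labels: list[str]
    ids: list[str]
    provenance: Provenance

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float32))
        n = self.matrix.shape[0]
        if len(self.labels) != n or len(self.ids) != n:
            raise ConsistencyError(
                f"bank matrix has {n} rows but {len(self.labels)} labels / {len(self.ids)} ids"
            )
        if len(set(self.ids)) != n:
            raise ConsistencyError("bank item ids must be unique")

    @property
    def n_items(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def row_of(self, item_id: str) -> int:
        try:
            return self.ids.index(item_id)
        except ValueError:
            raise KeyError(f"item id {item_id!r} not in bank") from None


def build_bank(
    vectors: list[FeatureVector],
    preprocess: str = "",
    backend: str = "",
) -> FeatureBank:
    """Stack homogeneous feature vectors into a bank (row order = input order)."""
    if not vectors:
        raise ConsistencyError("cannot build a bank from zero vectors")
    prov = Provenance.of_vector(vectors[0], preprocess=preprocess, backend=backend)
    dim = vectors[0].values.size
    for v in vectors[1:]:
        vprov = Provenance.of_vector(v, preprocess=preprocess, backend=backend)
        if vprov != prov:
            raise ConsistencyError(
                f"heterogeneous provenance: {vprov} vs {prov} (item {v.item_id!r})"
            )
        if v.values.size != dim:
            raise ConsistencyError(
                f"vector length mismatch: item {v.item_id!r} has {v.values.size}, expected {dim}"
            )
    ids = [v.item_id for v in vectors]
    if len(set(ids)) != len(ids):
        raise ConsistencyError("duplicate item ids among input vectors")
    matrix = np.stack([v.values for v in vectors]).astype(np.float32)
    return FeatureBank(
        matrix=matrix,
        labels=[v.label for v in vectors],
        ids=ids,
        provenance=prov,
    )


def save_bank(bank: FeatureBank, path: "str | Path") -> None:
    """Write a bank to one HDF5 file (dataset /features + metadata attribute)."""
    meta = {
        "schema_version": SCHEMA_VERSION,
        "labels": bank.labels,
        "ids": bank.ids,
        "provenance": asdict(bank.provenance),
    }
    with h5py.File(path, "w") as fh:
        fh.create_dataset("features", data=bank.matrix, dtype="float32", chunks=True)
        fh.attrs["metadata"] = json.dumps(meta)
        fh.attrs["schema_version"] = SCHEMA_VERSION


def load_bank(path: "str | Path") -> FeatureBank:
    """Reload a bank; the round trip is bit-exact on the matrix and metadata."""
    with h5py.File(path, "r") as fh:
        if "features" not in fh:
            raise BankFormatError(f"{path}: missing /features dataset")
        if "metadata" not in fh.attrs:
            raise BankFormatError(f"{path}: missing metadata attribute")
        meta = json.loads(fh.attrs["metadata"])
        version = meta.get("schema_version")
        if version != SCHEMA_VERSION:
            raise BankFormatError(
                f"{path}: schema version {version!r} not supported (expected {SCHEMA_VERSION!r})"
            )
        if "provenance" not in meta:
            raise BankFormatError(f"{path}: metadata missing provenance block")
        matrix = fh["features"][()]
    return FeatureBank(
        matrix=matrix,
        labels=list(meta["labels"]),
        ids=list(meta["ids"]),
        provenance=Provenance(**meta["provenance"]),
    )


def export_labels_csv(bank: FeatureBank, path: "str | Path") -> None:
    """Dump (item_id, label) rows for human inspection of a bank's contents."""
    pd.DataFrame({"item_id": bank.ids, "label": bank.labels}).to_csv(path, index=False)
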