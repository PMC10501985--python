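"""Online retrieval: cosine-similarity scoring and top-k ranking against a bank.

Similarity is the cosine of the angle between query and stored vector
(equivalently one minus the cosine distance), accumulated in 64-bit floats
regardless of bank storage precision.  Ranking is similarity-descending with
ties broken by ascending item id so duplicated patches rank deterministically.
Zero-norm vectors are an error, never silently scored 0: a zero pooled
feature indicates a dead layer or a backend bug.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bank import FeatureBank
from .errors import (
    ConsistencyError,
    DegenerateVectorError,
    DimensionError,
    InsufficientCandidatesError,
)
from .features import FeatureVector
from .registry import Reduction

__all__ = ["RankedRetrieval", "cosine_similarity", "rank", "top_k", "export_ranking_csv"]


@dataclass
class RankedRetrieval:
    """All non-excluded bank items ordered by similarity to one query."""

    query_id: str
    query_label: str
    entries: list[tuple[str, str, float]]  # (item_id, label, similarity)
    excluded_ids: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.entries)

    def labels(self) -> list[str]:
        return [label for _, label, _ in self.entries]


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """⟨u, v⟩ / (‖u‖ ‖v‖), in 64-bit; raises on zero norm or length mismatch."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.size != v.size:
        raise DimensionError(f"vector lengths differ: {u.size} vs {v.size}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateVectorError("cosine similarity undefined for zero-norm vectors")
    return float(np.dot(u, v) / (nu * nv))


def rank(
    query: FeatureVector,
    bank: FeatureBank,
    exclude_ids: Iterable[str] = (),
) -> RankedRetrieval:
    """Score the query against every stored vector and sort.

    The query's provenance (backbone, layer, reduction) must match the
    bank's; mixing feature spaces is a consistency error, not a warning.
    """
    if (
        query.backbone != bank.provenance.backbone
        or query.layer != bank.provenance.layer
        or Reduction.parse(query.reduction).value != bank.provenance.reduction
    ):
        raise ConsistencyError(
            f"query provenance ({query.backbone}/{query.layer}/"
            f"{Reduction.parse(query.reduction).value}) does not match bank "
            f"({bank.provenance.backbone}/{bank.provenance.layer}/{bank.provenance.reduction})"
        )
    q = np.asarray(query.values, dtype=np.float64)
    if q.size != bank.dim:
        raise DimensionError(f"query length {q.size} != bank dimension {bank.dim}")
    qnorm = np.linalg.norm(q)
    if qnorm == 0.0:
        raise DegenerateVectorError(f"query {query.item_id!r} has zero norm")

    excluded = frozenset(exclude_ids)
    keep = np.array([i not in excluded for i in bank.ids], dtype=bool)
    if not keep.any():
        raise InsufficientCandidatesError("no candidates remain after exclusion")

    matrix = bank.matrix[keep].astype(np.float64)
    # per-row dots (not one gemv): BLAS blocking can round identical rows
    # differently by position, which would make tie-breaking nondeterministic
    dots = np.array([np.dot(row, q) for row in matrix])
    norms = np.sqrt(np.array([np.dot(row, row) for row in matrix]))
    if np.any(norms == 0.0):
        bad = [i for i, flag in zip(np.asarray(bank.ids)[keep], norms == 0.0) if flag]
        raise DegenerateVectorError(f"bank items with zero-norm vectors: {bad[:5]}")
    sims = dots / (norms * qnorm)

    kept_ids = [i for i, f in zip(bank.ids, keep) if f]
    kept_labels = [l for l, f in zip(bank.labels, keep) if f]
    # descending similarity, ties by ascending item id (lexsort: last key primary)
    order = np.lexsort((np.asarray(kept_ids), -sims))
    entries = [(kept_ids[j], kept_labels[j], float(sims[j])) for j in order]
    return RankedRetrieval(
        query_id=query.item_id,
        query_label=query.label,
        entries=entries,
        excluded_ids=excluded,
    )


def top_k(result: RankedRetrieval, k: int) -> list[tuple[str, str, float]]:
    """First k ranked entries; k beyond the candidate count is an error.

    Explicit because precision-at-k divides by k: padding or truncating
    silently would bias every downstream metric.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k > len(result.entries):
        raise InsufficientCandidatesError(
            f"requested top {k} but only {len(result.entries)} candidates ranked"
        )
    return result.entries[:k]


def export_ranking_csv(result: RankedRetrieval, path: "str | Path", k: int | None = None) -> None:
    """Write (rank, item_id, label, similarity) rows for one query."""
    entries = result.entries if k is None else top_k(result, k)
    frame = pd.DataFrame(entries, columns=["item_id", "label", "similarity"])
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    frame.to_csv(path, index=False)
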