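"""Retrieval evaluation: P@k, MAP@k, GLP gain/loss, confusion matrices,
leave-one-out protocol and the reduction/layer/backbone selection procedures.

Terminology note — **MAP@k here is the plain mean of per-query P@k**, not the
interpolated "mean average precision" of the IR literature.  P@k for one
query is the fraction of the k top-ranked items sharing the query's class
(I_r / k).  GLP_m@k = P_avg@k − P_m@k quantifies the gain (positive) or loss
(negative) of global average pooling relative to reduction/configuration m.

The leave-one-out protocol uses every bank item as a query-by-example
against all remaining items, so a bank of N items yields exactly N queries
ranked over N − 1 candidates each.

Confusion matrices at k are macro-averaged over queries: row i, column j is
the mean, over queries of class i, of the fraction of class-j items among
the top k retrieved.  Rows therefore sum to 1 and the diagonal of row i is
the class-i mean P@k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bank import FeatureBank
from .errors import IncompleteGridError, InsufficientCandidatesError
from .features import FeatureVector
from .registry import Reduction, get_layer, reduced_size
from .retrieval import rank, top_k

__all__ = [
    "QueryOutcome",
    "ConfusionAtK",
    "EvalReport",
    "MetricTable",
    "GLPEntry",
    "ReductionSelection",
    "LayerSelection",
    "BackboneComparison",
    "DEFAULT_KS",
    "precision_at_k",
    "map_at_k",
    "confusion_at_k",
    "evaluate_leave_one_out",
    "glp",
    "reduction_gain_table",
    "select_best_reduction",
    "select_best_layer",
    "compare_backbones",
]

DEFAULT_KS: tuple[int, ...] = (5, 10, 50, 100)


@dataclass
class QueryOutcome:
    """The ranked retrieved labels (up to the largest evaluated k) for one query."""

    query_id: str
    query_label: str
    retrieved_labels: list[str]


@dataclass
class ConfusionAtK:
    """Per-class retrieval composition at cutoff k (rows: query class)."""

    classes: list[str]
    k: int
    matrix: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.classes, columns=self.classes)


@dataclass
class EvalReport:
    """Everything the leave-one-out evaluation produces for one configuration."""

    ks: tuple[int, ...]
    outcomes: list[QueryOutcome]
    map_at_k: dict[int, float]
    confusions: dict[int, ConfusionAtK]

    def per_query_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.outcomes:
            row = {"query_id": o.query_id, "label": o.query_label}
            for k in self.ks:
                row[f"p@{k}"] = precision_at_k(o, k)
            rows.append(row)
        return pd.DataFrame(rows)


def precision_at_k(outcome: QueryOutcome, k: int) -> float:
    """Fraction of the k top-ranked items sharing the query's class (I_r / k)."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k > len(outcome.retrieved_labels):
        raise InsufficientCandidatesError(
            f"query {outcome.query_id!r}: k={k} exceeds the "
            f"{len(outcome.retrieved_labels)} retrieved labels recorded"
        )
    hits = sum(1 for lab in outcome.retrieved_labels[:k] if lab == outcome.query_label)
    return hits / k


def map_at_k(outcomes: Sequence[QueryOutcome], k: int) -> float:
    """Mean of per-query P@k over all queries (this package's MAP@k)."""
    if not outcomes:
        raise ValueError("map_at_k needs at least one query outcome")
    return float(np.mean([precision_at_k(o, k) for o in outcomes]))


def confusion_at_k(
    outcomes: Sequence[QueryOutcome],
    k: int,
    classes: Sequence[str] | None = None,
) -> ConfusionAtK:
    """Macro-averaged class-composition matrix of the top-k retrievals."""
    if classes is None:
        seen: set[str] = set()
        for o in outcomes:
            seen.add(o.query_label)
            seen.update(o.retrieved_labels[:k])
        classes = sorted(seen)
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.float64)
    n_queries = np.zeros(len(classes), dtype=np.float64)
    for o in outcomes:
        i = index[o.query_label]
        n_queries[i] += 1
        for lab in o.retrieved_labels[:k]:
            counts[i, index[lab]] += 1.0 / k
    with np.errstate(invalid="ignore"):
        matrix = counts / n_queries[:, None]
    matrix[n_queries == 0] = 0.0
    return ConfusionAtK(classes=classes, k=k, matrix=matrix)


def evaluate_leave_one_out(
    bank: FeatureBank,
    ks: Sequence[int] = DEFAULT_KS,
) -> EvalReport:
    """Query-by-example with every bank item, leaving the query out of the results.

    For each of the N items the remaining N − 1 are ranked by cosine
    similarity and the top max(ks) labels recorded; P@k, MAP@k and the
    confusion matrices are computed from those outcomes.
    """
    ks = tuple(sorted(int(k) for k in ks))
    kmax = ks[-1]
    if bank.n_items <= kmax:
        raise InsufficientCandidatesError(
            f"bank of {bank.n_items} items cannot support k={kmax} "
            f"leave-one-out (needs at least {kmax + 1} items)"
        )
    outcomes: list[QueryOutcome] = []
    for i, item_id in enumerate(bank.ids):
        query = FeatureVector(
            values=bank.matrix[i].astype(np.float64),
            backbone=bank.provenance.backbone,
            layer=bank.provenance.layer,
            reduction=Reduction.parse(bank.provenance.reduction),
            item_id=item_id,
            label=bank.labels[i],
        )
        ranking = rank(query, bank, exclude_ids={item_id})
        labels = [lab for _, lab, _ in top_k(ranking, kmax)]
        outcomes.append(QueryOutcome(query_id=item_id, query_label=bank.labels[i], retrieved_labels=labels))
    classes = bank.classes()
    return EvalReport(
        ks=ks,
        outcomes=outcomes,
        map_at_k={k: map_at_k(outcomes, k) for k in ks},
        confusions={k: confusion_at_k(outcomes, k, classes=classes) for k in ks},
    )


def glp(reference_cell: float, other_cell: float) -> float:
    """Gain/loss of the reference configuration: reference P@k minus other P@k.

    Positive means the reference (conventionally the global-average-pooling
    side) gains precision over the compared configuration.
    """
    return float(reference_cell) - float(other_cell)


class MetricTable:
    """Mean-P@k cells keyed by (backbone, layer, reduction) × k.

    A thin wrapper over a pandas DataFrame with a three-level row index and
    integer k columns; the selection procedures consume it.
    """

    INDEX_NAMES = ("backbone", "layer", "reduction")

    def __init__(self, frame: pd.DataFrame):
        if list(frame.index.names) != list(self.INDEX_NAMES):
            raise ValueError(f"MetricTable index must be {self.INDEX_NAMES}")
        self.frame = frame.sort_index(axis=1)
        bad = self.frame.values[~np.isnan(self.frame.values)]
        if bad.size and (bad.min() < 0 or bad.max() > 1):
            raise ValueError("MetricTable cells must lie in [0, 1]")

    @classmethod
    def from_cells(
        cls, cells: Mapping[tuple[str, str, "Reduction | str"], Mapping[int, float]]
    ) -> "MetricTable":
        keys = [
            (b, l, Reduction.parse(r).value) for (b, l, r) in cells.keys()
        ]
        frame = pd.DataFrame(
            [dict(v) for v in cells.values()],
            index=pd.MultiIndex.from_tuples(keys, names=cls.INDEX_NAMES),
        )
        return cls(frame)

    @property
    def ks(self) -> list[int]:
        return [int(k) for k in self.frame.columns]

    def backbones(self) -> list[str]:
        return list(dict.fromkeys(self.frame.index.get_level_values("backbone")))

    def layers(self, backbone: str) -> list[str]:
        sub = self.frame.xs(backbone, level="backbone")
        return list(dict.fromkeys(sub.index.get_level_values("layer")))

    def reductions(self) -> list[str]:
        return list(dict.fromkeys(self.frame.index.get_level_values("reduction")))

    def cell(self, backbone: str, layer: str, reduction: "Reduction | str", k: int) -> float:
        key = (backbone, layer, Reduction.parse(reduction).value)
        try:
            value = self.frame.loc[key, k]
        except KeyError:
            raise IncompleteGridError(f"metric table has no cell {key} @ k={k}") from None
        if pd.isna(value):
            raise IncompleteGridError(f"metric table cell {key} @ k={k} is missing")
        return float(value)


@dataclass(frozen=True)
class GLPEntry:
    """One gain/loss value: reference configuration minus compared one, at k."""

    reference: str
    other: str
    k: int
    value: float


def reduction_gain_table(table: MetricTable) -> list[GLPEntry]:
    """Per-backbone average GLP@k of GAP versus each other reduction.

    For each backbone, reduction m and k: the mean over that backbone's
    layers of (P_gap@k − P_m@k).  Layers are weighted equally.
    """
    reductions = table.reductions()
    if Reduction.GAP.value not in reductions:
        raise IncompleteGridError("gain table needs GAP cells for every layer")
    others = [r for r in (Reduction.GMP.value, Reduction.FLATTEN.value) if r in reductions]
    entries: list[GLPEntry] = []
    for backbone in table.backbones():
        layers = table.layers(backbone)
        for m in others:
            for k in table.ks:
                diffs = [
                    glp(table.cell(backbone, l, Reduction.GAP, k), table.cell(backbone, l, m, k))
                    for l in layers
                ]
                entries.append(
                    GLPEntry(
                        reference=f"{backbone}:gap",
                        other=f"{backbone}:{m}",
                        k=k,
                        value=float(np.mean(diffs)),
                    )
                )
    return entries


@dataclass
class ReductionSelection:
    """Outcome of the reduction comparison, with the audit trail attached."""

    best: Reduction
    grand_means: dict[str, float]
    gain_table: list[GLPEntry]
    tied: bool = False


_REDUCTION_PREFERENCE = (Reduction.GAP, Reduction.GMP, Reduction.FLATTEN)


def select_best_reduction(table: MetricTable) -> ReductionSelection:
    """Pick the reduction with the highest grand-mean P@k over all layers and k.

    Exact ties fall back to the deterministic preference GAP > GMP > FLATTEN
    and are flagged.  The per-backbone GLP table rides along for reporting.
    """
    present = table.reductions()
    grand: dict[str, float] = {}
    for r in present:
        sub = table.frame.xs(r, level="reduction")
        values = sub.values.ravel()
        if np.isnan(values).any():
            raise IncompleteGridError(f"metric table has missing cells for reduction {r!r}")
        grand[r] = float(values.mean())
    best_value = max(grand.values())
    winners = [r for r in present if grand[r] == best_value]
    best = next(r for r in _REDUCTION_PREFERENCE if r.value in winners)
    gain = reduction_gain_table(table) if Reduction.GAP.value in present else []
    return ReductionSelection(best=best, grand_means=grand, gain_table=gain, tied=len(winners) > 1)


@dataclass
class LayerSelection:
    """Outcome of layer selection for one backbone, with the pairwise audit table."""

    layer: str
    unanimous: bool
    per_k_best: dict[int, str]
    candidates: list[str]
    deficits: dict[str, float]
    pairwise: pd.DataFrame  # rows: other candidates; columns: k; cells: glp(selected, other)


def select_best_layer(
    table: MetricTable,
    backbone: str | None = None,
    reduction: "Reduction | str | None" = None,
    sizes: Mapping[str, int] | None = None,
) -> LayerSelection:
    """Choose one backbone's best extraction layer across all precision levels.

    If a single layer attains the maximum mean P@k at every k it is chosen
    outright.  Otherwise the candidates are the per-k winners and the choice
    minimises the total deficit Σ_k (max_layer P@k − P_candidate@k) — the
    layer that loses least precision overall.  Residual ties prefer the
    smaller reduced feature size, then the lexicographically smaller name.
    The pairwise per-k gain/loss table versus every other candidate is
    attached so the decision can be audited.
    """
    backbones = table.backbones() if backbone is None else [backbone]
    if len(backbones) != 1:
        raise ValueError("select_best_layer needs a single backbone; pass backbone=...")
    b = backbones[0]
    reductions = table.reductions() if reduction is None else [Reduction.parse(reduction).value]
    if len(reductions) != 1:
        raise ValueError("select_best_layer needs a single reduction; pass reduction=...")
    r = reductions[0]
    layers = table.layers(b)
    ks = table.ks
    cells = {l: {k: table.cell(b, l, r, k) for k in ks} for l in layers}

    per_k_best: dict[int, str] = {}
    attainers: dict[int, list[str]] = {}
    for k in ks:
        best_value = max(cells[l][k] for l in layers)
        attainers[k] = [l for l in layers if cells[l][k] == best_value]
        per_k_best[k] = attainers[k][0]
    unanimous_set = set(layers)
    for k in ks:
        unanimous_set &= set(attainers[k])
    unanimous = bool(unanimous_set)

    candidates = list(dict.fromkeys(l for k in ks for l in attainers[k]))
    deficits = {
        l: float(sum(max(cells[m][k] for m in layers) - cells[l][k] for k in ks))
        for l in candidates
    }

    def _size(layer: str) -> int:
        if sizes is not None and layer in sizes:
            return int(sizes[layer])
        try:
            return reduced_size(get_layer(b, layer), r)
        except Exception:
            return 0  # unknown synthetic layer: fall through to name order

    chosen = min(candidates, key=lambda l: (deficits[l], _size(l), l))

    others = [l for l in candidates if l != chosen]
    pairwise = pd.DataFrame(
        {k: [glp(cells[chosen][k], cells[l][k]) for l in others] for k in ks},
        index=pd.Index(others, name="other_layer"),
    )
    return LayerSelection(
        layer=chosen,
        unanimous=unanimous,
        per_k_best=per_k_best,
        candidates=candidates,
        deficits=deficits,
        pairwise=pairwise,
    )


@dataclass
class BackboneComparison:
    """Final cross-backbone ranking (rows sorted by P@first-k descending)."""

    frame: pd.DataFrame
    confusions: dict[str, dict[int, ConfusionAtK]] = field(default_factory=dict)
    ties: list[str] = field(default_factory=list)


def compare_backbones(
    table: MetricTable,
    confusions: Mapping[str, Mapping[int, ConfusionAtK]] | None = None,
) -> BackboneComparison:
    """Rank backbones at their chosen (layer, reduction) configuration.

    Expects one row per backbone.  Rows sort by the smallest k's mean P@k
    descending; exact ties fall back to the next k, then the backbone name,
    and are recorded in ``ties``.
    """
    frame = table.frame.reset_index()
    counts = frame["backbone"].value_counts()
    if (counts > 1).any():
        raise ValueError(
            f"compare_backbones expects one row per backbone; duplicated: "
            f"{sorted(counts[counts > 1].index)}"
        )
    ks = table.ks
    sort_cols = [ks[0]] + ks[1:2]
    ties = []
    if frame.duplicated(subset=[ks[0]], keep=False).any():
        ties = sorted(frame.loc[frame.duplicated(subset=[ks[0]], keep=False), "backbone"])
    frame = frame.sort_values(
        by=sort_cols + ["backbone"],
        ascending=[False] * len(sort_cols) + [True],
        kind="mergesort",
    ).reset_index(drop=True)
    return BackboneComparison(
        frame=frame,
        confusions={b: dict(c) for b, c in (confusions or {}).items()},
        ties=ties,
    )
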