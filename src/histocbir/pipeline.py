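"""High-level flows gluing the modules together: index a dataset, sweep a grid.

The offline flow reads a labeled patch collection, runs every image through
resize → normalise → backend forward pass → reduction and stacks the vectors
into a bank.  The sweep runs that flow over a layers × reductions grid —
extracting each feature map once and reducing it three ways — then evaluates
every configuration with the leave-one-out protocol.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .backends import ExtractorBackend
from .bank import FeatureBank, build_bank
from .features import extract_feature_map, reduce_feature_map
from .metrics import DEFAULT_KS, EvalReport, MetricTable, evaluate_leave_one_out
from .preprocess import discover_dataset, load_patch, prepare
from .registry import Reduction, get_backbone

__all__ = ["index_dataset", "sweep_grid"]


def index_dataset(
    dataset: "str | Path",
    backbone: str,
    layer: str,
    reduction: "Reduction | str",
    backend: ExtractorBackend,
    interpolation: str = "bilinear",
) -> FeatureBank:
    """Extract one feature vector per dataset image and build the bank."""
    spec = get_backbone(backbone)
    reduction = Reduction.parse(reduction)
    vectors = []
    for row in discover_dataset(dataset).itertuples(index=False):
        patch = load_patch(row.path, label=row.label, item_id=row.item_id)
        prepared = prepare(patch, spec, interpolation=interpolation)
        fm = extract_feature_map(prepared, backbone, layer, backend)
        vectors.append(reduce_feature_map(fm, reduction, item_id=row.item_id, label=row.label))
    return build_bank(
        vectors,
        preprocess=f"{spec.preprocess.value}@{spec.input_size}",
        backend=getattr(backend, "name", repr(backend)),
    )


def sweep_grid(
    dataset: "str | Path",
    backbone: str,
    layers: Sequence[str],
    reductions: Sequence["Reduction | str"],
    backend: ExtractorBackend,
    ks: Sequence[int] = DEFAULT_KS,
    interpolation: str = "bilinear",
) -> tuple[MetricTable, dict[tuple[str, str], EvalReport]]:
    """Evaluate every (layer, reduction) configuration of one backbone.

    Each feature map is extracted once per (image, layer) and reduced under
    every requested reduction.  Returns the MetricTable of MAP@k cells plus
    the full per-configuration evaluation reports.
    """
    spec = get_backbone(backbone)
    reductions = [Reduction.parse(r) for r in reductions]
    frame = discover_dataset(dataset)
    patches = [
        load_patch(row.path, label=row.label, item_id=row.item_id)
        for row in frame.itertuples(index=False)
    ]
    prepared = [prepare(p, spec, interpolation=interpolation) for p in patches]

    cells: dict[tuple[str, str, Reduction], dict[int, float]] = {}
    reports: dict[tuple[str, str], EvalReport] = {}
    for layer in layers:
        per_reduction_vectors = {r: [] for r in reductions}
        for patch, prep in zip(patches, prepared):
            fm = extract_feature_map(prep, backbone, layer, backend)
            for r in reductions:
                per_reduction_vectors[r].append(
                    reduce_feature_map(fm, r, item_id=patch.item_id, label=patch.label)
                )
        for r in reductions:
            bank = build_bank(
                per_reduction_vectors[r],
                preprocess=f"{spec.preprocess.value}@{spec.input_size}",
                backend=getattr(backend, "name", repr(backend)),
            )
            report = evaluate_leave_one_out(bank, ks=ks)
            reports[(layer, r.value)] = report
            cells[(backbone, layer, r)] = dict(report.map_at_k)
    return MetricTable.from_cells(cells), reports
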