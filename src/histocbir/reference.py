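"""Bundled reference mean-P@k cells for the BACH retrieval benchmark.

The package ships the per-layer leave-one-out retrieval precisions reported
for the 400-patch, 4-class BACH breast-histology benchmark with
ImageNet-pretrained backbones and global-average-pooling reduction.  These
cells let the gain/loss (GLP) arithmetic and the layer-selection procedure be
exercised and audited on real benchmark numbers without downloading the
dataset or any pretrained weights.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .metrics import MetricTable
from .registry import Reduction

__all__ = [
    "reference_tables",
    "reference_ks",
    "best_layer_cell",
    "chosen_layer_row",
    "candidate_layer_table",
]

# number of leave-one-out queries behind every reference cell
REFERENCE_N_QUERIES = 400


@lru_cache(maxsize=1)
def reference_tables() -> dict:
    """The raw bundled reference document (see ``data/bach_reference.json``)."""
    with resources.files("histocbir.data").joinpath("bach_reference.json").open() as fh:
        return json.load(fh)


def reference_ks() -> list[int]:
    return [int(k) for k in reference_tables()["ks"]]


def best_layer_cell(backbone: str, k: int) -> tuple[str, float]:
    """(layer, mean P@k) of the per-k best layer for one backbone."""
    layer, value = reference_tables()["best_layer_per_k"][backbone][str(k)]
    return str(layer), float(value)


def chosen_layer_row(backbone: str) -> tuple[str, dict[int, float]]:
    """(chosen layer, {k: mean P@k}) of the finally selected layer."""
    entry = reference_tables()["chosen_layer_pk"][backbone]
    return str(entry["layer"]), {int(k): float(v) for k, v in entry["pk"].items()}


def candidate_layer_table(backbone: str) -> MetricTable:
    """Full per-k P@k cells for a backbone's candidate layers, as a MetricTable.

    For backbones whose best layer differed across k, the reference document
    records the chosen layer's row plus its per-k gain/loss against each
    rival; the rivals' absolute cells are reconstructed as
    ``P_other@k = P_chosen@k − GLP``.  Unanimous backbones yield a
    single-row table.
    """
    layer, pk = chosen_layer_row(backbone)
    cells = {(backbone, layer, Reduction.GAP): dict(pk)}
    gain_loss = reference_tables()["layer_gain_loss"].get(backbone)
    if gain_loss is not None:
        assert gain_loss["reference"] == layer
        for other, diffs in gain_loss["others"].items():
            cells[(backbone, other, Reduction.GAP)] = {
                int(k): pk[int(k)] - float(d) for k, d in diffs.items()
            }
    return MetricTable.from_cells(cells)
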