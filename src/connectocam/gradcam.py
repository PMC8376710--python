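"""Grad-CAM attribution on the trained classifier, mapped back to connections.

For one subject, Grad-CAM at a convolutional layer computes a channel weight
as the spatial average of the target-class score's gradient on each feature
map, then rectifies the channel-weighted sum of the feature maps.  Because
every filter has size 1 and pooling is absent, the resulting heat map is
natively 60x60 — no upsampling, no blur — and each grid cell corresponds to
exactly one connection (or one padding cell, which is discarded).

The target layer is the 4th (last) convolutional layer and the target class
is the patient output.  Attribution maps are computed only for patients
correctly classified in validation, max-normalized per patient, reorganized
onto the 84x84 connection space, and pooled (averaged by default) across
patients — optionally restricted to left- or right-dominant patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import NodeAtlas
from .cohort import CohortDataset, SubjectRecord
from .core import (GRID_SIDE, INDEX_MAP, N_EDGES, ModelInput,
                   preprocess_matrix, reorganize_to_connectome)
from .errors import DataError, ValidationError
from .evaluation import PooledResult
from .network import TrainedClassifier, _as_input_array

TARGET_CONV_LAYER = 3  # 4th convolutional layer, zero-based
SUBGROUPS = ("all", "left", "right")


@dataclass
class AttributionMap:
    """Rectified Grad-CAM heat on the 60x60 input grid for one subject."""

    grid: np.ndarray
    subject_id: str = ""
    target_class: int = 1

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (GRID_SIDE, GRID_SIDE):
            raise ValidationError(f"attribution grid must be {GRID_SIDE}x{GRID_SIDE}")
        if np.any(self.grid < 0):
            raise ValidationError("attribution values must be non-negative")


@dataclass
class PooledAttribution:
    matrix: np.ndarray
    n_subjects_pooled: int
    subgroup: str = "all"


@dataclass
class RankedConnections:
    """(region_a, region_b, heat) triples in descending heat order."""

    entries: list[tuple[str, str, float]]


def gradcam(model: TrainedClassifier, x, target_class: int = 1,
            layer: int | None = None) -> AttributionMap:
    """Grad-CAM heat map for one input.

    Channel weights are spatial means of d(class score)/d(feature map) over
    the 3600 grid positions; the map is ReLU(sum_c alpha_c * A_c).  The
    default target layer is the last (4th) convolutional layer.

    Cells whose input value is zero (structurally absent connections and the
    padding cells) are masked out: with 1x1 filters their activations are
    input-independent constants, so any heat there reflects bias terms, not
    evidence from this subject's data — left unmasked, such cells can flood
    a ranking with large constant values.
    """
    flat = _as_input_array(x)
    if layer is None:
        layer = len(model.net.conv_W) - 1
    A, dA = model.net.conv_activations_and_gradient(flat, layer, target_class)
    alpha = dA.mean(axis=0)
    heat = np.maximum(A @ alpha, 0.0) * (flat > 0)
    sid = x.source_subject if isinstance(x, ModelInput) else ""
    return AttributionMap(heat.reshape(GRID_SIDE, GRID_SIDE), sid, target_class)


def pool_attributions(maps: list[AttributionMap],
                      records: list[SubjectRecord] | None = None,
                      subgroup: str = "all",
                      index_map: np.ndarray = INDEX_MAP,
                      mode: str = "mean") -> PooledAttribution:
    """Normalize each subject's map by its own maximum, reorganize to 84x84,
    and pool across subjects (``mode``: "mean" or "sum").

    ``records``, when given, must align with ``maps`` and enables the
    dominant-side subgroup filter.
    """
    if subgroup not in SUBGROUPS:
        raise ValidationError(f"subgroup must be one of {SUBGROUPS}")
    if mode not in ("mean", "sum"):
        raise ValidationError("mode must be 'mean' or 'sum'")
    if subgroup != "all":
        if records is None:
            raise DataError("subject records are required for a subgroup filter")
        maps = [m for m, r in zip(maps, records) if r.dominant_side == subgroup]
    if not maps:
        raise DataError("no attribution maps to pool")
    stacked = []
    for m in maps:
        mx = m.grid.max()
        normalized = m.grid / mx if mx > 0 else m.grid
        stacked.append(reorganize_to_connectome(normalized, index_map))
    pooled = np.sum(stacked, axis=0)
    if mode == "mean":
        pooled = pooled / len(stacked)
    return PooledAttribution(pooled, len(stacked), subgroup)


def rank_connections(pooled: PooledAttribution, atlas: NodeAtlas,
                     k: int = 30) -> RankedConnections:
    """Top-k unordered region pairs by pooled heat.

    Ties are broken by canonical atlas order (lexicographic on the index
    pair) for reproducibility; k is clipped to the 3486 available pairs.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    k = min(k, N_EDGES)
    rows, cols = INDEX_MAP[:, 0], INDEX_MAP[:, 1]
    values = pooled.matrix[rows, cols]
    order = np.lexsort((cols, rows, -values))[:k]
    entries = [(atlas.labels[rows[i]], atlas.labels[cols[i]], float(values[i]))
               for i in order]
    return RankedConnections(entries)


def attribute_cohort(dataset: CohortDataset, metric: str, result: PooledResult,
                     subgroup: str = "all", target_class: int = 1,
                     mode: str = "mean") -> tuple[PooledAttribution, list[AttributionMap]]:
    """Pooled attribution over patients correctly classified in validation.

    Each cross-validation fold's selected model attributes its own validation
    patients (score >= 0.5), so no subject is attributed by a model that saw
    it in training.
    """
    if not result.fold_models:
        raise DataError("cross-validation result carries no fold models")
    score_of = {sid: s for sid, _, s in result.per_subject}
    maps: list[AttributionMap] = []
    records: list[SubjectRecord] = []
    for model, val_ids in zip(result.fold_models, result.fold_validation_ids):
        for sid in val_ids:
            rec = dataset.record(sid)
            if rec.group != "patient" or score_of[sid] < 0.5:
                continue
            x = preprocess_matrix(dataset.matrices[metric][sid])
            maps.append(gradcam(model, x, target_class))
            records.append(rec)
    pooled = pool_attributions(maps, records, subgroup=subgroup, mode=mode)
    return pooled, maps
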