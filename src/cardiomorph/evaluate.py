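"""Agreement between manual and automatic cardiomyocyte detections.

For every cell i of the manual mask, the overlap with each automatic cell j
is the percentage of the manual box raster covered by the automatic box
raster:

    I_ij = 100 * |B_mi  intersect  B_aj| / |B_mi|.

Note the normalization by the manual area only — I_ij is deliberately
asymmetric.  The per-manual-cell agreement is the row maximum
``I_i = max_j I_ij`` (0 when there are no automatic cells).  The population
of I_i values is summarised by its integer percentile curve Pc(k),
k = 1..100, and the area under that curve

    AUC = 1e-4 * sum_{k=1}^{100} (Pc(k) + Pc(k+1)) / 2,

with the boundary extension Pc(101) := Pc(100), so a constant curve at c
integrates exactly to c/100 and perfect agreement gives AUC = 1.

Manual masks enter as boxes: they are run through the same
contour -> min-area-box pipeline as the automatic mask, and boxes are
rasterized with the shared pixel-centre rule, so both routes use identical
geometry conventions.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .config import PipelineConfig
from .detect import CMRecord, RotatedBox, detect_from_mask, rasterize_box
from .masks import BinaryMask

__all__ = [
    "OverlapResult",
    "PercentileAUC",
    "overlap_percent",
    "max_overlap",
    "percentile_curve",
    "auc",
    "evaluate",
    "evaluate_masks",
]


@dataclasses.dataclass
class OverlapResult:
    """Overlap matrix and per-manual-cell maxima.

    ``Ii_j`` has one row per manual cell and one column per automatic cell;
    ``Ii`` holds the row maxima; ``matched_over_50`` counts manual cells
    whose best overlap strictly exceeds 50%.
    """

    Ii_j: np.ndarray
    Ii: np.ndarray
    n_automatic: int
    n_manual: int
    matched_over_50: int


@dataclasses.dataclass
class PercentileAUC:
    """Integer percentile curve of the I_i population and its AUC."""

    Pc: np.ndarray
    AUC: float


def _flat_raster(box: RotatedBox, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = rasterize_box(box, shape)
    return rows.astype(np.int64) * shape[1] + cols.astype(np.int64)


def overlap_percent(
    manual_box: RotatedBox, automatic_box: RotatedBox, shape: tuple[int, int]
) -> float:
    """Percentage of the manual box raster covered by the automatic box."""
    m = _flat_raster(manual_box, shape)
    if m.size == 0:
        raise ValueError("manual box rasterizes to an empty pixel set")
    a = _flat_raster(automatic_box, shape)
    inter = np.intersect1d(m, a, assume_unique=True).size
    return 100.0 * inter / m.size


def max_overlap(
    manual_box: RotatedBox,
    automatic_boxes: Sequence[RotatedBox],
    shape: tuple[int, int],
) -> float:
    """Best overlap of one manual cell over all automatic cells (0 if none)."""
    if not automatic_boxes:
        return 0.0
    return max(overlap_percent(manual_box, b, shape) for b in automatic_boxes)


def percentile_curve(values: Sequence[float]) -> np.ndarray:
    """Pc(k) for integer percentiles k = 1..100, linearly interpolated."""
    values = np.asarray(list(values), float)
    if values.size == 0:
        raise ValueError("need at least one value")
    return np.percentile(values, np.arange(1, 101))


def auc(pc: np.ndarray) -> float:
    """Trapezoidal area under a percentile curve, scaled to [0, 1]."""
    pc = np.asarray(pc, float)
    if pc.shape != (100,):
        raise ValueError(f"expected 100 percentile values, got {pc.shape}")
    ext = np.append(pc, pc[-1])  # Pc(101) := Pc(100)
    return float(np.sum((ext[:-1] + ext[1:]) / 2.0) / 1e4)


def evaluate(
    manual_records: Sequence[CMRecord],
    automatic_records: Sequence[CMRecord],
    shape: tuple[int, int],
) -> tuple[OverlapResult, PercentileAUC]:
    """Full agreement evaluation between two detection record lists."""
    nm, na = len(manual_records), len(automatic_records)
    if nm == 0:
        raise ValueError("no manual cells to evaluate against")
    rasters_m = [_flat_raster(r.box, shape) for r in manual_records]
    rasters_a = [_flat_raster(r.box, shape) for r in automatic_records]
    matrix = np.zeros((nm, na))
    for i, m in enumerate(rasters_m):
        if m.size == 0:
            raise ValueError(f"manual cell {i} rasterizes to an empty pixel set")
        for j, a in enumerate(rasters_a):
            inter = np.intersect1d(m, a, assume_unique=True).size
            matrix[i, j] = 100.0 * inter / m.size
    ii = matrix.max(axis=1) if na > 0 else np.zeros(nm)
    pc = percentile_curve(ii)
    result = OverlapResult(
        Ii_j=matrix,
        Ii=ii,
        n_automatic=na,
        n_manual=nm,
        matched_over_50=int((ii > 50.0).sum()),
    )
    return result, PercentileAUC(Pc=pc, AUC=auc(pc))


def evaluate_masks(
    manual_mask: BinaryMask,
    automatic_records: Sequence[CMRecord],
    config: PipelineConfig,
) -> tuple[OverlapResult, PercentileAUC, list[CMRecord]]:
    """Evaluate automatic detections against a manually delineated CM mask.

    The manual mask is run through the same geometry pipeline (contours,
    plausibility filters, min-area boxes) before comparison; the manual
    records are returned alongside the evaluation.
    """
    manual_records = detect_from_mask(manual_mask, config)
    result, pauc = evaluate(manual_records, automatic_records, manual_mask.shape)
    return result, pauc, manual_records
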