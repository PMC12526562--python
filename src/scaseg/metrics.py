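"""Segmentation quality metrics: overlap (DSC, IoU, sensitivity,
specificity, precision) and surface distances (HD95, ASD, NSD).

Surfaces are voxel sets: a foreground voxel is a surface voxel iff at least
one of its six axial neighbors is background or lies outside the grid.
Distances are Euclidean, in mm, between voxel centers; HD95/ASD/NSD are
computed on the pooled symmetric set of nearest-surface distances, which
makes them invariant under swapping prediction and truth.  Metrics that are
undefined for empty masks (e.g. sensitivity with empty truth) propagate as
NaN rather than zero so cohort means stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import LABEL_CODES, STRUCTURES, MetricConfig
from .volumes import LabelVolume

_SIX = ndimage.generate_binary_structure(3, 1)


def overlap_metrics(pred_mask: np.ndarray, truth_mask: np.ndarray) -> Dict[str, float]:
    """Confusion-table metrics for a binary mask pair."""
    pred_mask = np.asarray(pred_mask, dtype=bool)
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if pred_mask.shape != truth_mask.shape:
        raise ValueError("mask shape mismatch")
    tp = int(np.count_nonzero(pred_mask & truth_mask))
    fp = int(np.count_nonzero(pred_mask & ~truth_mask))
    fn = int(np.count_nonzero(~pred_mask & truth_mask))
    tn = int(pred_mask.size - tp - fp - fn)
    nan = float("nan")
    return {
        "dsc": 2 * tp / (2 * tp + fp + fn) if tp + fp + fn else nan,
        "iou": tp / (tp + fp + fn) if tp + fp + fn else nan,
        "sensitivity": tp / (tp + fn) if tp + fn else nan,
        "specificity": tn / (tn + fp) if tn + fp else nan,
        "precision": tp / (tp + fp) if tp + fp else nan,
    }


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (n, 3) of the 6-connectivity surface voxels of a mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, 3), dtype=np.intp)
    eroded = ndimage.binary_erosion(mask, structure=_SIX, border_value=0)
    return np.argwhere(mask & ~eroded)


def boundary_metrics(pred_mask: np.ndarray, truth_mask: np.ndarray,
                     spacing=(1.0, 1.0, 1.0),
                     cfg: Optional[MetricConfig] = None) -> Dict[str, float]:
    """HD95 / ASD / NSD from the pooled symmetric surface-distance set."""
    cfg = cfg or MetricConfig()
    cfg.validate()
    sp = surface_voxels(pred_mask).astype(float) * np.asarray(spacing)
    st = surface_voxels(truth_mask).astype(float) * np.asarray(spacing)
    nan = float("nan")
    if len(sp) == 0 or len(st) == 0:
        return {"hd95_mm": nan, "asd_mm": nan, "nsd": nan}
    d_pt = cKDTree(st).query(sp, k=1)[0]
    d_tp = cKDTree(sp).query(st, k=1)[0]
    pooled = np.concatenate([d_pt, d_tp])
    return {
        "hd95_mm": float(np.percentile(pooled, cfg.hd_percentile)),
        "asd_mm": float(pooled.mean()),
        "nsd": float(np.mean(pooled <= cfg.nsd_tolerance_mm)),
    }


@dataclass
class MetricReport:
    """Per-case metrics: per-structure DSC plus full-brainstem overlap and
    boundary measures."""

    dsc_per_structure: Dict[str, float]
    full: Dict[str, float] = field(default_factory=dict)

    def to_row(self) -> Dict[str, float]:
        row = {f"dsc_{s}": v for s, v in self.dsc_per_structure.items()}
        row.update(self.full)
        return row


def evaluate_case(pred: LabelVolume, truth: LabelVolume,
                  cfg: Optional[MetricConfig] = None) -> MetricReport:
    """Evaluate one parcellation against ground truth.

    Per-structure DSC for medulla/pons/mesencephalon; the full set of
    metrics on the whole-brainstem union (codes 1-3).  A structure absent
    from the truth is reported as NaN.
    """
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch between prediction and truth")
    if not np.allclose(pred.spacing, truth.spacing):
        raise ValueError("spacing mismatch between prediction and truth")
    cfg = cfg or MetricConfig()
    dscs = {}
    for s in STRUCTURES:
        code = LABEL_CODES[s]
        tmask = truth.data == code
        if not tmask.any():
            dscs[s] = float("nan")
            continue
        dscs[s] = overlap_metrics(pred.data == code, tmask)["dsc"]
    pu = pred.data > 0
    tu = truth.data > 0
    full = overlap_metrics(pu, tu)
    full["dsc_full"] = full.pop("dsc")
    full.update(boundary_metrics(pu, tu, truth.spacing, cfg))
    return MetricReport(dsc_per_structure=dscs, full=full)


def evaluate_batch(cases, cfg: Optional[MetricConfig] = None,
                   csv_path=None) -> pd.DataFrame:
    """Evaluate (case_id, pred, truth) triples; appends mean and sd summary
    rows and optionally writes the table as CSV."""
    rows = []
    for case_id, pred, truth in cases:
        row = {"case": case_id}
        row.update(evaluate_case(pred, truth, cfg).to_row())
        rows.append(row)
    df = pd.DataFrame(rows)
    numeric = df.drop(columns=["case"])
    summary = pd.DataFrame([
        {"case": "mean", **numeric.mean(skipna=True).to_dict()},
        {"case": "sd", **numeric.std(skipna=True, ddof=1).to_dict()},
    ])
    out = pd.concat([df, summary], ignore_index=True)
    if csv_path is not None:
        out.to_csv(csv_path, index=False)
    return out
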