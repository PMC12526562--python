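"""Brainstem volumetry and cohort statistics.

Structure volumes are voxel counts times the voxel volume, computed in
template space on uncropped label volumes, then normalized as a percentage
of total intracranial volume (%TICV).  Group differences use the
Kruskal-Wallis rank test; clinical associations use Spearman rank
correlations (4 structures x 3 scores = 12 tests) with Bonferroni
adjustment (``p_adj = min(1, 12 p)``; family-wise threshold
``0.05 / 12 = 0.0042``).  SARA and CAG correlations pool patients and
preclinical carriers; disease duration is restricted to patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import GROUPS, LABEL_CODES, STRUCTURES
from .volumes import LabelVolume

ALL_STRUCTURES = STRUCTURES + ("whole_brainstem",)
N_TESTS = 12
ALPHA = 0.05


def label_volumes(labels: LabelVolume, spacing=None) -> Dict[str, float]:
    """Structure volumes in mm^3; whole brainstem is the union of codes 1-3."""
    sp = spacing if spacing is not None else labels.spacing
    voxvol = float(np.prod(sp))
    out = {}
    for s in STRUCTURES:
        out[s] = float(np.count_nonzero(labels.data == LABEL_CODES[s])) * voxvol
    out["whole_brainstem"] = float(np.count_nonzero(labels.data > 0)) * voxvol
    return out


def percent_ticv(volume_mm3: float, ticv_mm3: float) -> float:
    if ticv_mm3 <= 0:
        raise ValueError("TICV must be positive")
    return 100.0 * volume_mm3 / ticv_mm3


def group_compare(values_by_group: Dict[str, np.ndarray]) -> Tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value."""
    samples = [np.asarray(v, dtype=float) for v in values_by_group.values()
               if len(v) > 0]
    if len(samples) < 2:
        raise ValueError("need at least two nonempty groups")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def bonferroni(p: float, m: int = N_TESTS) -> float:
    return float(min(1.0, p * m))


def significance_threshold(m: int = N_TESTS, alpha: float = ALPHA) -> float:
    """Per-test threshold alpha/m, reported rounded to 4 decimals."""
    return round(alpha / m, 4)


def subject_volumetry(cases) -> pd.DataFrame:
    """Per-subject table of structure volumes (mm^3) and %TICV.

    ``cases`` yields ``(record, labels)`` pairs where record carries group,
    clinical scores and TICV.
    """
    rows = []
    for record, labels in cases:
        vols = label_volumes(labels)
        row = {
            "subject_id": record.subject_id, "group": record.group,
            "sara": record.sara, "cag": record.cag,
            "duration_years": record.duration_years,
            "ticv_mm3": record.ticv_mm3,
        }
        for s in ALL_STRUCTURES:
            row[f"{s}_mm3"] = vols[s]
            row[f"{s}_pct_ticv"] = percent_ticv(vols[s], record.ticv_mm3)
        rows.append(row)
    return pd.DataFrame(rows)


def group_statistics(table: pd.DataFrame) -> pd.DataFrame:
    """Group mean %TICV per structure plus the Kruskal-Wallis test."""
    rows = []
    for s in ALL_STRUCTURES:
        col = f"{s}_pct_ticv"
        by_group = {g: table.loc[table["group"] == g, col].to_numpy()
                    for g in GROUPS if (table["group"] == g).any()}
        h, p = group_compare(by_group) if len(by_group) >= 2 else (float("nan"),) * 2
        row = {"structure": s, "kw_h": h, "kw_p": p}
        for g in GROUPS:
            vals = by_group.get(g, np.array([]))
            row[f"mean_{g}"] = float(vals.mean()) if len(vals) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def clinical_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations of structure %TICV with SARA, disease duration
    and CAG repeat length, Bonferroni-adjusted over the 12 tests."""
    carriers = table[table["group"].isin(["patient", "preclinical"])]
    patients = table[table["group"] == "patient"]
    score_frames = [("sara", carriers, "sara"),
                    ("duration", patients, "duration_years"),
                    ("cag", carriers, "cag")]
    rows = []
    for s in ALL_STRUCTURES:
        col = f"{s}_pct_ticv"
        for score, frame, score_col in score_frames:
            sub = frame[[col, score_col]].dropna()
            n = len(sub)
            if n < 3:
                rows.append({"structure": s, "score": score, "n": n,
                             "r": float("nan"), "p_raw": float("nan"),
                             "p_adj": float("nan"), "significant": False})
                continue
            r, p = stats.spearmanr(sub[col], sub[score_col])
            p_adj = bonferroni(float(p))
            rows.append({"structure": s, "score": score, "n": n,
                         "r": float(r), "p_raw": float(p), "p_adj": p_adj,
                         "significant": bool(p_adj < ALPHA)})
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = N_TESTS
    out.attrs["threshold"] = significance_threshold()
    return out


@dataclass
class CohortVolumetry:
    """Per-subject volumetry with group statistics and clinical
    correlations for a whole cohort."""

    table: pd.DataFrame
    group_stats: pd.DataFrame
    correlations: pd.DataFrame

    def write(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "volumetry.csv", index=False)
        self.group_stats.to_csv(out / "group_stats.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)


def cohort_volumetry(cases, out_dir=None) -> CohortVolumetry:
    """Full volumetric analysis of ``(record, labels)`` pairs."""
    table = subject_volumetry(cases)
    result = CohortVolumetry(
        table=table,
        group_stats=group_statistics(table),
        correlations=clinical_correlations(table),
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
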