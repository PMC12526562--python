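"""Synthetic template-space T1 phantoms of a three-part brainstem.

Real cohort MRI cannot be redistributed, so every downstream stage is
exercised on phantoms: a head-like ellipsoid (whose voxelized volume defines
the total intracranial volume, TICV) containing three stacked solids —
a narrow inferior cylinder (medulla), a wide middle ellipsoid (pons) and a
medium superior cylinder (mesencephalon).  Solid dimensions are solved
analytically so each structure's expected volume fraction equals the
configured group target (in % TICV) times a multiplicative noise factor;
group targets default to the cohort means reported for SCA2 patients,
preclinical carriers and controls.  The geometry is deliberately schematic:
the quantities under test are volumetric and statistical, not shape realism.

Intensities follow per-tissue-class means modulated by a smooth degree-2
polynomial bias field and additive Gaussian noise; labels are exact and
independent of the intensity model.  All randomness flows through one seeded
generator per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import GROUPS, LABEL_CODES, STRUCTURES, PhantomSpec
from .volumes import LabelVolume, VolumeGrid, write_volume

#: aspect ratios of the schematic solids (height as a multiple of radius for
#: the cylinders, polar over equatorial semi-axis for the pons ellipsoid)
MEDULLA_ASPECT = 5.0
MESENCEPHALON_ASPECT = 2.5
PONS_POLAR_RATIO = 0.75
HEAD_FILL = 0.42  # head semi-axes as a fraction of the grid extent


@dataclass
class SubjectRecord:
    """Per-subject metadata mirroring the cohort manifest."""

    subject_id: str
    group: str
    sara: float
    cag: int
    duration_years: Optional[float]
    ticv_mm3: float

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 0 <= self.sara <= 40:
            raise ValueError("SARA outside [0, 40]")
        if not 14 <= self.cag <= 60:
            raise ValueError("CAG outside plausible range [14, 60]")
        if (self.duration_years is not None) != (self.group == "patient"):
            raise ValueError("disease duration present iff group == patient")
        if self.ticv_mm3 <= 0:
            raise ValueError("TICV must be positive")


def _coordinate_grids(shape, spacing):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Random degree-2 polynomial in normalized coordinates, min-max scaled
    to [1 - amplitude, 1 + amplitude]; mimics pre-correction inhomogeneity."""
    if amplitude == 0:
        return np.ones(shape, dtype=np.float64)
    u = [np.linspace(-1.0, 1.0, n) for n in shape]
    U = np.meshgrid(*u, indexing="ij", sparse=True)
    monomials = [np.ones(shape)]
    for i in range(3):
        monomials.append(U[i] + np.zeros(shape))
    for i in range(3):
        for j in range(i, 3):
            monomials.append(U[i] * U[j] + np.zeros(shape))
    coeffs = rng.normal(size=len(monomials))
    field = sum(c * m for c, m in zip(coeffs, monomials))
    lo, hi = field.min(), field.max()
    if hi <= lo:
        return np.ones(shape, dtype=np.float64)
    return 1.0 - amplitude + 2.0 * amplitude * (field - lo) / (hi - lo)


def generate_phantom(spec: PhantomSpec, group: str, subject_id: str,
                     seed: int) -> Tuple[VolumeGrid, LabelVolume, SubjectRecord]:
    """Build one phantom image/label pair and its subject record.

    Identical ``(spec, group, subject_id, seed)`` give bit-identical output.
    Clinical scores in the returned record are neutral placeholders; see
    :func:`sample_clinical_scores`.
    """
    spec.validate()
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    shape = tuple(spec.grid_shape)
    spacing = tuple(spec.spacing)
    voxvol = float(np.prod(spacing))
    X, Y, Z = _coordinate_grids(shape, spacing)
    extent = [n * s for n, s in zip(shape, spacing)]
    center = np.array([e / 2.0 for e in extent])
    head_semi = np.array([HEAD_FILL * e for e in extent])

    head = ((X - center[0]) / head_semi[0]) ** 2 \
        + ((Y - center[1]) / head_semi[1]) ** 2 \
        + ((Z - center[2]) / head_semi[2]) ** 2 <= 1.0
    ticv_mm3 = float(head.sum()) * voxvol

    # target volumes (mm^3) with per-structure multiplicative noise
    targets = spec.group_fraction_targets[group]
    noise = rng.normal(1.0, spec.relative_volume_noise, size=len(STRUCTURES))
    noise = np.clip(noise, 0.2, None)
    vols = {s: targets[s] / 100.0 * ticv_mm3 * float(f)
            for s, f in zip(STRUCTURES, noise)}

    # sub-voxel jitter of the common axis decorrelates discretization error
    jitter = rng.uniform(-0.5, 0.5, size=3) * np.asarray(spacing)
    cx, cy, cz = center + jitter

    a_p = (vols["pons"] / (math.pi * PONS_POLAR_RATIO * 4.0 / 3.0)) ** (1.0 / 3.0)
    c_p = PONS_POLAR_RATIO * a_p
    r_m = (vols["medulla"] / (MEDULLA_ASPECT * math.pi)) ** (1.0 / 3.0)
    h_m = MEDULLA_ASPECT * r_m
    r_x = (vols["mesencephalon"] / (MESENCEPHALON_ASPECT * math.pi)) ** (1.0 / 3.0)
    h_x = MESENCEPHALON_ASPECT * r_x

    rho2 = (X - cx) ** 2 + (Y - cy) ** 2
    labels = np.zeros(shape, dtype=np.int16)
    pons = (rho2 / a_p ** 2 + (Z - cz) ** 2 / c_p ** 2) <= 1.0
    medulla = (rho2 <= r_m ** 2) & (Z < cz - c_p) & (Z >= cz - c_p - h_m)
    mes = (rho2 <= r_x ** 2) & (Z > cz + c_p) & (Z <= cz + c_p + h_x)
    labels[medulla] = LABEL_CODES["medulla"]
    labels[pons] = LABEL_CODES["pons"]
    labels[mes] = LABEL_CODES["mesencephalon"]

    if np.any((labels > 0) & ~head):
        raise ValueError("fractions too large for grid: structures exceed the head mask")

    means = spec.intensity_means
    image = np.full(shape, means["background"], dtype=np.float64)
    image[head] = means["head"]
    for s in STRUCTURES:
        image[labels == LABEL_CODES[s]] = means[s]
    image *= _bias_field(shape, spec.bias_amplitude, rng)
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=shape)

    record = SubjectRecord(
        subject_id=subject_id, group=group, sara=0.0,
        cag=38 if group != "control" else 20,
        duration_years=0.0 if group == "patient" else None,
        ticv_mm3=ticv_mm3,
    )
    return (VolumeGrid(image, spacing), LabelVolume(labels, spacing), record)


def sample_clinical_scores(record: SubjectRecord, whole_brainstem_fraction: float,
                           coupling: float, seed: int,
                           fraction_loc: float = 1.40,
                           fraction_scale: float = 0.25) -> SubjectRecord:
    """Draw SARA/CAG/duration so that, over a carrier population, the
    Spearman correlation of SARA with the whole-brainstem fraction
    approaches ``-|coupling|`` (smaller brainstem, worse ataxia).

    Uses a Gaussian copula: the latent severity is
    ``a * (-z) + sqrt(1 - a^2) * eps`` with ``z`` the standardized fraction
    and ``a = 2 sin(pi * |coupling| / 6)``, the coefficient for which the
    bivariate-normal Spearman correlation equals ``|coupling|``; a strictly
    monotone logistic map then takes the latent score onto [0, 40] without
    introducing ties.  Controls receive SARA near zero and a normal-range
    CAG; carriers draw CAG uniformly from the expanded range {36..40};
    disease duration is sampled for patients only.
    """
    if abs(coupling) > 1:
        raise ValueError("|coupling| must be <= 1")
    if whole_brainstem_fraction <= 0:
        raise ValueError("whole-brainstem fraction must be positive")
    if fraction_scale <= 0:
        raise ValueError("fraction_scale must be positive")
    rng = np.random.default_rng(seed)
    if record.group == "control":
        sara = float(min(abs(rng.normal(0.0, 0.75)), 2.0))
        cag = int(rng.integers(14, 32))
        duration = None
    else:
        a = 2.0 * math.sin(math.pi * abs(coupling) / 6.0)
        z = (whole_brainstem_fraction - fraction_loc) / fraction_scale
        eps = rng.normal()
        latent = a * (-z) + math.sqrt(max(0.0, 1.0 - a * a)) * eps
        sara = 40.0 / (1.0 + math.exp(-latent))
        cag = int(rng.integers(36, 41))
        duration = float(rng.uniform(1.0, 31.0)) if record.group == "patient" else None
    out = SubjectRecord(record.subject_id, record.group, sara, cag,
                        duration, record.ticv_mm3)
    out.validate()
    return out


def _measured_whole_fraction(labels: LabelVolume, ticv_mm3: float) -> float:
    vox = int(np.count_nonzero(labels.data))
    return 100.0 * vox * labels.voxel_volume_mm3 / ticv_mm3


def generate_cohort(spec: PhantomSpec, n_per_group: Dict[str, int], seed: int,
                    out_dir=None, coupling: float = 0.7):
    """Generate a full cohort; returns ``(cases, manifest)`` where cases is a
    list of ``(image, labels, record)`` and manifest a DataFrame with one row
    per subject.  Deterministic under ``seed``; optionally writes NIfTI pairs
    and ``manifest.csv`` under ``out_dir``."""
    spec.validate()
    if any(n < 0 for n in n_per_group.values()):
        raise ValueError("n_per_group must be nonnegative")
    total = sum(n_per_group.values())
    if total == 0:
        raise ValueError("empty cohort")
    unknown = set(n_per_group) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown groups: {sorted(unknown)}")

    # common standardization over the carrier mixture so the pooled
    # volume-SARA coupling spans both between- and within-group variance
    carrier_groups = [g for g in ("patient", "preclinical") if n_per_group.get(g, 0) > 0]
    if carrier_groups:
        w = np.array([n_per_group[g] for g in carrier_groups], dtype=float)
        w /= w.sum()
        mus = np.array([sum(spec.group_fraction_targets[g].values())
                        for g in carrier_groups])
        loc = float(w @ mus)
        var_between = float(w @ (mus - loc) ** 2)
        var_within = float(w @ (mus * spec.relative_volume_noise) ** 2)
        scale = math.sqrt(var_between + var_within) if var_between + var_within > 0 else 0.25
    else:
        loc, scale = 1.40, 0.25

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * total)
    cases = []
    rows = []
    idx = 0
    for group in GROUPS:
        for k in range(n_per_group.get(group, 0)):
            sid = f"{group[:3]}{k + 1:03d}"
            phantom_seed = children[2 * idx]
            score_seed = children[2 * idx + 1]
            image, labels, record = generate_phantom(
                spec, group, sid, phantom_seed.generate_state(1)[0] % (2 ** 31))
            frac = _measured_whole_fraction(labels, record.ticv_mm3)
            record = sample_clinical_scores(
                record, frac, coupling, score_seed.generate_state(1)[0] % (2 ** 31),
                fraction_loc=loc, fraction_scale=scale)
            cases.append((image, labels, record))
            rows.append({
                "subject_id": record.subject_id, "group": record.group,
                "sara": record.sara, "cag": record.cag,
                "duration_years": record.duration_years,
                "ticv_mm3": record.ticv_mm3,
            })
            idx += 1
    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "sara", "cag",
                                           "duration_years", "ticv_mm3"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for image, labels, record in cases:
            write_volume(image, out / f"{record.subject_id}_t1.nii.gz")
            write_volume(labels, out / f"{record.subject_id}_labels.nii.gz")
        manifest.to_csv(out / "manifest.csv", index=False)
    return cases, manifest
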