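"""Volume containers, NIfTI I/O and the preprocessing primitives.

The pipeline operates on template-space T1 volumes.  Two thin containers
wrap the raw arrays: :class:`VolumeGrid` for scalar intensities and
:class:`LabelVolume` for the integer parcellation (0 background, 1 medulla,
2 pons, 3 mesencephalon).  Both carry voxel spacing in mm and the
voxel-to-world affine so crops stay anchored in template coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple, Union

import nibabel as nib
import numpy as np

from .config import LABEL_CODES, RoiBox

N_CLASSES = 4


def _default_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class VolumeGrid:
    """A 3D scalar image on a regular lattice with mm spacing."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (0.8, 0.8, 0.8)
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelVolume:
    """An integer parcellation lattice with codes {0, 1, 2, 3}."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (0.8, 0.8, 0.8)
    affine: np.ndarray = None
    code_map: dict = field(default_factory=lambda: dict(LABEL_CODES))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D label volume, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.round(self.data)):
                raise ValueError("label volume must be integer valued")
            self.data = self.data.astype(np.int16)
        if self.data.min() < 0 or self.data.max() >= N_CLASSES:
            raise ValueError("label codes must lie in {0, 1, 2, 3}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


Volume = Union[VolumeGrid, LabelVolume]


# ---------------------------------------------------------------- NIfTI I/O

def read_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI payload, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(np.asarray(data, dtype=np.float64), spacing, np.asarray(img.affine))


def read_labels(path) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI payload, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(np.rint(data).astype(np.int16), spacing, np.asarray(img.affine))


def write_volume(volume: Volume, path) -> None:
    data = volume.data
    dtype = np.int16 if isinstance(volume, LabelVolume) else np.float32
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


# ------------------------------------------------------------- crop/uncrop

def crop_roi(volume: Volume, roi: RoiBox) -> Volume:
    """Extract the half-open box ``[start, start+shape)``; affine translated
    so world coordinates of retained voxels are unchanged."""
    roi.validate(volume.shape)
    sl = tuple(slice(s, s + n) for s, n in zip(roi.start, roi.shape))
    affine = np.asarray(volume.affine, dtype=float).copy()
    affine[:3, 3] += affine[:3, :3] @ np.asarray(roi.start, dtype=float)
    if isinstance(volume, LabelVolume):
        return LabelVolume(volume.data[sl].copy(), volume.spacing, affine, dict(volume.code_map))
    return VolumeGrid(volume.data[sl].copy(), volume.spacing, affine)


def uncrop(labels: LabelVolume, roi: RoiBox, full_shape: Tuple[int, int, int]) -> LabelVolume:
    """Paste a cropped label block back into a background-filled full grid."""
    if tuple(labels.shape) != tuple(roi.shape):
        raise ValueError("label shape does not match the ROI shape")
    roi.validate(full_shape)
    out = np.zeros(full_shape, dtype=labels.data.dtype)
    sl = tuple(slice(s, s + n) for s, n in zip(roi.start, roi.shape))
    out[sl] = labels.data
    affine = np.asarray(labels.affine, dtype=float).copy()
    affine[:3, 3] -= affine[:3, :3] @ np.asarray(roi.start, dtype=float)
    return LabelVolume(out, labels.spacing, affine, dict(labels.code_map))


def derive_roi(label_volumes, shape: Tuple[int, int, int] = (80, 80, 96)) -> RoiBox:
    """Place the crop box around the pooled foreground bounding box of a set
    of reference segmentations, with symmetric margins, clipped in-bounds."""
    label_volumes = list(label_volumes)
    if not label_volumes:
        raise ValueError("need at least one reference segmentation")
    full = label_volumes[0].shape
    lo = np.array(full, dtype=int)
    hi = np.zeros(3, dtype=int)
    for lab in label_volumes:
        fg = np.argwhere(lab.data > 0)
        if fg.size == 0:
            continue
        lo = np.minimum(lo, fg.min(axis=0))
        hi = np.maximum(hi, fg.max(axis=0) + 1)
    if np.any(hi <= lo):
        raise ValueError("reference segmentations contain no foreground")
    if any(h - l > n for h, l, n in zip(hi, lo, shape)):
        raise ValueError("foreground larger than the requested ROI shape")
    center = (lo + hi) / 2.0
    start = np.rint(center - np.asarray(shape) / 2.0).astype(int)
    start = np.clip(start, 0, np.asarray(full) - np.asarray(shape))
    return RoiBox(start=tuple(int(s) for s in start), shape=tuple(shape))


# ------------------------------------------------------------ normalization

def normalize_intensity(volume: VolumeGrid, lower_pct: float = 0.5,
                        upper_pct: float = 99.5) -> VolumeGrid:
    """Percentile-clipped min-max normalization to [0, 1].

    Intensities are clipped to the [lower_pct, upper_pct] percentile window
    (robust to bias-field tails) and affinely mapped so the window spans
    [0, 1].  Raises on a constant image, whose window is degenerate.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    lo, hi = np.percentile(data, [lower_pct, upper_pct])
    if hi <= lo:
        raise ValueError("degenerate intensity range; cannot normalize")
    out = (np.clip(data, lo, hi) - lo) / (hi - lo)
    return VolumeGrid(out, volume.spacing, np.asarray(volume.affine).copy())


# ------------------------------------------------------- one-hot / argmax

def one_hot(labels: LabelVolume, n_classes: int = N_CLASSES) -> np.ndarray:
    """Channel-first indicator lattice of shape ``(n_classes, *vol_shape)``."""
    if labels.data.max() >= n_classes:
        raise ValueError("label code >= n_classes")
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels.data == c
    return out


def argmax_labels(scores: np.ndarray, spacing=(0.8, 0.8, 0.8), affine=None) -> LabelVolume:
    """Collapse a channel-first score lattice to codes; ties break toward the
    lower channel index (numpy argmax convention)."""
    scores = np.asarray(scores)
    if scores.ndim != 4:
        raise ValueError("expected a (channels, x, y, z) score lattice")
    codes = np.argmax(scores, axis=0).astype(np.int16)
    return LabelVolume(codes, spacing, affine)
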