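"""Training protocol: Dice loss, rigid augmentation, stratified splits,
Adam optimization and inference.

The loss is one minus the soft Dice score averaged across output channels
(all four by default, background included; a foreground-only variant is
available through :class:`~scaseg.config.TrainConfig`).  Augmented copies
are generated ahead of training as a fixed expanded set, one random rigid
transform per copy.
"""

from __future__ import annotations

import copy
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import AugmentConfig, TrainConfig
from .network import NetworkHandle
from .nn import Adam, F32
from .volumes import LabelVolume, VolumeGrid, argmax_labels, one_hot

Pair = Tuple[VolumeGrid, LabelVolume]


# ------------------------------------------------------------------- loss

def soft_dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-5,
                   channels: str = "all") -> float:
    """``1 - mean_c (2 sum(p_c g_c) + eps) / (sum p_c + sum g_c + eps)``."""
    loss, _ = soft_dice_loss_grad(pred, target, eps, channels, need_grad=False)
    return loss


def soft_dice_loss_grad(pred: np.ndarray, target: np.ndarray, eps: float = 1e-5,
                        channels: str = "all", need_grad: bool = True):
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError("pred/target shape mismatch")
    c = pred.shape[0]
    sel = np.arange(c) if channels == "all" else np.arange(1, c)
    p = pred.reshape(c, -1)
    g = target.reshape(c, -1)
    inter = (p * g).sum(axis=1)
    num = 2.0 * inter + eps
    den = p.sum(axis=1) + g.sum(axis=1) + eps
    dsc = num / den
    loss = float(1.0 - dsc[sel].mean())
    if not need_grad:
        return loss, None
    grad = np.zeros_like(pred, dtype=F32)
    gf = grad.reshape(c, -1)
    k = len(sel)
    for ci in sel:
        gf[ci] = -(2.0 * g[ci] * den[ci] - num[ci]) / (den[ci] ** 2 * k)
    return loss, grad


# ------------------------------------------------------------ augmentation

def _rigid_transform(image: VolumeGrid, labels: LabelVolume,
                     angles_deg: Sequence[float], shifts: Sequence[int],
                     flip: bool) -> Pair:
    """Apply one rigid transform: per-axis rotations about the volume
    center, integer voxel shifts, optional left-right (first axis) flip.
    Linear interpolation for the image, nearest-neighbor for labels,
    out-of-field filled with background."""
    shape = np.asarray(image.shape, dtype=float)
    center = (shape - 1) / 2.0
    ax, ay, az = np.deg2rad(angles_deg)
    rx = np.array([[1, 0, 0],
                   [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                   [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0],
                   [np.sin(az), np.cos(az), 0],
                   [0, 0, 1]])
    rot = rz @ ry @ rx
    fl = np.diag([-1.0, 1.0, 1.0]) if flip else np.eye(3)
    # output voxel v samples input at A @ (v - c - t) + c
    amat = fl @ rot.T
    offset = center - amat @ (center + np.asarray(shifts, dtype=float))
    img = ndimage.affine_transform(image.data, amat, offset=offset, order=1,
                                   mode="constant", cval=0.0)
    lab = ndimage.affine_transform(labels.data, amat, offset=offset, order=0,
                                   mode="constant", cval=0)
    return (VolumeGrid(img, image.spacing, np.asarray(image.affine).copy()),
            LabelVolume(lab.astype(labels.data.dtype), labels.spacing,
                        np.asarray(labels.affine).copy()))


def augment_volume(image: VolumeGrid, labels: LabelVolume,
                   cfg: AugmentConfig, seed: int) -> Pair:
    """One seeded random rigid augmentation of an image/label pair."""
    cfg.validate()
    if image.shape != labels.shape:
        raise ValueError("image/label shape mismatch")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg, 3)
    t = cfg.translation_range_vox
    shifts = rng.integers(-t, t + 1, 3) if t > 0 else np.zeros(3, dtype=int)
    flip = bool(rng.random() < cfg.flip_probability)
    if not np.any(angles) and not np.any(shifts) and not flip:
        return image, labels
    return _rigid_transform(image, labels, angles, shifts, flip)


def expand_training_set(pairs: List[Pair], cfg: AugmentConfig) -> List[Pair]:
    """Originals plus ``copies_per_image`` random rigid copies of each."""
    if not pairs:
        raise ValueError("empty training set")
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(len(pairs) * cfg.copies_per_image) % (2 ** 31)
    out: List[Pair] = list(pairs)
    k = 0
    for image, labels in pairs:
        for _ in range(cfg.copies_per_image):
            out.append(augment_volume(image, labels, cfg, int(seeds[k])))
            k += 1
    return out


# ------------------------------------------------------------------ splits

def stratified_split(manifest: pd.DataFrame, counts_per_split, seed: int):
    """Partition a cohort manifest into train/validation/test so that every
    clinical group is represented in every split whenever the requested
    counts allow it.  Deterministic under ``seed``."""
    if isinstance(counts_per_split, dict):
        counts = [counts_per_split[k] for k in ("train", "val", "test")]
    else:
        counts = list(counts_per_split)
    if len(counts) != 3 or any(c < 0 for c in counts):
        raise ValueError("need nonnegative counts for train/val/test")
    n = len(manifest)
    if sum(counts) != n:
        raise ValueError(f"split counts {counts} do not sum to cohort size {n}")
    rng = np.random.default_rng(seed)
    by_group = {g: list(rng.permutation(idx.to_numpy()))
                for g, idx in manifest.groupby("group").groups.items()}
    groups = sorted(by_group)
    assigned = {0: [], 1: [], 2: []}
    remaining = list(counts)
    # first pass: one subject of each group per split, where feasible
    for s in range(3):
        for g in groups:
            if remaining[s] > 0 and by_group[g]:
                assigned[s].append(by_group[g].pop())
                remaining[s] -= 1
    # second pass: fill remaining capacity from the largest groups
    for s in range(3):
        while remaining[s] > 0:
            g = max(groups, key=lambda g: len(by_group[g]))
            if not by_group[g]:
                raise ValueError("infeasible split counts")
            assigned[s].append(by_group[g].pop())
            remaining[s] -= 1
    out = []
    for s in range(3):
        part = manifest.loc[sorted(assigned[s])].reset_index(drop=True)
        out.append(part)
    return tuple(out)


# ---------------------------------------------------------------- training

def _to_xy(pair: Pair):
    image, labels = pair
    x = np.asarray(image.data, dtype=F32)[None]
    y = one_hot(labels)
    return x, y


def validation_dsc(handle: NetworkHandle, val_data) -> float:
    """Mean hard Dice over the foreground channels of the validation set."""
    scores = []
    for pair in val_data:
        x, y = _to_xy(pair)
        prob = handle.net.forward(x, training=False)
        pred = prob.argmax(axis=0)
        truth = y.argmax(axis=0)
        for c in range(1, y.shape[0]):
            tp = np.count_nonzero((pred == c) & (truth == c))
            sz = np.count_nonzero(pred == c) + np.count_nonzero(truth == c)
            if sz > 0:
                scores.append(2.0 * tp / sz)
    return float(np.mean(scores)) if scores else float("nan")


def train(handle: NetworkHandle, dataset: List[Pair],
          val_dataset: Optional[List[Pair]], cfg: TrainConfig):
    """Adam on the soft Dice loss with seeded shuffling; retains the weights
    of the epoch with the best validation Dice.  Returns
    ``(handle, history)`` where history has one row per epoch with the mean
    training loss and the validation Dice."""
    cfg.validate()
    if not dataset:
        raise ValueError("empty training set")
    net = handle.net
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params(), lr=cfg.learning_rate)
    data = [_to_xy(p) for p in dataset]
    history = []
    best_dsc = -np.inf
    best_state = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(data))
        losses = []
        opt.zero_grad()
        pending = 0
        for k, i in enumerate(order):
            x, y = data[i]
            prob = net.forward(x, training=True, rng=rng)
            loss, grad = soft_dice_loss_grad(prob, y, cfg.dice_smooth_eps,
                                             cfg.loss_channels)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, step {k}")
            losses.append(loss)
            net.backward(grad)
            pending += 1
            if pending >= cfg.batch_size or k == len(order) - 1:
                opt.step()
                opt.zero_grad()
                pending = 0
        vd = validation_dsc(handle, val_dataset) if val_dataset else float("nan")
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_dsc": vd})
        if val_dataset and (np.isnan(vd) is False) and vd > best_dsc:
            best_dsc = vd
            best_state = [p.value.copy() for p in net.params()]
    if best_state is not None:
        for p, v in zip(net.params(), best_state):
            p.value[...] = v
    return handle, pd.DataFrame(history, columns=["epoch", "train_loss", "val_dsc"])


def segment(handle: NetworkHandle, image: VolumeGrid) -> LabelVolume:
    """Argmax parcellation of a preprocessed (model-input-shaped) volume."""
    x = np.asarray(image.data, dtype=F32)[None]
    prob = handle.net.forward(x, training=False)
    return argmax_labels(prob, image.spacing, np.asarray(image.affine).copy())
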