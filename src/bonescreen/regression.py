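"""Areal-BMD regression from radiograph ROIs.

The regressor contract: each ROI is resampled to a 0.15 mm working
resolution, letterboxed to a 512 x 512 grid and min-max normalised; a
backbone encodes the grid as a feature vector; two fully connected layers
with a ReLU produce the estimated BMD; spine models additionally receive
the vertebra index (L1..L4) as a one-hot vector of length 4 appended to
the features before the last layer.  Training minimises the L1 distance
to DXA ground truth under fourfold cross-validation, and inference
averages the four fold-models (ensemble mean).

The bundled reference backbone is a fixed pooled-intensity encoder (8 x 8
block means plus global mean and standard deviation, 66 features); only
the two-layer head is trained, with full-batch Adam.  Any callable
mapping a preprocessed grid to a feature vector can replace it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .morphometry import VERTEBRA_LEVELS

__all__ = [
    "ROIImage",
    "BMDPrediction",
    "AugmentRanges",
    "TrainConfig",
    "BMDEnsemble",
    "preprocess_roi",
    "augment",
    "pooled_features",
    "predict_bmd",
    "train_reference_model",
    "fold_partition",
    "TARGET_SPACING_MM",
    "TARGET_SIZE",
]

logger = logging.getLogger(__name__)

TARGET_SPACING_MM = 0.15
TARGET_SIZE = 512
#: predictions are clamped at this floor (g/cm^2); clamping is logged
BMD_FLOOR = 0.01

ROI_SITES = ("hip_left", "hip_right", "vertebra")


@dataclass(frozen=True)
class ROIImage:
    """A single-channel intensity ROI with physical pixel spacing (mm)."""

    grid: np.ndarray
    pixel_spacing: float
    site: str
    vertebra_level: str | None = None
    roi_id: str | None = None

    def __post_init__(self) -> None:
        if self.site not in ROI_SITES:
            raise ValueError(f"site must be one of {ROI_SITES}")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be > 0")
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.size == 0 or min(g.shape) == 0:
            raise ValueError("grid must be a nonempty 2-D array")
        if (self.site == "vertebra") != (self.vertebra_level is not None):
            raise ValueError("vertebra_level must be present iff site == 'vertebra'")
        if self.vertebra_level is not None and self.vertebra_level not in VERTEBRA_LEVELS:
            raise ValueError(f"vertebra_level must be one of {VERTEBRA_LEVELS}")


@dataclass(frozen=True)
class BMDPrediction:
    """Ensemble BMD prediction for one ROI (g/cm^2)."""

    roi_id: str | None
    predicted_bmd: float
    member_predictions: tuple[float, float, float, float]
    model_version: str

    def __post_init__(self) -> None:
        members = self.member_predictions
        if len(members) != 4:
            raise ValueError("expected exactly 4 ensemble member predictions")
        mean = sum(members) / 4.0
        if abs(self.predicted_bmd - mean) > 1e-9:
            raise ValueError("predicted_bmd must equal the mean of the members")


def preprocess_roi(image: ROIImage) -> np.ndarray:
    """Resample to 0.15 mm spacing, letterbox to 512 x 512, min-max normalise.

    Steps: bilinear resample by ``pixel_spacing / 0.15``; if the resampled
    grid overflows 512 px it is scaled down uniformly to fit (letterbox),
    then padded symmetrically with zeros to 512 x 512; finally the full
    frame is min-max normalised to [0, 1] (a constant frame maps to 0.5).
    The result is deterministic and idempotent: a 512 x 512 frame already
    at 0.15 mm spacing passes through up to the normalisation.
    """
    grid = np.asarray(image.grid, dtype=np.float64)
    factor = image.pixel_spacing / TARGET_SPACING_MM
    if factor != 1.0:
        grid = ndimage.zoom(grid, factor, order=1)
    if max(grid.shape) > TARGET_SIZE:
        shrink = TARGET_SIZE / max(grid.shape)
        grid = ndimage.zoom(grid, shrink, order=1)
        grid = grid[:TARGET_SIZE, :TARGET_SIZE]  # guard against rounding overshoot
    pads = [(TARGET_SIZE - s) // 2 for s in grid.shape]
    out = np.zeros((TARGET_SIZE, TARGET_SIZE), dtype=np.float64)
    out[pads[0] : pads[0] + grid.shape[0], pads[1] : pads[1] + grid.shape[1]] = grid
    lo, hi = out.min(), out.max()
    if hi > lo:
        out = (out - lo) / (hi - lo)
    else:
        out = np.full_like(out, 0.5)
    return out


@dataclass(frozen=True)
class AugmentRanges:
    """Half-widths of the uniform affine-augmentation distributions."""

    rotation_deg: float = 10.0
    scale: float = 0.05
    translate_frac: float = 0.05
    shear_deg: float = 0.0

    def is_identity(self) -> bool:
        return (
            self.rotation_deg == 0
            and self.scale == 0
            and self.translate_frac == 0
            and self.shear_deg == 0
        )


def _affine_matrix(theta: float, scale: float, shear: float) -> np.ndarray:
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    sh = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    return rot @ sh * scale


def augment(
    grid: np.ndarray,
    rng: np.random.Generator,
    ranges: AugmentRanges = AugmentRanges(),
) -> np.ndarray:
    """Random affine transform (rotation, scale, translation, shear) about
    the grid centre.  All-zero ranges return the grid unchanged; a fixed
    generator state gives an identical transform."""
    if ranges.is_identity():
        return np.array(grid, copy=True)
    theta = np.deg2rad(rng.uniform(-ranges.rotation_deg, ranges.rotation_deg))
    scale = 1.0 + rng.uniform(-ranges.scale, ranges.scale)
    shear = np.deg2rad(rng.uniform(-ranges.shear_deg, ranges.shear_deg))
    h, w = grid.shape
    tx = rng.uniform(-ranges.translate_frac, ranges.translate_frac) * w
    ty = rng.uniform(-ranges.translate_frac, ranges.translate_frac) * h
    m = _affine_matrix(theta, scale, shear)
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([ty, tx])
    # output -> input mapping for ndimage.affine_transform
    m_inv = np.linalg.inv(m)
    offset = centre - m_inv @ (centre + shift)
    return ndimage.affine_transform(
        np.asarray(grid, dtype=np.float64), m_inv, offset=offset, order=1, cval=0.0
    )


def pooled_features(grid: np.ndarray) -> np.ndarray:
    """Reference backbone: 8 x 8 block means + global mean and SD (66-dim)."""
    g = np.asarray(grid, dtype=np.float64)
    if g.shape != (TARGET_SIZE, TARGET_SIZE):
        raise ValueError("backbone expects a preprocessed 512 x 512 grid")
    block = TARGET_SIZE // 8
    blocks = g.reshape(8, block, 8, block).mean(axis=(1, 3)).ravel()
    return np.concatenate([blocks, [g.mean(), g.std()]])


def _one_hot(level: str | None) -> np.ndarray:
    v = np.zeros(4)
    if level is not None:
        v[VERTEBRA_LEVELS.index(level)] = 1.0
    return v


class _Head:
    """Two fully connected layers with ReLU; the vertebra one-hot is
    appended to the hidden activations before the final layer."""

    def __init__(self, n_features: int, hidden: int, rng: np.random.Generator):
        self.w1 = rng.normal(0.0, 1.0 / np.sqrt(n_features), (n_features, hidden))
        self.b1 = np.zeros(hidden)
        self.w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden + 4), (hidden + 4, 1))
        self.b2 = np.zeros(1)

    def forward(self, x: np.ndarray, onehot: np.ndarray) -> np.ndarray:
        hid = np.maximum(x @ self.w1 + self.b1, 0.0)
        z = np.concatenate([hid, onehot], axis=1)
        return (z @ self.w2 + self.b2).ravel()

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]


def _train_head(
    head: _Head,
    x: np.ndarray,
    onehot: np.ndarray,
    y: np.ndarray,
    epochs: int,
    lr: float,
) -> list[float]:
    """Full-batch Adam on the mean L1 loss; returns the per-epoch loss log."""
    params = head.params()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    log: list[float] = []
    n = len(y)
    for epoch in range(1, epochs + 1):
        hid_pre = x @ head.w1 + head.b1
        hid = np.maximum(hid_pre, 0.0)
        z = np.concatenate([hid, onehot], axis=1)
        pred = (z @ head.w2 + head.b2).ravel()
        resid = pred - y
        log.append(float(np.mean(np.abs(resid))))
        g_out = np.sign(resid)[:, None] / n  # d(mean L1)/d(pred)
        g_w2 = z.T @ g_out
        g_b2 = g_out.sum(axis=0)
        g_hid = (g_out @ head.w2[: hid.shape[1]].T) * (hid_pre > 0)
        g_w1 = x.T @ g_hid
        g_b1 = g_hid.sum(axis=0)
        for p, g, mi, vi in zip(params, [g_w1, g_b1, g_w2, g_b2], m, v):
            mi[...] = beta1 * mi + (1 - beta1) * g
            vi[...] = beta2 * vi + (1 - beta2) * g**2
            mhat = mi / (1 - beta1**epoch)
            vhat = vi / (1 - beta2**epoch)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
    return log


@dataclass(frozen=True)
class TrainConfig:
    """Reference-model training configuration."""

    seed: int = 0
    epochs: int = 300
    hidden: int = 16
    learning_rate: float = 0.01
    n_folds: int = 4
    min_fold_size: int = 2
    augment_per_sample: int = 0
    augment_ranges: AugmentRanges = field(default_factory=AugmentRanges)


def fold_partition(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded random partition without replacement; fold sizes differ by
    at most one.  Returns the fold index of each sample."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % n_folds
    return folds


class BMDEnsemble:
    """Four fold-models plus frozen feature statistics and backbone."""

    def __init__(
        self,
        heads: Sequence[_Head],
        feat_mean: np.ndarray,
        feat_sd: np.ndarray,
        site: str,
        model_version: str = "bonescreen-ref-1",
        backbone: Callable[[np.ndarray], np.ndarray] = pooled_features,
    ):
        if len(heads) != 4:
            raise ValueError("ensemble requires exactly 4 members")
        self.heads = list(heads)
        self.feat_mean = np.asarray(feat_mean, dtype=float)
        self.feat_sd = np.asarray(feat_sd, dtype=float)
        self.site = site  # 'hip' or 'spine'
        self.model_version = model_version
        self.backbone = backbone
        self.training_log: list[list[float]] = []

    def _features(self, roi: ROIImage) -> np.ndarray:
        f = self.backbone(preprocess_roi(roi))
        return (f - self.feat_mean) / self.feat_sd

    def predict(self, roi: ROIImage) -> BMDPrediction:
        return predict_bmd(roi, self)

    # -- text-only persistence -------------------------------------------
    def save(self, path) -> None:
        payload = {
            "model_version": self.model_version,
            "site": self.site,
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "members": [
                {
                    "w1": h.w1.tolist(),
                    "b1": h.b1.tolist(),
                    "w2": h.w2.tolist(),
                    "b2": h.b2.tolist(),
                }
                for h in self.heads
            ],
            "training_log": self.training_log,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "BMDEnsemble":
        with open(path) as fh:
            payload = json.load(fh)
        heads = []
        for mem in payload["members"]:
            h = _Head.__new__(_Head)
            h.w1 = np.asarray(mem["w1"])
            h.b1 = np.asarray(mem["b1"])
            h.w2 = np.asarray(mem["w2"])
            h.b2 = np.asarray(mem["b2"])
            heads.append(h)
        ens = cls(
            heads,
            np.asarray(payload["feat_mean"]),
            np.asarray(payload["feat_sd"]),
            payload["site"],
            payload["model_version"],
        )
        ens.training_log = payload.get("training_log", [])
        return ens


def _site_group(site: str) -> str:
    return "hip" if site in ("hip_left", "hip_right") else "spine"


def predict_bmd(roi: ROIImage, ensemble: BMDEnsemble) -> BMDPrediction:
    """Ensemble-mean BMD for one ROI; members are the four fold-models."""
    if _site_group(roi.site) != ensemble.site:
        raise ValueError(
            f"ROI site {roi.site!r} does not match ensemble site {ensemble.site!r}"
        )
    x = ensemble._features(roi)[None, :]
    onehot = _one_hot(roi.vertebra_level)[None, :]
    members = []
    for head in ensemble.heads:
        val = float(head.forward(x, onehot)[0])
        if val < BMD_FLOOR:
            logger.warning("member prediction %.4f clamped to %.2f", val, BMD_FLOOR)
            val = BMD_FLOOR
        members.append(val)
    return BMDPrediction(
        roi_id=roi.roi_id,
        predicted_bmd=sum(members) / 4.0,
        member_predictions=tuple(members),
        model_version=ensemble.model_version,
    )


def train_reference_model(
    dataset: Sequence[tuple[ROIImage, float]],
    config: TrainConfig = TrainConfig(),
) -> BMDEnsemble:
    """Train the four-member reference ensemble.

    Each member is trained on three of four seeded random folds with the
    mean L1 loss; per-epoch losses are logged on the ensemble.  Optional
    affine augmentation adds ``augment_per_sample`` transformed copies of
    every training ROI.
    """
    n = len(dataset)
    if n < config.n_folds * config.min_fold_size:
        raise ValueError(
            f"dataset of {n} is too small for {config.n_folds} folds of "
            f">= {config.min_fold_size}"
        )
    sites = {_site_group(roi.site) for roi, _ in dataset}
    if len(sites) != 1:
        raise ValueError("dataset mixes hip and spine ROIs")
    site = sites.pop()

    rng = np.random.default_rng(config.seed)
    feats, onehots, targets = [], [], []
    for roi, bmd in dataset:
        grid = preprocess_roi(roi)
        feats.append(pooled_features(grid))
        onehots.append(_one_hot(roi.vertebra_level))
        targets.append(bmd)
        for _ in range(config.augment_per_sample):
            aug = augment(grid, rng, config.augment_ranges)
            feats.append(pooled_features(aug))
            onehots.append(_one_hot(roi.vertebra_level))
            targets.append(bmd)
    x_all = np.asarray(feats)
    oh_all = np.asarray(onehots)
    y_all = np.asarray(targets)
    # sample index of each (possibly augmented) row, for fold assignment
    reps = 1 + config.augment_per_sample
    sample_idx = np.repeat(np.arange(n), reps)

    feat_mean = x_all.mean(axis=0)
    feat_sd = x_all.std(axis=0)
    feat_sd[feat_sd == 0] = 1.0
    x_all = (x_all - feat_mean) / feat_sd

    folds = fold_partition(n, config.n_folds, config.seed)
    heads, logs = [], []
    for k in range(config.n_folds):
        mask = folds[sample_idx] != k
        head = _Head(x_all.shape[1], config.hidden, np.random.default_rng(config.seed + 1000 + k))
        logs.append(
            _train_head(
                head,
                x_all[mask],
                oh_all[mask],
                y_all[mask],
                config.epochs,
                config.learning_rate,
            )
        )
        heads.append(head)
    ens = BMDEnsemble(heads, feat_mean, feat_sd, site)
    ens.training_log = logs
    return ens
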