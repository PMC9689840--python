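"""Trainable operators: instance segmenter and landmark heatmap models.

Both are small encoder-decoder per-pixel convolutional networks built on
:mod:`limbalign.nn`, sized to train on a single CPU in minutes.  The
segmenter predicts a per-pixel class map that is turned into labeled
instances by connected components; the landmark models regress one
Gaussian heatmap per landmark on 256x256 crops (processed internally at
128x128) and are trained with the rotation/scale augmentation co-applied
to the landmark coordinates.

Checkpoints are single ``.npz`` files holding config, weights and the
label vocabulary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize, AffineTransform, warp

from . import nn
from .landmarks import (LandmarkSet, decode_heatmaps, landmark_schema,
                        make_landmark_set)

SEGMENT_LABELS = ("femur", "tibia", "fibula", "talus",
                  "implant_femoral", "implant_tibial")


class VocabularyError(ValueError):
    """A structure label outside the fixed vocabulary was supplied."""


def _coord_channels(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    y = np.linspace(-1.0, 1.0, h, dtype=np.float32)[:, None] * np.ones((1, w), np.float32)
    x = np.linspace(-1.0, 1.0, w, dtype=np.float32)[None, :] * np.ones((h, 1), np.float32)
    return x, y


def _resize01(img: np.ndarray, shape) -> np.ndarray:
    return resize(img.astype(np.float32), shape, order=1, preserve_range=True,
                  anti_aliasing=True).astype(np.float32)


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class SegTrainConfig:
    epochs: int = 200
    learning_rate: float = 0.002   # default matches the published recipe
    seed: int = 0
    input_size: tuple[int, int] = (128, 128)
    batch_size: int = 4
    hidden: int = 12


@dataclass
class InferenceConfig:
    score_threshold: float = 0.5
    nms_iou: float = 0.5
    max_instances_per_label: int = 2
    min_area: int = 50


def _seg_features(img: np.ndarray, input_size) -> np.ndarray:
    small = _resize01(img, input_size)
    blur = ndi.gaussian_filter(small, 2.0)
    x, y = _coord_channels(*input_size)
    return np.stack([small - 0.5, blur - 0.5, x, y]).astype(np.float32)


def _build_seg_net(cfg: SegTrainConfig, rng) -> nn.Sequential:
    h = cfg.hidden
    return nn.Sequential([
        nn.Conv2D(4, h, 3, rng), nn.ReLU(),
        nn.AvgPool2(),
        nn.Conv2D(h, 2 * h, 3, rng), nn.ReLU(),
        nn.Conv2D(2 * h, 2 * h, 3, rng), nn.ReLU(),
        nn.Upsample2(),
        nn.Conv2D(2 * h, h, 3, rng), nn.ReLU(),
        nn.Conv2D(h, len(SEGMENT_LABELS) + 1, 1, rng),
    ])


class SegmenterModel:
    """Per-pixel classifier + connected-component instancing."""

    def __init__(self, config: SegTrainConfig | None = None, net=None):
        self.config = config or SegTrainConfig()
        rng = np.random.default_rng(self.config.seed)
        self.net = net or _build_seg_net(self.config, rng)
        self.labels = SEGMENT_LABELS
        self.history: dict = {}

    def fit(self, images, labelmaps):
        """Train on full-frame images and integer label maps.

        Exactly ``floor(n/2)`` of the training images are horizontally
        flip-augmented (image and label map together), mirroring the
        half-set flipping of the original training recipe.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        n = len(images)
        feats, labs = [], []
        order = rng.permutation(n)
        flipped = set(order[: n // 2].tolist())
        for i in range(n):
            img = images[i]
            lab = labelmaps[i]
            if i in flipped:
                img = np.fliplr(img)
                lab = np.fliplr(lab)
            feats.append(_seg_features(img, cfg.input_size))
            labs.append(resize(lab.astype(float), cfg.input_size, order=0,
                               preserve_range=True,
                               anti_aliasing=False).astype(np.int64))
        X = np.stack(feats)
        Y = np.stack(labs)
        # inverse-sqrt-frequency class weights so small structures
        # (talus, fibula) are not drowned out by background
        counts = np.bincount(Y.reshape(-1), minlength=len(SEGMENT_LABELS) + 1)
        weights = np.where(counts > 0, np.sqrt(counts.sum() / np.maximum(counts, 1)),
                           0.0)
        present = weights > 0
        weights[present] /= weights[present].mean()
        opt = nn.Adam(self.net.params, self.net.grads, lr=cfg.learning_rate)
        losses = []
        for _ in range(cfg.epochs):
            idx = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                b = idx[start:start + cfg.batch_size]
                logits = self.net.forward(X[b])
                loss, dl = nn.softmax_cross_entropy(logits, Y[b], weights)
                self.net.backward(dl)
                opt.step()
                epoch_loss += loss * len(b)
            losses.append(epoch_loss / n)
        self.history = {"loss_per_epoch": losses, "flipped_count": len(flipped)}
        return self

    def predict_probs(self, image: np.ndarray) -> np.ndarray:
        """Class probabilities upsampled to the input image frame."""
        feats = _seg_features(image, self.config.input_size)[None]
        logits = self.net.forward(feats)[0]
        z = logits - logits.max(axis=0, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=0, keepdims=True)
        h, w = image.shape
        return np.stack([_resize01(p, (h, w)) for p in probs])

    def save(self, path):
        meta = {"kind": "segmenter", "config": asdict(self.config),
                "labels": list(self.labels)}
        arrays = {f"w{i}": w for i, w in enumerate(self.net.get_weights())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path):
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg_d = meta["config"]
        cfg_d["input_size"] = tuple(cfg_d["input_size"])
        model = cls(SegTrainConfig(**cfg_d))
        model.net.set_weights([data[f"w{i}"] for i in range(len(model.net.params))])
        return model


# ---------------------------------------------------------------------------
# landmarks


@dataclass
class LandmarkTrainConfig:
    epochs: int = 100
    learning_rate: float = 0.001   # default matches the published recipe
    seed: int = 0
    internal_size: int = 128       # crops are 256x256; processed at this size
    sigma: float = 5.0             # Gaussian target s.d. in 256-crop pixels
    batch_size: int = 1
    hidden: int = 16
    rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    peak_threshold: float = 0.2


def augment_crop(pixels: np.ndarray, xy: np.ndarray, angle_deg: float,
                 scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotate/scale a crop about its center with landmarks co-transformed."""
    h, w = pixels.shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    t = math_affine(angle_deg, scale, c)
    inv = np.linalg.inv(t)
    out = warp(pixels, AffineTransform(matrix=inv), order=1, mode="edge",
               preserve_range=True).astype(np.float32)
    ones = np.ones((xy.shape[0], 1))
    new_xy = (np.hstack([xy, ones]) @ t.T)[:, :2]
    return out, new_xy


def math_affine(angle_deg: float, scale: float, center: np.ndarray) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]) * scale
    t = center - R @ center
    m = np.eye(3)
    m[:2, :2] = R
    m[:2, 2] = t
    return m


def _lm_features(crop256: np.ndarray, size: int) -> np.ndarray:
    small = _resize01(crop256, (size, size))
    b1 = ndi.gaussian_filter(small, 1.5)
    b2 = ndi.gaussian_filter(small, 6.0)
    x, y = _coord_channels(size, size)
    return np.stack([small - 0.5, b1 - 0.5, b2 - 0.5, x, y]).astype(np.float32)


def render_heatmaps(xy: np.ndarray, size: int, sigma: float) -> np.ndarray:
    """Gaussian target heatmaps (one channel per landmark) at ``size``."""
    L = xy.shape[0]
    g = np.arange(size, dtype=np.float32)
    out = np.zeros((L, size, size), dtype=np.float32)
    for i in range(L):
        x, y = xy[i]
        if not np.isfinite(x) or not np.isfinite(y):
            continue
        dx2 = (g - x) ** 2
        dy2 = (g - y) ** 2
        out[i] = np.exp(-(dy2[:, None] + dx2[None, :]) / (2 * sigma * sigma))
    return out


def _build_lm_net(n_out: int, cfg: LandmarkTrainConfig, rng) -> nn.Sequential:
    h = cfg.hidden
    return nn.Sequential([
        nn.Conv2D(5, h, 3, rng), nn.ReLU(),
        nn.AvgPool2(),
        nn.Conv2D(h, 2 * h, 3, rng), nn.ReLU(),
        nn.AvgPool2(),
        nn.Conv2D(2 * h, 2 * h, 3, rng), nn.ReLU(),
        nn.AvgPool2(),
        nn.Conv2D(2 * h, 2 * h, 3, rng), nn.ReLU(),
        nn.Conv2D(2 * h, 2 * h, 3, rng), nn.ReLU(),
        nn.Upsample2(),
        nn.Conv2D(2 * h, 2 * h, 3, rng), nn.ReLU(),
        nn.Upsample2(),
        nn.Conv2D(2 * h, h, 3, rng), nn.ReLU(),
        nn.Upsample2(),
        nn.Conv2D(h, h, 3, rng), nn.ReLU(),
        nn.Conv2D(h, h, 3, rng), nn.ReLU(),
        nn.Conv2D(h, n_out, 1, rng),
    ])


class LandmarkModel:
    """Heatmap-regression landmark placer for one region."""

    def __init__(self, region: str, config: LandmarkTrainConfig | None = None,
                 net=None):
        self.region = region
        self.schema = landmark_schema(region)
        self.config = config or LandmarkTrainConfig()
        rng = np.random.default_rng(self.config.seed)
        self.net = net or _build_lm_net(len(self.schema), self.config, rng)
        self.history: dict = {}

    def fit(self, crops, landmark_sets):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        n = len(crops)
        size = cfg.internal_size
        ratio = size / 256.0
        sigma_int = cfg.sigma * ratio
        opt = nn.Adam(self.net.params, self.net.grads, lr=cfg.learning_rate)
        losses = []
        for _ in range(cfg.epochs):
            idx = rng.permutation(n)
            feats, targets = [], []
            for i in idx:
                xy = landmark_sets[i].coords()
                angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
                scale = rng.uniform(*cfg.scale_range)
                pix, axy = augment_crop(np.asarray(crops[i], np.float32), xy,
                                        angle, scale)
                feats.append(_lm_features(pix, size))
                targets.append(render_heatmaps(axy * ratio, size, sigma_int))
            X = np.stack(feats)
            T = np.stack(targets)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                sl = slice(start, start + cfg.batch_size)
                pred = self.net.forward(X[sl])
                loss, dp = nn.spatial_softmax_ce(pred, T[sl])
                self.net.backward(dp)
                opt.step()
                epoch_loss += loss * (X[sl].shape[0])
            losses.append(epoch_loss / n)
        self.history = {"loss_per_epoch": losses}
        return self

    def heatmaps(self, crop256: np.ndarray) -> np.ndarray:
        """Calibrated per-channel localization maps.

        Each channel is the spatial softmax of its logits, rescaled so its
        peak equals the channel's mass concentration (the probability mass
        in the 3x3 window around the argmax).  A confidently localized
        landmark thus peaks near 1 and a diffuse channel peaks low, which
        is what the relative-peak missing rule in decoding expects.
        """
        feats = _lm_features(np.asarray(crop256, np.float32),
                             self.config.internal_size)[None]
        logits = self.net.forward(feats)[0]
        L, H, W = logits.shape
        flat = logits.reshape(L, -1)
        z = flat - flat.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = (e / e.sum(axis=1, keepdims=True)).reshape(L, H, W)
        out = np.empty_like(p)
        for i in range(L):
            iy, ix = np.unravel_index(int(p[i].argmax()), (H, W))
            win = p[i, max(0, iy - 1):iy + 2, max(0, ix - 1):ix + 2]
            conc = float(win.sum())
            peak = float(p[i].max())
            out[i] = p[i] * (conc / peak if peak > 0 else 0.0)
        return out

    def predict(self, crop256: np.ndarray,
                peak_threshold: float | None = None) -> LandmarkSet:
        hm = self.heatmaps(crop256)
        thr = self.config.peak_threshold if peak_threshold is None else peak_threshold
        ls = decode_heatmaps(hm, self.region, peak_threshold=thr)
        ratio = 256.0 / self.config.internal_size
        xy = ls.coords() * ratio
        confs = [p.confidence for p in ls.points]
        return make_landmark_set(self.region, xy, frame="crop", confidences=confs)

    def save(self, path):
        cfg = asdict(self.config)
        meta = {"kind": "landmarks", "region": self.region, "config": cfg,
                "names": [e.name for e in self.schema]}
        arrays = {f"w{i}": w for i, w in enumerate(self.net.get_weights())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path):
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg_d = meta["config"]
        cfg_d["scale_range"] = tuple(cfg_d["scale_range"])
        model = cls(meta["region"], LandmarkTrainConfig(**cfg_d))
        model.net.set_weights([data[f"w{i}"] for i in range(len(model.net.params))])
        return model


def load_checkpoint(path):
    """Load either kind of model from a single-file checkpoint."""
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    if meta["kind"] == "segmenter":
        return SegmenterModel.load(path)
    return LandmarkModel.load(path)
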