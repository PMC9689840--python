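"""Instance segmentation of bones and implant components.

Produces one labeled instance per structure (femur, tibia, fibula, talus
and the two TKA implant components) with a binary mask, tight bounding box
and a confidence score.  Two routes exist: a trained per-pixel classifier
(:func:`train_segmenter` / :func:`segment`) and a ground-truth oracle
(:func:`oracle_segment`) that lets every downstream stage be tested in
isolation from learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .models import (SEGMENT_LABELS, InferenceConfig, SegTrainConfig,
                     SegmenterModel, VocabularyError)

__all__ = ["SegmentationResult", "train_segmenter", "segment",
           "oracle_segment", "mask_iou", "build_labelmap",
           "SEGMENT_LABELS", "VocabularyError"]

# rasterization priority when structures overlap (implants are on top,
# being the brightest structures)
_LABEL_PRIORITY = ("femur", "tibia", "fibula", "talus",
                   "implant_femoral", "implant_tibial")


@dataclass
class SegmentationResult:
    """One detected structure instance in the image frame."""

    label: str
    mask: np.ndarray            # bool, image frame
    box: tuple[float, float, float, float]  # half-open (x0, y0, x1, y1)
    score: float
    polygon: object | None = None  # optional exact shapely geometry

    def __post_init__(self):
        if self.label not in SEGMENT_LABELS:
            raise VocabularyError(f"unknown structure label {self.label!r}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")

    @property
    def box_center_x(self) -> float:
        return 0.5 * (self.box[0] + self.box[2])


def tight_box(mask: np.ndarray) -> tuple[float, float, float, float]:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask has no bounding box")
    # half-open box convention: [x0, x1) x [y0, y1)
    return (float(xs.min()), float(ys.min()),
            float(xs.max() + 1), float(ys.max() + 1))


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def build_labelmap(masks: dict[str, np.ndarray], shape) -> np.ndarray:
    """Integer training target: 0 = background, 1.. = label vocabulary order."""
    lab = np.zeros(shape, dtype=np.int64)
    for name in _LABEL_PRIORITY:
        if name in masks:
            lab[np.asarray(masks[name], bool)] = SEGMENT_LABELS.index(name) + 1
    for name in masks:
        if name not in SEGMENT_LABELS:
            raise VocabularyError(f"unknown structure label {name!r}")
    return lab


def train_segmenter(images, masks, config: SegTrainConfig | None = None) -> SegmenterModel:
    """Train the instance segmenter on annotated images.

    ``images`` are normalized [0,1] arrays; ``masks`` is a parallel list of
    ``{label: binary mask}`` dicts.  Exactly ``floor(n/2)`` training images
    are horizontally flip-augmented so the model is insensitive to the leg
    side.  The returned model is serializable (``model.save``) and carries
    ``model.history['loss_per_epoch']``.
    """
    if len(images) < 2:
        raise ValueError("training needs at least 2 annotated images")
    labelmaps = [build_labelmap(m, im.shape) for im, m in zip(images, masks)]
    model = SegmenterModel(config or SegTrainConfig())
    model.fit(images, labelmaps)
    return model


def _instances_from_probs(probs: np.ndarray,
                          cfg: InferenceConfig) -> list[SegmentationResult]:
    classmap = probs.argmax(axis=0)
    results: list[SegmentationResult] = []
    for li, label in enumerate(SEGMENT_LABELS):
        cls = li + 1
        region = classmap == cls
        if not region.any():
            continue
        comp, ncomp = ndi.label(region)
        cand = []
        for c in range(1, ncomp + 1):
            m = comp == c
            if m.sum() < cfg.min_area:
                continue
            score = float(probs[cls][m].mean())
            if score < cfg.score_threshold:
                continue
            cand.append(SegmentationResult(label, m, tight_box(m), score))
        # per-label NMS by mask IoU, keep at most two instances (bilateral)
        cand.sort(key=lambda r: -r.score)
        kept: list[SegmentationResult] = []
        for r in cand:
            if len(kept) >= cfg.max_instances_per_label:
                break
            if all(mask_iou(r.mask, k.mask) < cfg.nms_iou for k in kept):
                kept.append(r)
        results.extend(kept)
    return results


def segment(radiograph, model: SegmenterModel,
            config: InferenceConfig | None = None) -> list[SegmentationResult]:
    """Detect and delineate structures on a normalized radiograph.

    An empty list is a valid outcome; it feeds detection-rate accounting
    downstream rather than raising.
    """
    cfg = config or InferenceConfig()
    pixels = radiograph.pixels if hasattr(radiograph, "pixels") else radiograph
    probs = model.predict_probs(np.asarray(pixels, dtype=np.float32))
    return _instances_from_probs(probs, cfg)


def oracle_segment(ground_truth) -> list[SegmentationResult]:
    """Perfect segmentation from phantom ground truth (score 1.0).

    Accepts a phantom :class:`~limbalign.phantom.GroundTruth` (all legs) or
    a single leg truth; each structure yields one result whose box is the
    tight box of its mask and which carries the exact polygon.
    """
    legs = getattr(ground_truth, "legs", None) or [ground_truth]
    results = []
    for leg in legs:
        for label, mask in leg.masks.items():
            poly = leg.shapes.get(label) if hasattr(leg, "shapes") else None
            results.append(SegmentationResult(
                label=label, mask=np.asarray(mask, bool),
                box=tight_box(mask), score=1.0, polygon=poly))
    return results
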