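"""Evaluation harnesses: oracle-path recovery and scaled-down learning runs.

These drive the same code paths as the measurement pipeline; they exist so
that the validation suite and the reproducibility script share one
implementation of "generate phantoms, run the method, score the result".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PARAMETERS, Unavailable, detection_rates
from .io import normalized
from .landmarks import oracle_landmarks
from .models import LandmarkTrainConfig, SegTrainConfig
from .phantom import generate_phantom, sample_specs
from .pipeline import PipelineConfig, measure_ground_truth, measure_image
from .roi import crop_region, prepare_model_input, split_legs
from .segmentation import mask_iou, oracle_segment, segment, train_segmenter
from .landmarks import train_landmark_model
from .training import phantom_crop_dataset, phantom_seg_dataset


def oracle_angle_errors(n: int = 100, seed: int = 0,
                        implant: str = "none") -> dict:
    """Oracle-path parameter recovery over ``n`` sampled phantoms.

    Returns the per-parameter maximum absolute deviation from the analytic
    ground truth (degrees) and the detection rates.
    """
    specs = sample_specs(n, seed=seed, implant=implant)
    errors = {p: [] for p in PARAMETERS}
    reports = []
    for spec in specs:
        _, gt = generate_phantom(spec)
        reps = measure_ground_truth(gt)
        assert len(reps) == 1
        rep = reps[0]
        reports.append(rep)
        for p in PARAMETERS:
            v = rep.angles[p]
            if not isinstance(v, Unavailable):
                errors[p].append(abs(v - gt.true_angles[p]))
    rates = detection_rates(reports)
    return {
        "max_error": {p: (max(e) if e else float("nan")) for p, e in errors.items()},
        "overall_max_error": max(max(e) for e in errors.values() if e),
        "rates": rates,
        "n": n,
    }


@dataclass
class TinyPipeline:
    """Scaled-down trained models for the learning smoke evaluation."""

    segmenter: object
    landmark_models: dict
    config: PipelineConfig = field(default_factory=PipelineConfig)


def train_tiny_pipeline(seed: int = 0, n_train_seg: int = 30,
                        n_train_crops: int = 40, seg_epochs: int = 20,
                        lm_epochs: int = 30,
                        regions=("proximal_femur", "knee_native", "talus")) -> TinyPipeline:
    """Train the segmenter and region landmark models on phantom data."""
    images, masks, _ = phantom_seg_dataset(n_train_seg, seed=seed)
    seg = train_segmenter(images, masks,
                          SegTrainConfig(epochs=seg_epochs, seed=seed))
    lm_models = {}
    for region in regions:
        crops, lsets = phantom_crop_dataset(region, n_train_crops,
                                            seed=seed + 1000)
        cfg = LandmarkTrainConfig(epochs=lm_epochs, seed=seed)
        lm_models[region] = train_landmark_model(region, crops, lsets, cfg)
    return TinyPipeline(segmenter=seg, landmark_models=lm_models)


def heldout_segmentation_iou(pipeline: TinyPipeline, n: int = 10,
                             seed: int = 12345) -> dict:
    """Mask IoU vs ground truth per bone over held-out phantoms."""
    specs = sample_specs(n, seed=seed)
    per_label: dict[str, list[float]] = {}
    for spec in specs:
        rad, gt = generate_phantom(spec)
        results = segment(rad, pipeline.segmenter)
        for label, true_mask in gt.masks.items():
            best = 0.0
            for r in results:
                if r.label == label:
                    best = max(best, mask_iou(r.mask, true_mask))
            per_label.setdefault(label, []).append(best)
    return {label: {"mean": float(np.mean(v)), "min": float(np.min(v))}
            for label, v in per_label.items()}


def heldout_landmark_error(pipeline: TinyPipeline, region: str = "talus",
                           n: int = 10, seed: int = 54321) -> dict:
    """Mean landmark error (px at the 256x256 crop) on held-out phantoms.

    Crops come from oracle segmentation so the score isolates the landmark
    stage.
    """
    specs = sample_specs(n, seed=seed,
                         implant="tka" if region == "knee_tka" else "none")
    model = pipeline.landmark_models[region]
    errs = []
    for spec in specs:
        rad, gt = generate_phantom(spec)
        image01 = normalized(rad)
        leg = split_legs(oracle_segment(gt))[0]
        crop = prepare_model_input(crop_region(region, leg, image01, gt.side))
        pred = model.predict(crop.pixels)
        truth = oracle_landmarks(gt.legs[0], region, crop.transform)
        pxy, txy = pred.coords(), truth.coords()
        ok = np.isfinite(pxy).all(axis=1)
        d = np.linalg.norm(pxy[ok] - txy[ok], axis=1)
        errs.extend(d.tolist())
        errs.extend([256.0] * int((~ok).sum()))  # a lost landmark scores badly
    return {"mean_error_px": float(np.mean(errs)), "n_landmarks": len(errs)}


def end_to_end_angle_rmse(pipeline: TinyPipeline, n: int = 30,
                          seed: int = 99) -> dict:
    """Fully trained-path angle RMSE vs ground truth on held-out phantoms."""
    specs = sample_specs(n, seed=seed)
    sq, found = {p: [] for p in PARAMETERS}, {p: 0 for p in PARAMETERS}
    reports = []
    for spec in specs:
        rad, gt = generate_phantom(spec)
        reps = measure_image(rad, pipeline.segmenter, pipeline.landmark_models,
                             pipeline.config)
        rep = reps[0]
        reports.append(rep)
        for p in PARAMETERS:
            v = rep.angles[p]
            if not isinstance(v, Unavailable):
                sq[p].append((v - gt.true_angles[p]) ** 2)
                found[p] += 1
    all_sq = [s for v in sq.values() for s in v]
    rates = detection_rates(reports)
    return {
        "rmse": {p: float(np.sqrt(np.mean(v))) if v else float("nan")
                 for p, v in sq.items()},
        "overall_rmse": float(np.sqrt(np.mean(all_sq))) if all_sq else float("nan"),
        "rates": rates,
        "n": n,
    }
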