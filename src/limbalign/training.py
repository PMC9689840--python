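"""Phantom-backed training datasets for the two trainable stages."""

from __future__ import annotations

import numpy as np

from .io import normalized
from .landmarks import LandmarkSet, oracle_landmarks
from .phantom import generate_phantom, sample_specs
from .roi import crop_region, prepare_model_input, split_legs
from .segmentation import oracle_segment


def phantom_seg_dataset(n: int, seed: int = 0, implant: str = "none"):
    """Normalized phantom images with per-structure mask dicts (+ truths)."""
    specs = sample_specs(n, seed=seed, implant=implant)
    images, masks, truths = [], [], []
    for spec in specs:
        rad, gt = generate_phantom(spec)
        images.append(normalized(rad).astype(np.float32))
        masks.append(gt.masks)
        truths.append(gt)
    return images, masks, truths


def phantom_crop_dataset(region: str, n: int, seed: int = 0):
    """Model-ready crops and crop-frame oracle landmark sets for a region.

    Crops are produced through the real ROI path (oracle segmentation ->
    leg group -> crop -> preparation), so training inputs match what the
    pipeline feeds the model at measurement time.
    """
    implant = "tka" if region == "knee_tka" else "none"
    specs = sample_specs(n, seed=seed, implant=implant)
    crops, lsets = [], []
    for spec in specs:
        rad, gt = generate_phantom(spec)
        image01 = normalized(rad)
        leg = split_legs(oracle_segment(gt))[0]
        crop = prepare_model_input(
            crop_region(region, leg, image01, side=gt.side))
        crops.append(crop.pixels)
        lsets.append(oracle_landmarks(gt.legs[0], region, crop.transform))
    return crops, lsets
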