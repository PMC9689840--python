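"""Per-leg grouping, leg-side rule and the four region crops.

The four landmark regions are cropped from segmentation bounding boxes:
the upper quarter of the femur box (proximal femur), the merged lower
eighth of the femur box and upper eighth of the tibia box (native knee),
the box around both implant components (TKA knee), and the talus box
directly.  Each crop is padded by 5% per side, clipped to the image,
contrast-equalized, flipped for left legs (landmark models are trained on
right-leg crops only) and resized to 256x256, with every step recorded in
an exactly invertible transform.

Leg side follows the fibula/tibia rule under standard radiographic
display (patient's right on the viewer's left, overridable): the fibula
is lateral, so a fibula box center left of the tibia's means a right leg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import exposure
from skimage.transform import resize

from .segmentation import SegmentationResult

__all__ = ["RegionCrop", "CropTransform", "LegGroup", "GroupingError",
           "SideError", "RegionUnavailable", "split_legs",
           "determine_leg_side", "crop_region", "prepare_model_input",
           "MODEL_INPUT_SIZE"]

MODEL_INPUT_SIZE = 256


class GroupingError(ValueError):
    """Structures cannot be partitioned into one or two legs."""


class SideError(ValueError):
    """The leg side cannot be determined."""


class RegionUnavailable(Exception):
    """A prerequisite structure for a region crop is missing.

    Consumed by detection-rate accounting, not a fatal error.
    """

    def __init__(self, region: str, reason: str):
        super().__init__(f"{region}: {reason}")
        self.region = region
        self.reason = reason


@dataclass(frozen=True)
class CropTransform:
    """Invertible crop-frame -> image-frame mapping.

    Composition (crop to image): undo the resize to 256x256 with per-axis
    scale factors, undo the horizontal flip (applied at the 256-wide crop
    frame), then add the crop offset:
    ``p_img = offset + S * flip(p_crop)``.
    """

    offset: tuple[float, float]            # (x0, y0) of the crop in the image
    scale: tuple[float, float]             # (crop_w/256, crop_h/256)
    flipped: bool = False
    out_size: int = MODEL_INPUT_SIZE

    def to_image(self, p) -> tuple[float, float]:
        x, y = float(p[0]), float(p[1])
        if self.flipped:
            x = (self.out_size - 1) - x
        return (self.offset[0] + self.scale[0] * x,
                self.offset[1] + self.scale[1] * y)

    def to_crop(self, p) -> tuple[float, float]:
        x = (float(p[0]) - self.offset[0]) / self.scale[0]
        y = (float(p[1]) - self.offset[1]) / self.scale[1]
        if self.flipped:
            x = (self.out_size - 1) - x
        return (x, y)


@dataclass
class RegionCrop:
    """A sub-image for one landmark region plus its invertible transform."""

    region: str
    pixels: np.ndarray
    transform: CropTransform
    side: str
    prepared: bool = False


@dataclass
class LegGroup:
    """At most one instance per structure label, for one leg."""

    results: dict[str, SegmentationResult]

    def __contains__(self, label):
        return label in self.results

    def get(self, label):
        return self.results.get(label)

    @property
    def has_implant(self) -> bool:
        return ("implant_femoral" in self.results
                and "implant_tibial" in self.results)

    def center_x(self) -> float:
        return float(np.mean([r.box_center_x for r in self.results.values()]))


def split_legs(results: list[SegmentationResult]) -> list[LegGroup]:
    """Partition instances into one or two legs by box x-centers.

    Two-means clustering on horizontal box centers, with a single-cluster
    fallback when the split does not separate (unilateral images).  A
    group containing two instances of the same label is a grouping error.
    """
    if not results:
        raise GroupingError("no segmentation results to group")
    xs = np.array([r.box_center_x for r in results])
    # duplicate labels force a two-leg reading; otherwise try one cluster
    labels = [r.label for r in results]
    has_dup = len(labels) != len(set(labels))
    spread = xs.max() - xs.min()
    widths = np.array([r.box[2] - r.box[0] for r in results])
    if not has_dup and spread < 1.5 * widths.mean():
        groups = [list(range(len(results)))]
    else:
        # 2-means on x-centers, initialized at the extremes
        c = np.array([xs.min(), xs.max()])
        for _ in range(20):
            assign = np.abs(xs[:, None] - c[None, :]).argmin(axis=1)
            for k in (0, 1):
                if (assign == k).any():
                    c[k] = xs[assign == k].mean()
        groups = [np.flatnonzero(assign == k).tolist() for k in (0, 1)]
        groups = [g for g in groups if g]
    legs = []
    for g in groups:
        d: dict[str, SegmentationResult] = {}
        for i in g:
            r = results[i]
            if r.label in d:
                raise GroupingError(
                    f"duplicate {r.label!r} instances in one leg group")
            d[r.label] = r
        legs.append(LegGroup(d))
    legs.sort(key=lambda g: g.center_x())
    return legs


def determine_leg_side(tibia_box, fibula_box, standard_display: bool = True) -> str:
    """Leg side from the relative position of fibula and tibia boxes."""
    tx = 0.5 * (tibia_box[0] + tibia_box[2])
    fx = 0.5 * (fibula_box[0] + fibula_box[2])
    if fx == tx:
        raise SideError("fibula and tibia x-centers coincide; side undetermined")
    fibula_left = fx < tx
    if standard_display:
        return "right" if fibula_left else "left"
    return "left" if fibula_left else "right"


_REGION_REQUIREMENTS = {
    "proximal_femur": ("femur",),
    "knee_native": ("femur", "tibia"),
    "knee_tka": ("implant_femoral", "implant_tibial"),
    "talus": ("talus",),
}


def _region_box(region: str, leg: LegGroup) -> tuple[float, float, float, float]:
    for label in _REGION_REQUIREMENTS[region]:
        if label not in leg:
            raise RegionUnavailable(region, f"missing structure: {label}")
    if region == "proximal_femur":
        x0, y0, x1, y1 = leg.get("femur").box
        return (x0, y0, x1, y0 + 0.25 * (y1 - y0))
    if region == "knee_native":
        fx0, fy0, fx1, fy1 = leg.get("femur").box
        tx0, ty0, tx1, ty1 = leg.get("tibia").box
        fem_eighth = (fx0, fy1 - (fy1 - fy0) / 8.0, fx1, fy1)
        tib_eighth = (tx0, ty0, tx1, ty0 + (ty1 - ty0) / 8.0)
        return (min(fem_eighth[0], tib_eighth[0]),
                min(fem_eighth[1], tib_eighth[1]),
                max(fem_eighth[2], tib_eighth[2]),
                max(fem_eighth[3], tib_eighth[3]))
    if region == "knee_tka":
        a = leg.get("implant_femoral").box
        b = leg.get("implant_tibial").box
        return (min(a[0], b[0]), min(a[1], b[1]),
                max(a[2], b[2]), max(a[3], b[3]))
    if region == "talus":
        return leg.get("talus").box
    raise ValueError(f"unknown region {region!r}")


def crop_region(region: str, leg: LegGroup, image: np.ndarray,
                side: str, padding: float = 0.05) -> RegionCrop:
    """Extract the (pre-resize) crop for a region from the full image."""
    x0, y0, x1, y1 = _region_box(region, leg)
    px = padding * (x1 - x0)
    py = padding * (y1 - y0)
    h, w = image.shape
    xi0 = int(np.floor(max(0.0, x0 - px)))
    yi0 = int(np.floor(max(0.0, y0 - py)))
    xi1 = int(np.ceil(min(float(w), x1 + px)))
    yi1 = int(np.ceil(min(float(h), y1 + py)))
    if xi1 <= xi0 or yi1 <= yi0:
        raise RegionUnavailable(region, "degenerate (zero-area) crop")
    sub = np.asarray(image[yi0:yi1, xi0:xi1], dtype=float)
    t = CropTransform(offset=(float(xi0), float(yi0)),
                      scale=((xi1 - xi0) / MODEL_INPUT_SIZE,
                             (yi1 - yi0) / MODEL_INPUT_SIZE),
                      flipped=False)
    return RegionCrop(region=region, pixels=sub, transform=t, side=side)


def prepare_model_input(crop: RegionCrop) -> RegionCrop:
    """Flip (left legs), equalize contrast and resize to 256x256.

    The flip flag and both scale factors are recorded in the transform so
    back-projection of detected landmarks is exact.
    """
    sub = crop.pixels
    if sub.size == 0:
        raise RegionUnavailable(crop.region, "degenerate (zero-area) crop")
    flip = crop.side == "left"
    if flip:
        sub = np.fliplr(sub)
    if sub.max() > sub.min():
        eq = exposure.equalize_hist(sub)
    else:
        eq = np.full_like(sub, 0.5, dtype=float)
    out = resize(eq, (MODEL_INPUT_SIZE, MODEL_INPUT_SIZE), order=1,
                 preserve_range=True, anti_aliasing=False)
    t = crop.transform
    new_t = CropTransform(offset=t.offset, scale=t.scale, flipped=flip)
    return RegionCrop(region=crop.region, pixels=out.astype(np.float32),
                      transform=new_t, side=crop.side, prepared=True)
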