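"""Named anatomical landmarks and heatmap-regression placement.

Four region models are used on 256x256 crops: proximal femur (9 landmarks),
native knee joint (20), total-knee-arthroplasty implant (15) and talus (2).
Each landmark carries a *role*; downstream goniometry consumes roles only
(e.g. the two distal-condyle tangent points define the femoral joint line),
so outline landmarks can move without touching angle code.  The exact
positions of outline landmarks are defined by the phantom generator, which
is the single source of truth for the schemas' geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

REGIONS = ("proximal_femur", "knee_native", "knee_tka", "talus")

ROLES = frozenset({
    "head_contour", "neck_waist", "greater_trochanter", "lesser_trochanter",
    "condyle_tangent_medial", "condyle_tangent_lateral", "condylar_notch",
    "plateau_edge_medial", "plateau_edge_lateral", "tibial_spine",
    "stem_axis", "talus_medial", "talus_lateral", "outline",
})


class SchemaError(ValueError):
    """Landmark set does not match its region schema."""


@dataclass(frozen=True)
class SchemaEntry:
    name: str
    role: str
    component: str | None = None  # femoral | tibial | None


@dataclass(frozen=True)
class Point:
    name: str
    role: str
    x: float
    y: float
    confidence: float = 1.0
    component: str | None = None

    @property
    def missing(self) -> bool:
        return math.isnan(self.x) or math.isnan(self.y)


@dataclass
class LandmarkSet:
    """Named, role-tagged 2-D points for one region, in crop or image frame."""

    region: str
    points: list[Point]
    frame: str = "image"  # crop | image

    def __post_init__(self):
        names = [p.name for p in self.points]
        if len(set(names)) != len(names):
            raise SchemaError("landmark names must be unique")
        schema = landmark_schema(self.region)
        if len(self.points) != len(schema):
            raise SchemaError(
                f"region {self.region!r} expects {len(schema)} landmarks, "
                f"got {len(self.points)}")
        for p in self.points:
            if p.role not in ROLES:
                raise SchemaError(f"unknown role {p.role!r}")
            if not (0.0 <= p.confidence <= 1.0):
                raise SchemaError("confidence must lie in [0, 1]")

    def get(self, name: str) -> Point:
        for p in self.points:
            if p.name == name:
                return p
        raise KeyError(name)

    def by_role(self, role: str) -> list[Point]:
        return [p for p in self.points if p.role == role]

    def coords(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    def with_coords(self, xy: np.ndarray, frame: str | None = None,
                    confidences=None) -> "LandmarkSet":
        pts = []
        for i, p in enumerate(self.points):
            conf = p.confidence if confidences is None else float(confidences[i])
            pts.append(Point(p.name, p.role, float(xy[i, 0]), float(xy[i, 1]),
                             conf, p.component))
        return LandmarkSet(self.region, pts, frame or self.frame)


def _schema_proximal_femur() -> list[SchemaEntry]:
    entries = [SchemaEntry(f"head_contour_{i}", "head_contour") for i in range(5)]
    entries += [
        SchemaEntry("neck_waist_sup", "neck_waist"),
        SchemaEntry("neck_waist_inf", "neck_waist"),
        SchemaEntry("greater_trochanter_tip", "greater_trochanter"),
        SchemaEntry("lesser_trochanter_tip", "lesser_trochanter"),
    ]
    return entries


def _schema_knee_native() -> list[SchemaEntry]:
    fem = [
        SchemaEntry("condyle_tangent_medial", "condyle_tangent_medial", "femoral"),
        SchemaEntry("condyle_tangent_lateral", "condyle_tangent_lateral", "femoral"),
        SchemaEntry("condylar_notch", "condylar_notch", "femoral"),
    ] + [SchemaEntry(f"condyle_outline_{i}", "outline", "femoral") for i in range(7)]
    tib = [
        SchemaEntry("plateau_edge_medial", "plateau_edge_medial", "tibial"),
        SchemaEntry("plateau_edge_lateral", "plateau_edge_lateral", "tibial"),
        SchemaEntry("tibial_spine_medial", "tibial_spine", "tibial"),
        SchemaEntry("tibial_spine_lateral", "tibial_spine", "tibial"),
    ] + [SchemaEntry(f"plateau_outline_{i}", "outline", "tibial") for i in range(6)]
    return fem + tib


def _schema_knee_tka() -> list[SchemaEntry]:
    fem = [
        SchemaEntry("implant_tangent_medial", "condyle_tangent_medial", "femoral"),
        SchemaEntry("implant_tangent_lateral", "condyle_tangent_lateral", "femoral"),
    ] + [SchemaEntry(f"implant_femoral_outline_{i}", "outline", "femoral")
         for i in range(3)]
    tib = [
        SchemaEntry("tray_edge_medial", "plateau_edge_medial", "tibial"),
        SchemaEntry("tray_edge_lateral", "plateau_edge_lateral", "tibial"),
        SchemaEntry("stem_axis_proximal", "stem_axis", "tibial"),
        SchemaEntry("stem_axis_distal", "stem_axis", "tibial"),
    ] + [SchemaEntry(f"implant_tibial_outline_{i}", "outline", "tibial")
         for i in range(6)]
    return fem + tib


def _schema_talus() -> list[SchemaEntry]:
    return [SchemaEntry("talus_dome_medial", "talus_medial"),
            SchemaEntry("talus_dome_lateral", "talus_lateral")]


_SCHEMAS = {
    "proximal_femur": _schema_proximal_femur(),
    "knee_native": _schema_knee_native(),
    "knee_tka": _schema_knee_tka(),
    "talus": _schema_talus(),
}


def landmark_schema(region: str) -> list[SchemaEntry]:
    """Ordered (name, role, component) schema for a region.

    Counts are fixed: 9 for the proximal femur, 20 for the native knee,
    15 for a TKA implant (5 femoral-component, 10 tibial-component) and 2
    for the talus.
    """
    try:
        return list(_SCHEMAS[region])
    except KeyError:
        raise SchemaError(f"unknown region {region!r}") from None


def make_landmark_set(region: str, xy: np.ndarray, frame: str = "image",
                      confidences=None) -> LandmarkSet:
    schema = landmark_schema(region)
    xy = np.asarray(xy, dtype=float)
    if xy.shape != (len(schema), 2):
        raise SchemaError(
            f"region {region!r} expects {len(schema)} points, got {xy.shape}")
    pts = []
    for i, e in enumerate(schema):
        conf = 1.0 if confidences is None else float(confidences[i])
        pts.append(Point(e.name, e.role, float(xy[i, 0]), float(xy[i, 1]),
                         conf, e.component))
    return LandmarkSet(region, pts, frame)


# ---------------------------------------------------------------------------
# heatmap decoding

def decode_heatmaps(heatmaps: np.ndarray, schema_or_region,
                    peak_threshold: float = 0.2) -> LandmarkSet:
    """Decode per-landmark heatmaps into subpixel coordinates.

    Each landmark is placed at its channel's argmax refined by the
    center of mass of the 3x3 neighborhood; confidence is the channel peak
    divided by the global maximum over all channels.  Channels whose peak
    falls below ``peak_threshold`` (as a fraction of the global maximum)
    are marked missing (NaN coordinates).  Coordinates are returned in the
    heatmap array frame.
    """
    if isinstance(schema_or_region, str):
        schema = landmark_schema(schema_or_region)
        region = schema_or_region
    else:
        schema = list(schema_or_region)
        region = None
    hm = np.asarray(heatmaps, dtype=float)
    if hm.ndim != 3 or hm.shape[0] != len(schema):
        raise SchemaError(
            f"expected {len(schema)} heatmap channels, got shape {hm.shape}")
    H, W = hm.shape[1:]
    global_max = float(hm.max())
    xs = np.full(len(schema), np.nan)
    ys = np.full(len(schema), np.nan)
    confs = np.zeros(len(schema))
    for i in range(len(schema)):
        ch = hm[i]
        peak = float(ch.max())
        conf = peak / global_max if global_max > 0 else 0.0
        confs[i] = max(0.0, min(1.0, conf))
        if global_max <= 0 or peak < peak_threshold * global_max:
            continue
        iy, ix = np.unravel_index(int(ch.argmax()), ch.shape)
        y0, y1 = max(0, iy - 1), min(H, iy + 2)
        x0, x1 = max(0, ix - 1), min(W, ix + 2)
        win = np.clip(ch[y0:y1, x0:x1], 0.0, None)
        tot = win.sum()
        if tot > 0:
            gy, gx = np.mgrid[y0:y1, x0:x1]
            ys[i] = float((win * gy).sum() / tot)
            xs[i] = float((win * gx).sum() / tot)
        else:
            ys[i], xs[i] = float(iy), float(ix)
    if region is None:
        # schema passed explicitly: build points directly
        pts = [Point(e.name, e.role, xs[i], ys[i], confs[i], e.component)
               for i, e in enumerate(schema)]
        # cannot validate counts against a named region here
        ls = LandmarkSet.__new__(LandmarkSet)
        ls.region = "custom"
        ls.points = pts
        ls.frame = "crop"
        return ls
    xy = np.column_stack([xs, ys])
    return make_landmark_set(region, xy, frame="crop", confidences=confs)


# ---------------------------------------------------------------------------
# oracle placement and model-based detection

def oracle_landmarks(ground_truth, region: str, transform) -> LandmarkSet:
    """Ground-truth landmarks mapped into the crop frame (confidence 1).

    ``ground_truth`` is anything exposing ``landmarks[region]`` as an
    image-frame :class:`LandmarkSet` (a phantom leg truth, in practice).
    """
    lms = ground_truth.landmarks[region]
    xy = lms.coords()
    crop_xy = np.array([transform.to_crop(p) for p in xy], dtype=float)
    return lms.with_coords(crop_xy, frame="crop")


def detect_landmarks(crop, model, peak_threshold: float | None = None) -> LandmarkSet:
    """Run a trained heatmap model on a prepared crop and decode the result."""
    if crop.region != model.region:
        raise SchemaError(
            f"crop region {crop.region!r} does not match model region "
            f"{model.region!r}")
    return model.predict(crop.pixels, peak_threshold=peak_threshold)


def train_landmark_model(region: str, crops: Sequence, landmark_sets: Sequence[LandmarkSet],
                         config=None):
    """Train the heatmap-regression model for one region.

    ``crops`` are model-ready 256x256 crops (arrays or RegionCrops);
    ``landmark_sets`` are matching crop-frame landmark sets.  Returns the
    trained model; ``model.history`` carries the per-epoch loss.
    """
    from .models import LandmarkModel, LandmarkTrainConfig

    if len(crops) == 0:
        raise ValueError("empty training set")
    for ls in landmark_sets:
        if ls.region != region:
            raise SchemaError(
                f"training landmark set region {ls.region!r} != {region!r}")
        landmark_schema(region)  # raises for unknown region
    config = config or LandmarkTrainConfig()
    model = LandmarkModel(region, config)
    arrays = [c.pixels if hasattr(c, "pixels") else np.asarray(c) for c in crops]
    model.fit(arrays, landmark_sets)
    return model


# ---------------------------------------------------------------------------
# landmark tables (CSV / JSON)


def landmarks_to_records(image_id: str, sets) -> list[dict]:
    """Flatten landmark sets into table rows.

    Columns: image_id, region, name, role, x, y, confidence, frame.
    """
    rows = []
    for region, ls in sets.items():
        for p in ls.points:
            rows.append({"image_id": image_id, "region": region,
                         "name": p.name, "role": p.role, "x": p.x, "y": p.y,
                         "confidence": p.confidence, "frame": ls.frame})
    return rows


def save_landmarks_csv(path, image_id: str, sets) -> None:
    import pandas as pd

    pd.DataFrame(landmarks_to_records(image_id, sets)).to_csv(path, index=False)


def load_landmarks_csv(path, image_id: str | None = None) -> dict[str, LandmarkSet]:
    """Read a landmark table back into per-region landmark sets.

    Rows are matched to each region's schema by landmark name; missing
    names become NaN points with zero confidence, so a partial table still
    yields a valid (partially unavailable) geometry input.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if image_id is not None:
        df = df[df["image_id"] == image_id]
    out: dict[str, LandmarkSet] = {}
    for region, grp in df.groupby("region"):
        schema = landmark_schema(region)
        by_name = {r["name"]: r for _, r in grp.iterrows()}
        xy = np.full((len(schema), 2), np.nan)
        conf = np.zeros(len(schema))
        for i, e in enumerate(schema):
            row = by_name.get(e.name)
            if row is not None:
                xy[i] = (row["x"], row["y"])
                conf[i] = row["confidence"]
        frames = grp["frame"].unique()
        out[region] = make_landmark_set(region, xy, frame=str(frames[0]),
                                        confidences=conf)
    return out
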