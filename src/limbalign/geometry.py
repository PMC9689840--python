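"""Axes, joint lines and the five lower-limb alignment angles.

All computations live in the image frame: origin at the top-left pixel,
x to the right, y downward, 0-based coordinates.  Under the standard
radiographic display convention (patient's right side on the viewer's
left) the medial direction of a right leg is +x and of a left leg is -x.

Angle conventions (fixed and mirror-stable):

* ``mFAmTA`` (hip-knee-ankle angle): ``180 - delta`` where ``delta`` is the
  signed varus(+)/valgus(-) rotation from the distally-oriented mechanical
  femur axis to the distally-oriented mechanical tibia axis.  Neutral
  alignment is 180 deg, varus < 180, valgus > 180.
* ``FSAmTA``: same formula with the anatomical femoral shaft axis (fitted
  from the femur segmentation mask) in place of the mechanical femur axis.
* ``mMPTA``: angle between the proximally-oriented tibial mechanical axis
  ray and the medially-oriented tibial plateau ray.
* ``mLDFA``: angle between the proximally-oriented femoral mechanical axis
  ray and the laterally-oriented femoral condylar joint-line ray.
* ``mLDTA``: angle between the proximally-oriented tibial mechanical axis
  ray and the laterally-oriented ankle (talar dome) ray.

A parameter whose prerequisite structures or landmarks are missing is
reported as unavailable with a machine-readable reason rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .landmarks import LandmarkSet, Point

PARAMETERS = ("mMPTA", "mLDFA", "mFAmTA", "mLDTA", "FSAmTA")

__all__ = [
    "PARAMETERS",
    "Line",
    "Unavailable",
    "AxisBundle",
    "AlignmentReport",
    "DegenerateFitError",
    "project_to_image",
    "fit_circle",
    "fit_shaft_axis",
    "build_axes",
    "signed_angle",
    "ray_angle",
    "compute_alignment",
    "detection_rates",
]


class DegenerateFitError(ValueError):
    """Raised when a geometric fit has no unique solution."""


@dataclass(frozen=True)
class Line:
    """An oriented line: a point it passes through and a unit direction."""

    point: np.ndarray
    direction: np.ndarray
    orientation_tag: str = ""

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = float(np.hypot(d[0], d[1]))
        if n == 0.0:
            raise ValueError("line direction must be non-zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / n)


@dataclass(frozen=True)
class Unavailable:
    """Marker for a parameter or intermediate that could not be computed."""

    reason: str

    def __bool__(self):  # truthiness means "is available"
        return False


@dataclass
class AxisBundle:
    """Named axes, joint lines and centers for one leg."""

    side: str
    hip_center: np.ndarray | Unavailable
    femoral_knee_center: np.ndarray | Unavailable
    tibial_knee_center: np.ndarray | Unavailable
    ankle_center: np.ndarray | Unavailable
    femur_mech: Line | Unavailable
    tibia_mech: Line | Unavailable
    femur_shaft: Line | Unavailable
    femoral_joint_line: Line | Unavailable
    plateau_line: Line | Unavailable
    ankle_line: Line | Unavailable


@dataclass
class AlignmentReport:
    """Five alignment angles for one leg plus the evidence behind them."""

    side: str
    angles: dict[str, float | Unavailable]
    intermediate: AxisBundle | None = None
    source_id: str = ""

    def available(self) -> dict[str, float]:
        return {k: v for k, v in self.angles.items() if not isinstance(v, Unavailable)}


# ---------------------------------------------------------------------------
# frame projection

def project_to_image(landmarks: LandmarkSet, transform) -> LandmarkSet:
    """Map a crop-frame landmark set back to the image frame.

    ``transform`` is the crop's invertible :class:`~limbalign.roi.CropTransform`.
    Confidences are preserved.
    """
    if landmarks.frame != "crop":
        raise ValueError(f"expected crop-frame landmarks, got {landmarks.frame!r}")
    pts = []
    for p in landmarks.points:
        if math.isnan(p.x) or math.isnan(p.y):
            pts.append(p)
            continue
        x, y = transform.to_image((p.x, p.y))
        pts.append(Point(p.name, p.role, float(x), float(y), p.confidence, p.component))
    return LandmarkSet(region=landmarks.region, points=pts, frame="image")


# ---------------------------------------------------------------------------
# fits

def fit_circle(points: Sequence[Sequence[float]]) -> tuple[np.ndarray, float]:
    """Algebraic least-squares circle (Kasa formulation).

    Exact for points lying exactly on a circle; raises
    :class:`DegenerateFitError` for fewer than three or collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise DegenerateFitError("circle fit needs at least 3 two-dimensional points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise DegenerateFitError("circle fit is degenerate (collinear points)")
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0:
        raise DegenerateFitError("circle fit produced a non-positive radius")
    return np.array([cx, cy]), float(np.sqrt(r2))


def _polygon_row_chords(shape, y_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from shapely.geometry import LineString

    minx, _, maxx, _ = shape.bounds
    xs, ys = [], []
    for y in y_values:
        seg = LineString([(minx - 1.0, float(y)), (maxx + 1.0, float(y))])
        inter = seg.intersection(shape)
        if inter.is_empty:
            continue
        x0, _, x1, _ = inter.bounds
        xs.append(0.5 * (x0 + x1))
        ys.append(float(y))
    return np.asarray(xs), np.asarray(ys)


def fit_shaft_axis(mask, span: tuple[float, float] = (0.40, 0.70)) -> Line:
    """Anatomical shaft axis from a femur mask by a row-centroid fit.

    ``mask`` is either a binary array in the image frame or an exact polygon
    (a shapely geometry, as predicted masks are polygonal).  Rows within the
    ``span`` fraction of the structure's vertical extent contribute one
    centroid each; a least-squares line through them, oriented proximal to
    distal (+y), is returned.
    """
    import shapely.geometry

    if isinstance(mask, shapely.geometry.base.BaseGeometry):
        _, y0, _, y1 = mask.bounds
        lo = y0 + span[0] * (y1 - y0)
        hi = y0 + span[1] * (y1 - y0)
        rows = np.arange(math.ceil(lo), math.floor(hi) + 1, dtype=float)
        if rows.size < 50:
            raise DegenerateFitError(
                f"shaft fit needs >= 50 rows in span, got {rows.size}")
        xs, ys = _polygon_row_chords(mask, rows)
    else:
        m = np.asarray(mask, dtype=bool)
        row_any = m.any(axis=1)
        idx = np.flatnonzero(row_any)
        if idx.size == 0:
            raise DegenerateFitError("empty mask")
        y0, y1 = idx[0], idx[-1]
        lo = int(round(y0 + span[0] * (y1 - y0)))
        hi = int(round(y0 + span[1] * (y1 - y0)))
        rows = np.arange(lo, hi + 1)
        rows = rows[row_any[rows]]
        if rows.size < 50:
            raise DegenerateFitError(
                f"shaft fit needs >= 50 rows in span, got {rows.size}")
        cols = np.arange(m.shape[1], dtype=float)
        sub = m[rows].astype(float)
        xs = (sub * cols).sum(axis=1) / sub.sum(axis=1)
        ys = rows.astype(float)
    if xs.size < 2:
        raise DegenerateFitError("too few usable rows for shaft fit")
    # near-vertical structure: regress x on y
    coef = np.polyfit(ys, xs, 1)
    slope = coef[0]
    direction = np.array([slope, 1.0])
    point = np.array([np.polyval(coef, ys.mean()), ys.mean()])
    return Line(point=point, direction=direction, orientation_tag="proximal->distal")


# ---------------------------------------------------------------------------
# angles

def _medial_x_sign(side: str, standard_display: bool = True) -> float:
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    s = 1.0 if side == "right" else -1.0
    return s if standard_display else -s


def signed_angle(a: Line, b: Line, side: str) -> float:
    """Signed rotation from ``a`` to ``b`` in degrees, varus positive.

    Both lines are taken with their stored (distal) orientation.  The sign
    is flipped with the leg side so that a rotation of the distal direction
    toward the medial side is positive on either leg; perpendicular
    directions give 90, anti-parallel give 180.
    """
    da, db = a.direction, b.direction
    cross = da[0] * db[1] - da[1] * db[0]
    dot = float(np.dot(da, db))
    mu = _medial_x_sign(side)
    ang = math.degrees(math.atan2(-mu * cross, dot))
    if ang == -180.0:
        ang = 180.0
    return ang


def ray_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two rays, in [0, 180] degrees."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = float(np.dot(u, v) / (np.hypot(*u) * np.hypot(*v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


# ---------------------------------------------------------------------------
# axis construction

def _collect(landmarks: LandmarkSet | None, role: str,
             min_confidence: float) -> list[Point]:
    if landmarks is None:
        return []
    out = []
    for p in landmarks.points:
        if p.role != role:
            continue
        if math.isnan(p.x) or math.isnan(p.y) or p.confidence < min_confidence:
            continue
        out.append(p)
    return out


def _midpoint(points: list[Point]) -> np.ndarray:
    arr = np.array([[p.x, p.y] for p in points], float)
    return arr.mean(axis=0)


def build_axes(
    landmark_sets: Mapping[str, LandmarkSet],
    side: str,
    femur_mask=None,
    min_confidence: float = 0.0,
) -> AxisBundle:
    """Construct mechanical axes, shaft axis and joint lines for one leg.

    ``landmark_sets`` maps region name to an image-frame landmark set; any
    region may be absent.  ``femur_mask`` (binary array or polygon) feeds the
    anatomical shaft-axis fit.  Landmarks below ``min_confidence`` are
    ignored, which is what propagates detection failures into per-parameter
    availability.
    """
    prox = landmark_sets.get("proximal_femur")
    knee = landmark_sets.get("knee_tka") or landmark_sets.get("knee_native")
    talus = landmark_sets.get("talus")

    def unavailable(msg):
        return Unavailable(msg)

    # hip center from the femoral head contour
    head_pts = _collect(prox, "head_contour", min_confidence)
    if len(head_pts) >= 3:
        try:
            hip, _ = fit_circle([[p.x, p.y] for p in head_pts])
        except DegenerateFitError:
            hip = unavailable("degenerate femoral head circle fit")
    else:
        hip = unavailable("missing landmark: head_contour (proximal femur)")

    # knee centers
    notch = _collect(knee, "condylar_notch", min_confidence)
    tan_med = _collect(knee, "condyle_tangent_medial", min_confidence)
    tan_lat = _collect(knee, "condyle_tangent_lateral", min_confidence)
    if notch:
        fem_knee = np.array([notch[0].x, notch[0].y])
    elif tan_med and tan_lat:
        fem_knee = _midpoint([tan_med[0], tan_lat[0]])
    else:
        fem_knee = unavailable("missing landmark: femoral knee center")

    spines = _collect(knee, "tibial_spine", min_confidence)
    plat_med = _collect(knee, "plateau_edge_medial", min_confidence)
    plat_lat = _collect(knee, "plateau_edge_lateral", min_confidence)
    if len(spines) >= 2:
        tib_knee = _midpoint(spines[:2])
    elif plat_med and plat_lat:
        tib_knee = _midpoint([plat_med[0], plat_lat[0]])
    else:
        tib_knee = unavailable("missing landmark: tibial knee center")

    tal_med = _collect(talus, "talus_medial", min_confidence)
    tal_lat = _collect(talus, "talus_lateral", min_confidence)
    if tal_med and tal_lat:
        ankle = _midpoint([tal_med[0], tal_lat[0]])
    else:
        ankle = unavailable("missing structure: talus")

    def axis(p_from, p_to, tag):
        if isinstance(p_from, Unavailable):
            return p_from
        if isinstance(p_to, Unavailable):
            return p_to
        d = np.asarray(p_to, float) - np.asarray(p_from, float)
        if np.hypot(*d) == 0:
            return Unavailable("coincident axis endpoints")
        return Line(point=np.asarray(p_from, float), direction=d, orientation_tag=tag)

    femur_mech = axis(hip, fem_knee, "proximal->distal")
    tibia_mech = axis(tib_knee, ankle, "proximal->distal")

    if femur_mask is not None:
        try:
            femur_shaft = fit_shaft_axis(femur_mask)
        except DegenerateFitError as e:
            femur_shaft = Unavailable(f"shaft fit failed: {e}")
    else:
        femur_shaft = Unavailable("missing structure: femur mask")

    def joint_line(p_med, p_lat, tag):
        if not p_med or not p_lat:
            return Unavailable(f"missing landmark: {tag}")
        d = np.array([p_lat[0].x - p_med[0].x, p_lat[0].y - p_med[0].y])
        if np.hypot(*d) == 0:
            return Unavailable(f"degenerate joint line: {tag}")
        return Line(point=np.array([p_med[0].x, p_med[0].y]), direction=d,
                    orientation_tag="medial->lateral")

    femoral_joint = joint_line(tan_med, tan_lat, "femoral condylar joint line")
    plateau = joint_line(plat_med, plat_lat, "tibial plateau line")
    ankle_line = joint_line(tal_med, tal_lat, "ankle line")

    return AxisBundle(
        side=side,
        hip_center=hip,
        femoral_knee_center=fem_knee,
        tibial_knee_center=tib_knee,
        ankle_center=ankle,
        femur_mech=femur_mech,
        tibia_mech=tibia_mech,
        femur_shaft=femur_shaft,
        femoral_joint_line=femoral_joint,
        plateau_line=plateau,
        ankle_line=ankle_line,
    )


def compute_alignment(bundle: AxisBundle, side: str | None = None) -> AlignmentReport:
    """Compute the five alignment parameters from an axis bundle.

    Unavailability is data: each missing parameter carries the reason of the
    first missing prerequisite instead of raising.
    """
    side = side or bundle.side
    angles: dict[str, float | Unavailable] = {}

    def first_reason(*parts):
        for p in parts:
            if isinstance(p, Unavailable):
                return p
        return None

    # mFAmTA
    miss = first_reason(bundle.femur_mech, bundle.tibia_mech)
    if miss is None:
        delta = signed_angle(bundle.femur_mech, bundle.tibia_mech, side)
        angles["mFAmTA"] = 180.0 - delta
    else:
        angles["mFAmTA"] = miss

    # FSAmTA (shaft axis from the segmentation mask)
    miss = first_reason(bundle.femur_shaft, bundle.tibia_mech)
    if miss is None:
        delta = signed_angle(bundle.femur_shaft, bundle.tibia_mech, side)
        angles["FSAmTA"] = 180.0 - delta
    else:
        angles["FSAmTA"] = miss

    # mMPTA: proximal tibial ray vs medial plateau ray
    miss = first_reason(bundle.tibia_mech, bundle.plateau_line)
    if miss is None:
        medial_ray = -bundle.plateau_line.direction  # stored medial->lateral
        angles["mMPTA"] = ray_angle(-bundle.tibia_mech.direction, medial_ray)
    else:
        angles["mMPTA"] = miss

    # mLDFA: proximal femoral ray vs lateral condylar joint-line ray
    miss = first_reason(bundle.femur_mech, bundle.femoral_joint_line)
    if miss is None:
        angles["mLDFA"] = ray_angle(-bundle.femur_mech.direction,
                                    bundle.femoral_joint_line.direction)
    else:
        angles["mLDFA"] = miss

    # mLDTA: proximal tibial ray vs lateral ankle-line ray
    miss = first_reason(bundle.tibia_mech, bundle.ankle_line)
    if miss is None:
        angles["mLDTA"] = ray_angle(-bundle.tibia_mech.direction,
                                    bundle.ankle_line.direction)
    else:
        angles["mLDTA"] = miss

    return AlignmentReport(side=side, angles=angles, intermediate=bundle)


def detection_rates(reports: Sequence[AlignmentReport]) -> dict[str, dict[str, float]]:
    """Per-parameter availability over a batch of reports.

    Returns ``{parameter: {"available": k, "total": n, "fraction": k/n,
    "percent": 100k/n}}``.
    """
    if len(reports) == 0:
        raise ValueError("detection rates need at least one report")
    out = {}
    n = len(reports)
    for param in PARAMETERS:
        k = sum(1 for r in reports
                if not isinstance(r.angles.get(param, Unavailable("absent")), Unavailable))
        out[param] = {"available": float(k), "total": float(n),
                      "fraction": k / n, "percent": 100.0 * k / n}
    return out
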