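"""Synthetic full-leg radiograph phantoms with analytic ground truth.

Each phantom is a geometric stick-figure leg built from capsule and
polygon primitives (femoral head disc, neck and shaft capsules, condylar
and plateau trapezoids, a thin fibular capsule, a talar dome and an
optional two-component knee implant), rendered bright-on-dark, blurred
and noised.  The construction is parametrized directly by the five
alignment angles' generating values, so the ground truth — landmark
coordinates, per-structure masks/polygons and the five angles — is exact
and in closed form:

* ``mFAmTA  = 180 - knee_varus_valgus``           (varus positive)
* ``FSAmTA  = 180 - knee_varus_valgus - anat_mech_femur_angle``
* ``mMPTA   =  90 - plateau_obliquity``
* ``mLDFA   =  90 + femoral_jointline_obliquity``
* ``mLDTA   =  90 + ankle_obliquity``

The phantom emulates standard radiographic display: the patient's right
leg appears on the viewer's left, and the fibula is lateral to the tibia.
Landmark schemas are exactly those of :mod:`limbalign.landmarks`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .io import Radiograph
from .landmarks import LandmarkSet, make_landmark_set

__all__ = ["PhantomSpec", "LegTruth", "GroundTruth", "GeometryError",
           "generate_phantom", "ground_truth_angles", "sample_specs",
           "DEFAULT_RANGES"]

MECH_TILT_DEG = 3.0  # fixed medial tilt of the femoral mechanical axis
_JOINT_GAP = 14.0    # px between femoral joint line and tibial plateau


class GeometryError(ValueError):
    """The requested leg does not fit the frame or the spec is invalid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generating parameters of one synthetic full-leg radiograph."""

    side: str = "right"
    image_size: tuple[int, int] = (768, 384)   # (H, W)
    hip_center: tuple[float, float] | None = None
    femur_length: float = 290.0
    tibia_length: float = 270.0
    neck_shaft_offset: tuple[float, float] = (0.0, 0.0)
    anat_mech_femur_angle: float = 6.0
    knee_varus_valgus: float = 0.0             # varus positive, degrees
    femoral_jointline_obliquity: float = 0.0
    plateau_obliquity: float = 0.0
    ankle_obliquity: float = 0.0
    implant: str = "none"                      # none | tka
    bilateral: bool = False
    noise_sd: float = 0.02
    blur_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise GeometryError(f"side must be left or right, got {self.side!r}")
        if self.femur_length <= 0 or self.tibia_length <= 0:
            raise GeometryError("bone lengths must be positive")
        for name in ("femoral_jointline_obliquity", "plateau_obliquity",
                     "ankle_obliquity"):
            if abs(getattr(self, name)) > 15.0:
                raise GeometryError(f"{name} must lie within +-15 degrees")
        if self.implant not in ("none", "tka"):
            raise GeometryError(f"implant must be 'none' or 'tka', got {self.implant!r}")

    def resolved_hip(self, mirrored: bool = False) -> np.ndarray:
        h, w = self.image_size
        if self.hip_center is not None:
            hx, hy = self.hip_center
        else:
            frame_w = w / 2.0 if self.bilateral else float(w)
            hx = 0.47 * frame_w
            hy = 0.125 * h
            if self.side == "left" and not self.bilateral:
                hx = (w - 1) - hx
        if mirrored:
            hx = (w - 1) - hx
        return np.array([float(hx), float(hy)])


@dataclass
class LegTruth:
    """Exact ground truth for one rendered leg."""

    side: str
    landmarks: dict[str, LandmarkSet]
    masks: dict[str, np.ndarray]
    shapes: dict[str, object]            # exact shapely geometries
    true_angles: dict[str, float]


@dataclass
class GroundTruth:
    """Ground truth for a phantom frame (one or two legs)."""

    legs: list[LegTruth]
    image_size: tuple[int, int]

    # single-leg conveniences
    @property
    def side(self) -> str:
        return self.legs[0].side

    @property
    def landmarks(self):
        return self.legs[0].landmarks

    @property
    def masks(self):
        return self.legs[0].masks

    @property
    def shapes(self):
        return self.legs[0].shapes

    @property
    def true_angles(self):
        return self.legs[0].true_angles


def ground_truth_angles(spec: PhantomSpec) -> dict[str, float]:
    """Closed-form generating values of the five alignment parameters."""
    vv = spec.knee_varus_valgus
    return {
        "mFAmTA": 180.0 - vv,
        "FSAmTA": 180.0 - vv - spec.anat_mech_femur_angle,
        "mMPTA": 90.0 - spec.plateau_obliquity,
        "mLDFA": 90.0 + spec.femoral_jointline_obliquity,
        "mLDTA": 90.0 + spec.ankle_obliquity,
    }


# ---------------------------------------------------------------------------
# geometric construction


def _rot_varus(v: np.ndarray, deg: float, mu: float) -> np.ndarray:
    """Rotate a distally-pointing direction toward the medial side by deg."""
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] + mu * s * v[1], -mu * s * v[0] + c * v[1]])


def _perp_medial(d: np.ndarray, mu: float) -> np.ndarray:
    p = np.array([d[1], -d[0]])
    if p[0] * mu < 0:
        p = -p
    return p


def _build_leg(spec: PhantomSpec, side: str, hip: np.ndarray) -> LegTruth:
    from shapely.geometry import LineString, Point as SPoint, Polygon
    from shapely.ops import unary_union

    mu = 1.0 if side == "right" else -1.0
    vv = spec.knee_varus_valgus
    Lf, Lt = spec.femur_length, spec.tibia_length

    vertical = np.array([0.0, 1.0])
    d_f = _rot_varus(vertical, MECH_TILT_DEG, mu)
    d_t = _rot_varus(d_f, vv, mu)
    d_shaft = _rot_varus(d_f, -spec.anat_mech_femur_angle, mu)

    H = np.asarray(hip, float)
    K_f = H + Lf * d_f
    K_t = K_f + _JOINT_GAP * d_t
    A = K_t + Lt * d_t

    n_lat_f = -_perp_medial(d_f, mu)
    n_med_t = _perp_medial(d_t, mu)
    n_lat_t = -n_med_t

    def ray(base_perp, along, deg):
        a = math.radians(deg)
        return math.cos(a) * base_perp + math.sin(a) * along

    l_hat = ray(n_lat_f, d_f, spec.femoral_jointline_obliquity)   # lateral condylar ray
    m_hat = ray(n_med_t, -d_t, spec.plateau_obliquity)            # medial plateau ray
    a_hat = ray(n_lat_t, d_t, spec.ankle_obliquity)               # lateral ankle ray

    # ---- primitive sizes (px), proportioned to default bone lengths
    r_head = 0.072 * Lf
    shaft_hw = 0.052 * Lf
    neck_hw = 0.031 * Lf
    w_f = 46.0          # half-separation of the condylar tangent landmarks
    hc = 36.0           # condyle trapezoid height
    w_t = 44.0          # plateau landmark half-separation
    ht = 34.0           # plateau trapezoid height
    tib_hw = 0.048 * Lt
    fib_hw = 6.5
    fib_off = 33.0
    w_a = 36.0          # talus landmark half-separation
    dome_h = 26.0

    T = K_f - 0.90 * Lf * d_shaft + np.asarray(spec.neck_shaft_offset, float)

    shapes: dict[str, object] = {}
    head = SPoint(H).buffer(r_head, quad_segs=24)
    neck = LineString([H, T]).buffer(neck_hw, quad_segs=12)
    shaft = LineString([K_f - 0.93 * Lf * d_shaft,
                        K_f - 0.5 * hc * d_shaft]).buffer(shaft_hw, quad_segs=12)
    condyles = Polygon([K_f + (w_f + 6) * l_hat,
                        K_f - (w_f + 6) * l_hat,
                        K_f - hc * d_f - 0.6 * w_f * l_hat,
                        K_f - hc * d_f + 0.6 * w_f * l_hat])
    shapes["femur"] = unary_union([head, neck, shaft, condyles])

    plateau = Polygon([K_t + (w_t + 6) * m_hat,
                       K_t - (w_t + 6) * m_hat,
                       K_t + ht * d_t - 0.55 * w_t * m_hat,
                       K_t + ht * d_t + 0.55 * w_t * m_hat])
    tib_shaft = LineString([K_t + 0.5 * ht * d_t,
                            A - 20.0 * d_t]).buffer(tib_hw, quad_segs=12)
    shapes["tibia"] = unary_union([plateau, tib_shaft])

    fib0 = K_t + 30.0 * d_t + fib_off * n_lat_t
    fib1 = A - 18.0 * d_t + fib_off * n_lat_t
    shapes["fibula"] = LineString([fib0, fib1]).buffer(fib_hw, quad_segs=12)

    shapes["talus"] = Polygon([A + (w_a + 5) * a_hat,
                               A - (w_a + 5) * a_hat,
                               A - (w_a - 8) * a_hat + dome_h * d_t,
                               A + (w_a - 8) * a_hat + dome_h * d_t])

    # ---- landmarks
    lms: dict[str, LandmarkSet] = {}

    # mirror-consistent construction: x-components scale with the medial sign
    head_angles = np.deg2rad([-150.0, -90.0, -30.0, 30.0, 150.0])
    head_pts = [H + r_head * np.array([mu * math.cos(t), math.sin(t)])
                for t in head_angles]
    neck_dir = T - H
    nn = np.hypot(*neck_dir)
    neck_dir = neck_dir / nn if nn > 0 else np.array([mu * -1.0, 0.1])
    neck_perp = mu * np.array([neck_dir[1], -neck_dir[0]])
    mid_neck = 0.5 * (H + T)
    lt_tip = K_f - 0.84 * Lf * d_shaft + (shaft_hw - 2.0) * _perp_medial(d_shaft, mu)
    prox_xy = np.array(head_pts + [
        mid_neck + (neck_hw - 1.5) * neck_perp,
        mid_neck - (neck_hw - 1.5) * neck_perp,
        T,
        lt_tip,
    ])
    lms["proximal_femur"] = make_landmark_set("proximal_femur", prox_xy)

    if spec.implant == "none":
        cond_top = K_f - hc * d_f
        fem_outline = [
            K_f + (w_f + 6) * l_hat, K_f - (w_f + 6) * l_hat,
            cond_top + 0.6 * w_f * l_hat, cond_top - 0.6 * w_f * l_hat,
            K_f - 0.5 * hc * d_f + 0.7 * w_f * l_hat,
            K_f - 0.5 * hc * d_f - 0.7 * w_f * l_hat,
            K_f - 0.5 * hc * d_f,
        ]
        plat_bot = K_t + ht * d_t
        tib_outline = [
            K_t + (w_t + 6) * m_hat, K_t - (w_t + 6) * m_hat,
            plat_bot + 0.55 * w_t * m_hat, plat_bot - 0.55 * w_t * m_hat,
            K_t + 0.5 * ht * d_t + 0.6 * w_t * m_hat,
            K_t + 0.5 * ht * d_t - 0.6 * w_t * m_hat,
        ]
        knee_xy = np.array(
            [K_f - w_f * l_hat,                 # medial tangent (l_hat is lateral)
             K_f + w_f * l_hat,                 # lateral tangent
             K_f] + fem_outline +
            [K_t + w_t * m_hat,                 # medial plateau edge
             K_t - w_t * m_hat,                 # lateral plateau edge
             K_t + 8.0 * m_hat,                 # medial tibial spine
             K_t - 8.0 * m_hat] + tib_outline)
        lms["knee_native"] = make_landmark_set("knee_native", knee_xy)
    else:
        fem_top = K_f - 18.0 * d_f
        imp_fem = Polygon([K_f + (w_f + 8) * l_hat,
                           K_f - (w_f + 8) * l_hat,
                           fem_top - (w_f + 2) * l_hat,
                           fem_top + (w_f + 2) * l_hat])
        shapes["implant_femoral"] = imp_fem
        tray_bot = K_t + 12.0 * d_t
        tray = Polygon([K_t + (w_t + 8) * m_hat,
                        K_t - (w_t + 8) * m_hat,
                        tray_bot - (w_t + 2) * m_hat,
                        tray_bot + (w_t + 2) * m_hat])
        stem = LineString([K_t + 12.0 * d_t,
                           K_t + 80.0 * d_t]).buffer(7.0, quad_segs=12)
        shapes["implant_tibial"] = unary_union([tray, stem])
        tka_xy = np.array([
            K_f - w_f * l_hat,                  # medial tangent
            K_f + w_f * l_hat,                  # lateral tangent
            fem_top + (w_f + 2) * 0.8 * l_hat,  # outline x3
            fem_top - (w_f + 2) * 0.8 * l_hat,
            K_f - 9.0 * d_f,
            K_t + w_t * m_hat,                  # medial tray edge
            K_t - w_t * m_hat,                  # lateral tray edge
            K_t + 25.0 * d_t,                   # stem axis proximal
            K_t + 60.0 * d_t,                   # stem axis distal
            tray_bot + (w_t + 2) * 0.8 * m_hat,  # outline x6
            tray_bot - (w_t + 2) * 0.8 * m_hat,
            K_t + 6.0 * d_t,
            K_t + 40.0 * d_t + 3.0 * m_hat,
            K_t + 40.0 * d_t - 3.0 * m_hat,
            K_t + 76.0 * d_t,
        ])
        lms["knee_tka"] = make_landmark_set("knee_tka", tka_xy)

    # the medial dome corner is opposite the lateral ankle ray
    talus_xy = np.array([A - w_a * a_hat, A + w_a * a_hat])
    lms["talus"] = make_landmark_set("talus", talus_xy)

    masks = {name: rasterize(shape, spec.image_size)
             for name, shape in shapes.items()}
    for name, m in masks.items():
        if not m.any():
            raise GeometryError(f"structure {name} rasterized to an empty mask")

    return LegTruth(side=side, landmarks=lms, masks=masks, shapes=shapes,
                    true_angles=ground_truth_angles(spec))


def rasterize(shape, image_size) -> np.ndarray:
    """Binary pixel mask of a shapely geometry (pixel-center convention)."""
    from skimage.draw import polygon as draw_polygon

    h, w = image_size
    out = np.zeros((h, w), dtype=bool)
    geoms = getattr(shape, "geoms", [shape])
    for g in geoms:
        xs, ys = np.asarray(g.exterior.coords).T
        rr, cc = draw_polygon(ys, xs, shape=(h, w))
        out[rr, cc] = True
    return out


def _check_fits(shapes: Sequence, image_size) -> None:
    h, w = image_size
    for shape in shapes:
        x0, y0, x1, y1 = shape.bounds
        if x0 < 0 or y0 < 0 or x1 > w - 1 or y1 > h - 1:
            raise GeometryError(
                f"leg does not fit the {h}x{w} frame "
                f"(structure bounds {x0:.0f},{y0:.0f},{x1:.0f},{y1:.0f})")


_INTENSITY = {"background": 0.1, "bone": 0.6, "implant": 0.95}


def generate_phantom(spec: PhantomSpec) -> tuple[Radiograph, GroundTruth]:
    """Render a phantom radiograph and its exact ground truth.

    The same spec and seed always produce bit-identical pixels; a bilateral
    spec renders two mirrored legs in one frame.
    """
    legs = []
    if spec.bilateral:
        first = spec.side
        second = "left" if first == "right" else "right"
        legs.append(_build_leg(spec, first, spec.resolved_hip()))
        legs.append(_build_leg(spec, second, spec.resolved_hip(mirrored=True)))
    else:
        legs.append(_build_leg(spec, spec.side, spec.resolved_hip()))

    all_shapes = [s for leg in legs for s in leg.shapes.values()]
    _check_fits(all_shapes, spec.image_size)

    h, w = spec.image_size
    canvas = np.full((h, w), _INTENSITY["background"], dtype=float)
    for leg in legs:
        for name, mask in leg.masks.items():
            value = _INTENSITY["implant"] if name.startswith("implant") else _INTENSITY["bone"]
            canvas[mask] = np.maximum(canvas[mask], value)
    if spec.blur_sigma > 0:
        canvas = ndi.gaussian_filter(canvas, spec.blur_sigma)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)

    rad = Radiograph(pixels=canvas, window_center=0.5, window_width=1.0,
                     source_id=f"phantom-seed{spec.seed}")
    return rad, GroundTruth(legs=legs, image_size=spec.image_size)


# ---------------------------------------------------------------------------
# spec sampling

DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "knee_varus_valgus": (-8.0, 8.0),
    "anat_mech_femur_angle": (5.0, 7.0),
    "femoral_jointline_obliquity": (-4.0, 4.0),
    "plateau_obliquity": (-4.0, 4.0),
    "ankle_obliquity": (-4.0, 4.0),
    "femur_length": (270.0, 300.0),
    "tibia_length": (255.0, 285.0),
    "noise_sd": (0.01, 0.03),
}


def sample_specs(n: int, ranges: dict | None = None, seed: int = 0,
                 implant: str = "none", bilateral: bool = False,
                 sides: Sequence[str] = ("right", "left")) -> list[PhantomSpec]:
    """Draw ``n`` reproducible phantom specs, each field uniform in its range."""
    if n < 1:
        raise ValueError(f"need n >= 1 specs, got {n}")
    eff = dict(DEFAULT_RANGES)
    if ranges:
        for key, rng_pair in ranges.items():
            if key not in DEFAULT_RANGES:
                raise ValueError(f"unknown sampled field {key!r}")
            lo, hi = rng_pair
            if not lo <= hi:
                raise ValueError(f"empty/inverted range for {key!r}: {rng_pair}")
            eff[key] = (float(lo), float(hi))
    for key in ("femoral_jointline_obliquity", "plateau_obliquity",
                "ankle_obliquity"):
        lo, hi = eff[key]
        if lo < -15 or hi > 15:
            raise ValueError(f"{key} range exceeds the +-15 degree invariant")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        fields = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in eff.items()}
        side = sides[int(rng.integers(len(sides)))]
        specs.append(PhantomSpec(side=side, implant=implant, bilateral=bilateral,
                                 seed=int(rng.integers(2**31 - 1)), **fields))
    return specs
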