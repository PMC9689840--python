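"""End-to-end measurement workflow.

One radiograph in, one alignment report per detected leg out:
normalize -> segment -> split legs -> side rule -> region crops ->
landmarks (TKA-aware model choice) -> back-projection -> axes -> the five
angles, with per-parameter availability accounting.  A ground-truth
sidecar (written by the phantom simulator) can substitute for the trained
models stage by stage, which is how the deterministic logic is validated
in isolation from learning.

Batch behavior: a failing image is logged and reported as all-unavailable;
the batch never aborts on one bad input.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import io as rio
from .geometry import (AlignmentReport, PARAMETERS, Unavailable, build_axes,
                       compute_alignment, detection_rates, project_to_image)
from .landmarks import LandmarkSet, Point, detect_landmarks, oracle_landmarks
from .roi import (LegGroup, RegionUnavailable, SideError, crop_region,
                  determine_leg_side, prepare_model_input, split_legs)
from .segmentation import SegmentationResult, oracle_segment, segment

log = logging.getLogger("limbalign")

__all__ = ["PipelineConfig", "measure_leg", "measure_image",
           "measure_ground_truth", "run_measure", "write_summary_csv"]


@dataclass
class PipelineConfig:
    segmenter_path: str | None = None
    landmark_paths: dict = field(default_factory=dict)  # region -> checkpoint
    score_threshold: float = 0.5
    peak_threshold: float = 0.2
    standard_display: bool = True
    output_dir: str = "."
    seed: int = 0
    verbosity: int = 1
    oracle: bool = False
    overlays: bool = False

    def __post_init__(self):
        for thr in (self.score_threshold, self.peak_threshold):
            if not 0.0 <= thr <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")

    def load_models(self):
        from .models import load_checkpoint

        seg = load_checkpoint(self.segmenter_path) if self.segmenter_path else None
        lms = {region: load_checkpoint(p)
               for region, p in self.landmark_paths.items()}
        return seg, lms


def _unavailable_report(side: str, reason: str, source_id: str = "") -> AlignmentReport:
    return AlignmentReport(
        side=side, angles={p: Unavailable(reason) for p in PARAMETERS},
        source_id=source_id)


def measure_leg(image01: np.ndarray, leg: LegGroup, landmark_models: dict,
                config: PipelineConfig, leg_truth=None,
                drop_regions=()) -> AlignmentReport:
    """Measure one leg group; ``leg_truth`` switches on the oracle route.

    ``drop_regions`` suppresses landmark regions (emulating a failed
    landmark stage) for availability accounting.
    """
    tibia, fibula = leg.get("tibia"), leg.get("fibula")
    if tibia is None or fibula is None:
        return _unavailable_report(
            "right", "undetermined side: tibia or fibula not detected")
    try:
        side = determine_leg_side(tibia.box, fibula.box,
                                  standard_display=config.standard_display)
    except SideError as e:
        return _unavailable_report("right", f"undetermined side: {e}")

    knee_region = "knee_tka" if leg.has_implant else "knee_native"
    sets: dict[str, LandmarkSet] = {}
    for region in ("proximal_femur", knee_region, "talus"):
        if region in drop_regions:
            continue
        try:
            crop = prepare_model_input(crop_region(region, leg, image01, side))
        except RegionUnavailable as e:
            log.info("region unavailable: %s", e)
            continue
        if leg_truth is not None:
            lset = oracle_landmarks(leg_truth, region, crop.transform)
        else:
            model = landmark_models.get(region)
            if model is None:
                continue
            lset = detect_landmarks(crop, model,
                                    peak_threshold=config.peak_threshold)
        sets[region] = project_to_image(lset, crop.transform)

    femur = leg.get("femur")
    femur_mask = None
    if femur is not None:
        femur_mask = femur.polygon if femur.polygon is not None else femur.mask
    bundle = build_axes(sets, side, femur_mask=femur_mask)
    return compute_alignment(bundle, side)


def measure_image(radiograph, segmenter, landmark_models: dict,
                  config: PipelineConfig,
                  ground_truth=None) -> list[AlignmentReport]:
    """Measure every leg on one radiograph (two for bilateral images)."""
    image01 = rio.normalized(radiograph)
    if ground_truth is not None:
        results = oracle_segment(ground_truth)
        truth_legs = list(ground_truth.legs)
    else:
        results = segment(radiograph.__class__(
            pixels=image01, window_center=0.5, window_width=1.0,
            source_id=radiograph.source_id), segmenter)
        truth_legs = None
    if not results:
        return [_unavailable_report("right", "no structures detected",
                                    radiograph.source_id)]
    groups = split_legs(results)
    reports = []
    for gi, leg in enumerate(groups):
        truth = None
        if truth_legs is not None:
            truth = _match_truth(leg, truth_legs)
        rep = measure_leg(image01, leg, landmark_models, config, leg_truth=truth)
        rep.source_id = radiograph.source_id
        reports.append(rep)
    return reports


def _match_truth(leg: LegGroup, truth_legs):
    """Pair a leg group with the ground-truth leg nearest in x."""
    cx = leg.center_x()
    def truth_cx(t):
        m = next(iter(t.masks.values()))
        xs = np.nonzero(m.any(axis=0))[0]
        return 0.5 * (xs[0] + xs[-1])
    return min(truth_legs, key=lambda t: abs(truth_cx(t) - cx))


def measure_ground_truth(ground_truth, config: PipelineConfig | None = None,
                         drop_structures=(), drop_regions=()) -> list[AlignmentReport]:
    """Oracle-path measurement straight from phantom ground truth.

    ``drop_structures`` removes segmentation labels before grouping and
    ``drop_regions`` suppresses landmark regions, emulating the two kinds
    of stage failure for availability tests.
    """
    config = config or PipelineConfig(oracle=True)
    results = [r for r in oracle_segment(ground_truth)
               if r.label not in set(drop_structures)]
    h, w = ground_truth.image_size
    image01 = np.zeros((h, w), dtype=np.float32)  # pixels unused on oracle path
    if not results:
        return [_unavailable_report("right", "no structures detected")]
    groups = split_legs(results)
    reports = []
    for leg in groups:
        truth = _match_truth(leg, list(ground_truth.legs))
        reports.append(measure_leg(image01, leg, {}, config, leg_truth=truth,
                                   drop_regions=drop_regions))
    return reports


# ---------------------------------------------------------------------------
# sidecar ground truth (JSON, written by the simulator)


def ground_truth_to_json(gt) -> dict:
    legs = []
    for leg in gt.legs:
        lm = {}
        for region, ls in leg.landmarks.items():
            lm[region] = [{"name": p.name, "role": p.role, "x": p.x, "y": p.y,
                           "confidence": p.confidence, "component": p.component}
                          for p in ls.points]
        polys = {}
        for label, shape in leg.shapes.items():
            geoms = getattr(shape, "geoms", [shape])
            polys[label] = [np.asarray(g.exterior.coords).tolist() for g in geoms]
        legs.append({"side": leg.side, "true_angles": leg.true_angles,
                     "landmarks": lm, "polygons": polys})
    return {"image_size": list(gt.image_size), "legs": legs}


def ground_truth_from_json(d: dict):
    from shapely.geometry import Polygon
    from shapely.ops import unary_union

    from .landmarks import LandmarkSet
    from .phantom import GroundTruth, LegTruth, rasterize

    image_size = tuple(d["image_size"])
    legs = []
    for leg_d in d["legs"]:
        lms = {}
        for region, pts in leg_d["landmarks"].items():
            points = [Point(p["name"], p["role"], p["x"], p["y"],
                            p["confidence"], p.get("component")) for p in pts]
            lms[region] = LandmarkSet(region=region, points=points, frame="image")
        shapes = {}
        masks = {}
        for label, rings in leg_d["polygons"].items():
            shape = unary_union([Polygon(r) for r in rings])
            shapes[label] = shape
            masks[label] = rasterize(shape, image_size)
        legs.append(LegTruth(side=leg_d["side"], landmarks=lms, masks=masks,
                             shapes=shapes, true_angles=leg_d["true_angles"]))
    return GroundTruth(legs=legs, image_size=image_size)


# ---------------------------------------------------------------------------
# batch driver


def _report_to_row(path, leg_index, rep: AlignmentReport) -> dict:
    row = {"image": os.path.basename(os.fspath(path)), "leg": leg_index,
           "side": rep.side}
    for p in PARAMETERS:
        v = rep.angles.get(p)
        if isinstance(v, Unavailable):
            row[p] = ""
            row[f"{p}_reason"] = v.reason
        else:
            row[p] = f"{v:.6f}"
            row[f"{p}_reason"] = ""
    return row


def report_to_json(rep: AlignmentReport) -> dict:
    angles = {}
    for p, v in rep.angles.items():
        if isinstance(v, Unavailable):
            angles[p] = {"available": False, "reason": v.reason}
        else:
            angles[p] = {"available": True, "degrees": v}
    out = {"side": rep.side, "source": rep.source_id, "angles": angles}
    b = rep.intermediate
    if b is not None:
        inter = {}
        for name in ("hip_center", "femoral_knee_center", "tibial_knee_center",
                     "ankle_center"):
            v = getattr(b, name)
            inter[name] = None if isinstance(v, Unavailable) else list(map(float, v))
        for name in ("femur_mech", "tibia_mech", "femur_shaft",
                     "femoral_joint_line", "plateau_line", "ankle_line"):
            v = getattr(b, name)
            inter[name] = None if isinstance(v, Unavailable) else {
                "point": list(map(float, v.point)),
                "direction": list(map(float, v.direction))}
        out["intermediate"] = inter
    return out


def write_summary_csv(rows, rates, path) -> None:
    import csv

    fields = ["image", "leg", "side"] + [p for p in PARAMETERS] + \
             [f"{p}_reason" for p in PARAMETERS]
    with open(path, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=fields)
        wr.writeheader()
        for row in rows:
            wr.writerow(row)
        for p in PARAMETERS:
            wr.writerow({"image": f"detection_rate_{p}",
                         "leg": "", "side": "",
                         p: f"{rates[p]['percent']:.1f}"})


def run_measure(paths, config: PipelineConfig) -> dict:
    """Measure a batch of radiographs and write reports + summary.

    Returns ``{"reports": [...], "rates": {...}, "failures": [...]}``.
    Output: one JSON report per image, an optional overlay PNG, and a
    deterministic batch summary CSV with per-parameter detection rates.
    """
    segmenter, lm_models = (None, {})
    if not config.oracle:
        segmenter, lm_models = config.load_models()
    os.makedirs(config.output_dir, exist_ok=True)
    all_reports, rows, failures = [], [], []
    for path in paths:
        try:
            rad = rio.load_radiograph(path)
            gt = None
            sidecar = os.fspath(path) + ".truth.json"
            if config.oracle:
                if not os.path.exists(sidecar):
                    raise FileNotFoundError(f"oracle mode needs sidecar {sidecar}")
                with open(sidecar) as fh:
                    gt = ground_truth_from_json(json.load(fh))
            reports = measure_image(rad, segmenter, lm_models, config,
                                    ground_truth=gt)
        except Exception as e:  # noqa: BLE001 - batch robustness is the contract
            log.warning("failed to measure %s: %s", path, e)
            failures.append((os.fspath(path), str(e)))
            reports = [_unavailable_report("right", f"image failure: {e}",
                                           os.path.basename(os.fspath(path)))]
        for li, rep in enumerate(reports):
            rows.append(_report_to_row(path, li, rep))
            all_reports.append(rep)
        base = os.path.splitext(os.path.basename(os.fspath(path)))[0]
        if config.overlays:
            try:
                from .viz import save_overlay

                save_overlay(os.path.join(config.output_dir,
                                          base + ".overlay.png"),
                             rio.normalized(rad), reports)
            except Exception as e:  # overlay is best-effort
                log.warning("overlay failed for %s: %s", path, e)
        with open(os.path.join(config.output_dir, base + ".report.json"), "w") as fh:
            json.dump([report_to_json(r) for r in reports], fh, indent=2,
                      sort_keys=True)
    rates = detection_rates(all_reports)
    write_summary_csv(rows, rates, os.path.join(config.output_dir, "summary.csv"))
    return {"reports": all_reports, "rates": rates, "failures": failures}
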