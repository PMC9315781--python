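"""Readers, writers, pipeline configuration, and the end-to-end runner.

Annotation input follows the VGG Image Annotator (VIA) JSON dialects: both
the full project layout (``_via_img_metadata``) and the bare per-image
region-list export are accepted.  Rectangles map to half-open 0-based
boxes as (x, y, x+width, y+height); polygons reduce to their axis-aligned
bounding rectangle, since the pipeline consumes boxes only.

Results are written as CSV (canonical, lossless at 6 significant digits)
or XLSX with a single "estimates" worksheet.  `run_pipeline` ties the
stages together: load frames, optional enhancement, detection, a score
filter (0.8 by default), box-to-size extraction, and the chained
depth/size/weight prediction — logging one line per stage with
input/output counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cascade import CascadeWeightEstimator, load_cascade
from .detection import (BBox, Detection, OracleDetector, ThresholdDetector,
                        bbox_to_size, filter_by_score)
from .enhancement import EnhancementConfig, enhance
from .synthetic import Scene, SceneAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "AnnotationSet",
    "read_via_annotations",
    "write_results",
    "read_results",
    "write_detections",
    "read_detections",
    "save_scenes",
    "load_scenes",
    "PipelineConfig",
    "run_pipeline",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "fish_id", "age_weeks", "length_px", "width_px",
    "depth_est_cm", "length_est_cm", "width_est_cm", "weight_est_g",
]

DETECTION_COLUMNS = ["image_id", "x_min", "y_min", "x_max", "y_max", "score"]


@dataclass(frozen=True)
class Region:
    """One annotated region: a box plus its free-form attributes."""

    bbox: BBox
    attributes: dict = field(default_factory=dict)
    shape: str = "rect"


#: filename -> list of regions
AnnotationSet = dict


def _coerce_attributes(raw: dict) -> dict:
    out = {}
    for key, value in (raw or {}).items():
        try:
            out[key] = float(value)
        except (TypeError, ValueError):
            out[key] = value
    return out


def _region_from_via(raw: dict) -> Region | None:
    shape = raw.get("shape_attributes", {})
    name = shape.get("name")
    if name == "rect":
        x, y = float(shape["x"]), float(shape["y"])
        w, h = float(shape["width"]), float(shape["height"])
        bbox = BBox(x, y, x + w, y + h)
    elif name in ("polygon", "polyline"):
        xs = [float(v) for v in shape["all_points_x"]]
        ys = [float(v) for v in shape["all_points_y"]]
        bbox = BBox(min(xs), min(ys), max(xs), max(ys))
    else:
        logger.warning("skipping region with unknown shape type %r", name)
        return None
    return Region(bbox=bbox,
                  attributes=_coerce_attributes(raw.get("region_attributes")),
                  shape="rect" if name == "rect" else "polygon")


def read_via_annotations(path) -> AnnotationSet:
    """Parse a VIA project file or bare region-list export."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed JSON in {path}: line {exc.lineno}: "
                         f"{exc.msg}") from exc
    if "_via_img_metadata" in payload:
        payload = payload["_via_img_metadata"]
    out: AnnotationSet = {}
    for key, entry in payload.items():
        if isinstance(entry, list):  # bare dialect: filename -> [regions]
            filename, regions = key, entry
        else:
            filename = entry.get("filename", key)
            regions = entry.get("regions", [])
        parsed = [_region_from_via(r) for r in regions]
        out[filename] = [r for r in parsed if r is not None]
    return out


def write_results(rows, path, fmt: str | None = None) -> None:
    """Write per-fish estimates as CSV (default) or XLSX.

    ``rows`` is a DataFrame or iterable of dicts with the result columns;
    zero rows produce a header-only file.
    """
    frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(
        list(rows), columns=RESULT_COLUMNS)
    frame = frame.reindex(columns=RESULT_COLUMNS)
    path = Path(path)
    fmt = fmt or ("xlsx" if path.suffix.lower() == ".xlsx" else "csv")
    if fmt == "csv":
        frame.to_csv(path, index=False, float_format="%.6g")
    elif fmt == "xlsx":
        frame.to_excel(path, index=False, sheet_name="estimates")
    else:
        raise ValueError(f"unknown results format {fmt!r}")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_detections(detections_by_image: dict, path) -> None:
    """CSV export of scored boxes: image_id, x_min, y_min, x_max, y_max, score."""
    rows = []
    for image_id, dets in detections_by_image.items():
        for d in dets:
            rows.append([image_id, d.bbox.x_min, d.bbox.y_min,
                         d.bbox.x_max, d.bbox.y_max, d.score])
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def read_detections(path) -> dict:
    frame = pd.read_csv(path)
    out: dict[str, list[Detection]] = {}
    for _, row in frame.iterrows():
        out.setdefault(str(row["image_id"]), []).append(Detection(
            bbox=BBox(row["x_min"], row["y_min"], row["x_max"], row["y_max"]),
            score=float(row["score"])))
    return out


# --- scene serialisation (PNG + companion VIA-style JSON) ----------------

def save_scenes(scenes, directory) -> Path:
    """Write scenes as numbered PNGs plus one VIA-style annotations.json."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    metadata = {}
    for i, scene in enumerate(scenes):
        filename = f"scene_{i:04d}.png"
        iio.imwrite(directory / filename, scene.image)
        regions = []
        for ann in scene.annotations:
            x0, y0, x1, y1 = ann.bbox
            regions.append({
                "shape_attributes": {"name": "rect", "x": x0, "y": y0,
                                     "width": x1 - x0, "height": y1 - y0},
                "region_attributes": {"fish_id": ann.fish_id,
                                      "age_weeks": ann.age_weeks,
                                      "depth_cm": ann.depth_label_cm},
            })
        metadata[filename] = {"filename": filename, "regions": regions,
                              "turbidity": scene.turbidity}
    ann_path = directory / "annotations.json"
    ann_path.write_text(json.dumps({"_via_img_metadata": metadata}, indent=1))
    return ann_path


def load_scenes(directory) -> list[Scene]:
    """Rebuild Scene objects from a directory written by `save_scenes`."""
    import imageio.v3 as iio

    directory = Path(directory)
    payload = json.loads((directory / "annotations.json").read_text())
    metadata = payload.get("_via_img_metadata", payload)
    scenes = []
    for filename in sorted(metadata):
        entry = metadata[filename]
        image = np.asarray(iio.imread(directory / filename))
        annotations = []
        for region in entry.get("regions", []):
            shape = region["shape_attributes"]
            attrs = region.get("region_attributes", {})
            annotations.append(SceneAnnotation(
                fish_id=str(attrs.get("fish_id", "")),
                bbox=(float(shape["x"]), float(shape["y"]),
                      float(shape["x"]) + float(shape["width"]),
                      float(shape["y"]) + float(shape["height"])),
                depth_label_cm=float(attrs.get("depth_cm", 0.0)),
                age_weeks=int(attrs.get("age_weeks", 0))))
        scenes.append(Scene(image=image, annotations=annotations,
                            turbidity=float(entry.get("turbidity", 0.0))))
    return scenes


# --- pipeline -----------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration (YAML-loadable)."""

    enhancement: EnhancementConfig = field(default_factory=EnhancementConfig)
    detector: str = "oracle"
    detector_params: dict = field(default_factory=dict)
    score_threshold: float = 0.8
    age_weeks: float | None = None
    model_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.detector not in ("oracle", "threshold"):
            raise ValueError(f"unknown detector backend {self.detector!r}")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        enh_raw = raw.pop("enhancement", {})
        enh_kwargs = {}
        for key in ("gamma", "alpha", "beta", "enabled"):
            if key in enh_raw:
                enh_kwargs[key] = enh_raw[key]
        if "sharpen_kernel" in enh_raw:
            enh_kwargs["sharpen_kernel"] = np.asarray(enh_raw["sharpen_kernel"],
                                                      dtype=float)
        if "ccm" in enh_raw:
            enh_kwargs["ccm"] = np.asarray(enh_raw["ccm"], dtype=float)
        if "offsets" in enh_raw:
            enh_kwargs["offsets"] = np.asarray(enh_raw["offsets"], dtype=float)
        return cls(enhancement=EnhancementConfig(**enh_kwargs), **raw)

    def build_detector(self):
        if self.detector == "oracle":
            return OracleDetector(seed=self.seed, **self.detector_params)
        return ThresholdDetector(**self.detector_params)


def run_pipeline(config: PipelineConfig, scenes,
                 model: CascadeWeightEstimator | None = None,
                 age_weeks: float | None = None,
                 out_path=None) -> pd.DataFrame:
    """Frames -> (enhance) -> detect -> filter -> sizes -> weights.

    ``scenes`` is a list of Scene objects or a directory written by
    `save_scenes`; the fish age is supplied by the user (``age_weeks`` or
    the config).  A fitted cascade must be given directly or through
    ``config.model_path``.  Returns the per-fish results table (and writes
    it when ``out_path`` is set); no detections anywhere yields an empty
    table with a warning, not an error.
    """
    if model is None:
        if not config.model_path:
            raise ValueError("no trained cascade: pass `model` or set "
                             "`model_path` in the pipeline config")
        model = load_cascade(config.model_path)
    age = age_weeks if age_weeks is not None else config.age_weeks
    if age is None:
        raise ValueError("fish age is user-supplied: set `age_weeks`")

    if isinstance(scenes, (str, Path)):
        scenes = load_scenes(scenes)
    scenes = list(scenes)
    logger.info("step 1 (frames): %d scene(s)", len(scenes))

    detector = config.build_detector()
    enhanced = 0
    rows = []
    n_detected = n_kept = 0
    for i, scene in enumerate(scenes):
        if config.enhancement.enabled:
            scene = Scene(image=enhance(scene.image, config.enhancement),
                          annotations=scene.annotations,
                          turbidity=scene.turbidity)
            enhanced += 1
        detections = detector.detect(scene)
        n_detected += len(detections)
        kept = filter_by_score(detections, config.score_threshold)
        n_kept += len(kept)
        for k, det in enumerate(kept):
            size = bbox_to_size(det.bbox)
            rows.append({"fish_id": f"scene{i:04d}_det{k:02d}",
                         "age_weeks": age,
                         "length_px": size.length_px,
                         "width_px": size.width_px})
    logger.info("step 2 (enhance): %d image(s) enhanced", enhanced)
    logger.info("step 3 (detect): %d detection(s), %d past the %.2f score "
                "filter", n_detected, n_kept, config.score_threshold)

    if not rows:
        logger.warning("no detections passed the filter; empty results")
        return pd.DataFrame(columns=RESULT_COLUMNS)

    obs = pd.DataFrame(rows)
    stages = model.predict_stages(
        obs[["age_weeks", "length_px", "width_px"]].to_numpy(dtype=float))
    logger.info("steps 4-6 (depth/cm/weight): %d fish estimated", len(stages))
    results = pd.DataFrame({
        "fish_id": obs["fish_id"],
        "age_weeks": obs["age_weeks"],
        "length_px": obs["length_px"],
        "width_px": obs["width_px"],
        "depth_est_cm": stages["depth_cm"].to_numpy(),
        "length_est_cm": stages["length_cm"].to_numpy(),
        "width_est_cm": stages["width_cm"].to_numpy(),
        "weight_est_g": stages["weight_g"].to_numpy(),
    })
    if out_path is not None:
        write_results(results, out_path)
    return results
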