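"""Synthetic Tilapia cohorts, underwater sightings, and rendered turbid scenes.

The generator stands in for an in-house biofloc-tank recording campaign:
Tilapia raised from week 20 to week 28, photographed every two weeks with a
fixed monocular camera at 1920x1080, with camera-to-fish distance ("depth")
read off floor markers spaced 10 cm apart.  Three layers are emulated:

* a growth model — cohort weight statistics interpolated between the two
  anchor weighings (166.45 +/- 26.38 g at week 20, 482.24 +/- 91.64 g at
  week 28), with length recovered through a cube-law allometry
  W = a * L^3 and width a fixed fraction of length;
* a pinhole camera — projected pixel size = true size * focal_px / depth,
  plus additive pixel measurement noise and marker-quantised depth labels;
* a scene renderer — fish drawn as filled ellipses on a flat water
  background, with turbidity modelled as contrast loss, a green colour
  cast, and Gaussian blur.  Ground-truth boxes are recorded exactly.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "FishRecord",
    "GrowthModel",
    "CameraModel",
    "Observation",
    "SceneAnnotation",
    "Scene",
    "ObservationOutOfFrame",
    "sample_population",
    "observe",
    "render_scene",
    "make_file_dataset",
    "FILE_DATASET_COLUMNS",
]

#: Canonical column order of the tabular ("file") dataset.
FILE_DATASET_COLUMNS = [
    "fish_id", "age_weeks", "length_px", "width_px",
    "depth_true_cm", "depth_label_cm", "length_cm", "width_cm", "weight_g",
]


class ObservationOutOfFrame(ValueError):
    """The fish's noiseless projection does not fit inside the image frame."""


@dataclass(frozen=True)
class FishRecord:
    """One animal: identity, age, true body dimensions, and mass."""

    fish_id: str
    age_weeks: int
    length_cm: float
    width_cm: float
    weight_g: float

    def __post_init__(self):
        if not self.weight_g > 0:
            raise ValueError("weight_g must be positive")
        if not self.length_cm > self.width_cm > 0:
            raise ValueError("require length_cm > width_cm > 0")


@dataclass(frozen=True)
class GrowthModel:
    """Cohort growth calibration between two anchor weighings.

    Mean and SD of weight are interpolated linearly in age between the
    anchors; individual weights are normal truncated at zero.  Length
    follows the cube-law allometry L = (W / allometric_a)^(1/3) and width
    is ``width_ratio * length``.  The default ``allometric_a`` places a
    166.45 g fish at 20 cm, so lengths span roughly 20-28.5 cm and widths
    7.6-10.8 cm over the anchor ages — inside the observed 20-30 cm and
    7-12 cm ranges.
    """

    anchor_ages: tuple[int, int] = (20, 28)
    anchor_mean_weights_g: tuple[float, float] = (166.45, 482.24)
    anchor_sd_weights_g: tuple[float, float] = (26.38, 91.64)
    allometric_a: float = 166.45 / 20.0**3
    width_ratio: float = 0.38

    def __post_init__(self):
        if self.anchor_ages[1] <= self.anchor_ages[0]:
            raise ValueError("anchor ages must be increasing")
        if self.anchor_mean_weights_g[1] <= self.anchor_mean_weights_g[0]:
            raise ValueError("anchor mean weights must be increasing with age")
        if not self.allometric_a > 0:
            raise ValueError("allometric_a must be positive")
        if not 0 < self.width_ratio < 1:
            raise ValueError("width_ratio must lie in (0, 1)")

    def _interp(self, age, pair):
        a0, a1 = self.anchor_ages
        t = (np.asarray(age, dtype=float) - a0) / (a1 - a0)
        return pair[0] + t * (pair[1] - pair[0])

    def mean_weight(self, age_weeks):
        return self._interp(age_weeks, self.anchor_mean_weights_g)

    def sd_weight(self, age_weeks):
        return self._interp(age_weeks, self.anchor_sd_weights_g)

    def length_from_weight(self, weight_g):
        return (np.asarray(weight_g, dtype=float) / self.allometric_a) ** (1.0 / 3.0)

    def check_age(self, age_weeks) -> None:
        a0, a1 = self.anchor_ages
        ages = np.atleast_1d(np.asarray(age_weeks))
        bad = ages[(ages < a0) | (ages > a1)]
        if bad.size:
            raise ValueError(
                f"age(s) {sorted(set(bad.tolist()))} outside the calibrated span "
                f"[{a0}, {a1}] weeks"
            )


@dataclass(frozen=True)
class CameraModel:
    """Pinhole projection geometry: projected_px = true_cm * focal_px / depth_cm.

    ``marker_spacing_cm`` is the spacing of the depth reference markers;
    ``None`` disables quantisation (depth labels equal true depth).
    """

    focal_px: float = 1000.0
    image_width_px: int = 1920
    image_height_px: int = 1080
    depth_min_cm: float = 5.0
    depth_max_cm: float = 60.0
    marker_spacing_cm: float | None = 10.0

    def __post_init__(self):
        if not self.focal_px > 0:
            raise ValueError("focal_px must be positive")
        if not self.depth_min_cm < self.depth_max_cm:
            raise ValueError("require depth_min_cm < depth_max_cm")

    def project(self, true_cm, depth_cm):
        return np.asarray(true_cm, dtype=float) * self.focal_px / np.asarray(depth_cm, dtype=float)

    def quantize_depth(self, depth_cm):
        """Nearest-marker depth label, clamped to the depth bounds."""
        if self.marker_spacing_cm is None:
            return np.asarray(depth_cm, dtype=float)
        s = self.marker_spacing_cm
        label = s * np.floor(np.asarray(depth_cm, dtype=float) / s + 0.5)
        return np.clip(label, self.depth_min_cm, self.depth_max_cm)


@dataclass(frozen=True)
class Observation:
    """One underwater sighting of a fish, with its training annotations."""

    fish_id: str
    age_weeks: int
    length_px: float
    width_px: float
    depth_true_cm: float
    depth_label_cm: float
    length_cm: float
    width_cm: float
    weight_g: float


@dataclass(frozen=True)
class SceneAnnotation:
    fish_id: str
    bbox: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max
    depth_label_cm: float
    age_weeks: int


@dataclass
class Scene:
    """A rendered frame with exact ground-truth annotations."""

    image: np.ndarray  # H x W x 3, uint8
    annotations: list[SceneAnnotation] = field(default_factory=list)
    turbidity: float = 0.0


def _truncated_normal(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    """Normal truncated at zero; degenerates to the constant when sd == 0."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    sd = np.broadcast_to(np.asarray(sd, dtype=float), size).copy()
    out = mean.copy()
    pos = sd > 0
    if np.any(pos):
        a = (0.0 - mean[pos]) / sd[pos]
        out[pos] = stats.truncnorm.rvs(
            a, np.inf, loc=mean[pos], scale=sd[pos], random_state=rng
        )
    return out


def _sample_population(rng: np.random.Generator, n: int, ages,
                       growth: GrowthModel) -> list[FishRecord]:
    ages = sorted(set(int(a) for a in ages))
    if not ages:
        raise ValueError("ages must be a non-empty set of weeks")
    growth.check_age(ages)
    if n == 0:
        return []
    age = rng.choice(np.asarray(ages), size=n)
    weight = _truncated_normal(rng, growth.mean_weight(age), growth.sd_weight(age), n)
    length = growth.length_from_weight(weight)
    width = growth.width_ratio * length
    return [
        FishRecord(
            fish_id=f"fish_{i:05d}",
            age_weeks=int(age[i]),
            length_cm=float(length[i]),
            width_cm=float(width[i]),
            weight_g=float(weight[i]),
        )
        for i in range(n)
    ]


def sample_population(n: int, ages, growth: GrowthModel | None = None,
                      seed: int = 0) -> list[FishRecord]:
    """Draw a cohort of ``n`` fish at the given ages.

    Weights come from the growth model's age-interpolated truncated normal;
    lengths and widths follow deterministically through the allometry, so
    the cohort statistics converge to the anchor mean/SD as n grows.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    growth = growth or GrowthModel()
    rng = np.random.default_rng(seed)
    return _sample_population(rng, n, ages, growth)


def _observe(rng: np.random.Generator, fish: FishRecord, camera: CameraModel,
             depth_cm: float, pixel_noise_sd: float) -> Observation:
    if not camera.depth_min_cm <= depth_cm <= camera.depth_max_cm:
        raise ValueError(
            f"depth {depth_cm} cm outside camera bounds "
            f"[{camera.depth_min_cm}, {camera.depth_max_cm}]"
        )
    length_px_true = float(camera.project(fish.length_cm, depth_cm))
    if length_px_true > camera.image_width_px:
        raise ObservationOutOfFrame(
            f"projected length {length_px_true:.0f} px exceeds image width "
            f"{camera.image_width_px} px (fish {fish.fish_id} at {depth_cm} cm)"
        )
    width_px_true = float(camera.project(fish.width_cm, depth_cm))
    noise = rng.normal(0.0, pixel_noise_sd, 2) if pixel_noise_sd > 0 else np.zeros(2)
    return Observation(
        fish_id=fish.fish_id,
        age_weeks=fish.age_weeks,
        length_px=length_px_true + float(noise[0]),
        width_px=width_px_true + float(noise[1]),
        depth_true_cm=float(depth_cm),
        depth_label_cm=float(camera.quantize_depth(depth_cm)),
        length_cm=fish.length_cm,
        width_cm=fish.width_cm,
        weight_g=fish.weight_g,
    )


def observe(fish: FishRecord, camera: CameraModel, depth_cm: float,
            pixel_noise_sd: float = 2.0, seed: int = 0) -> Observation:
    """Project one fish onto the image plane at the given camera distance.

    Raises :class:`ObservationOutOfFrame` when the noiseless projected
    length exceeds the image width (the fish cannot be fully framed), and
    ``ValueError`` for depths outside the camera bounds.
    """
    rng = np.random.default_rng(seed)
    return _observe(rng, fish, camera, depth_cm, pixel_noise_sd)


# Flat-water background and fish body colours (RGB).  Chosen for clean
# foreground/background contrast at zero turbidity so a plain threshold
# detector can recover the fish.
_WATER_RGB = np.array([38.0, 84.0, 110.0])
_FISH_RGB = np.array([178.0, 176.0, 165.0])


def render_scene(fish_obs, camera: CameraModel | None = None,
                 turbidity: float = 0.0, seed: int = 0) -> Scene:
    """Render observations as filled ellipses on a turbid-water background.

    Fish positions are drawn reproducibly from ``seed`` and do not depend on
    ``turbidity``, so the same seed at different turbidities yields identical
    annotations over different pixels.  Turbidity in [0, 1] applies contrast
    reduction, a green cast, and Gaussian blur, in that order; annotations
    record the exact drawn bounding boxes.
    """
    if not 0.0 <= turbidity <= 1.0:
        raise ValueError("turbidity must lie in [0, 1]")
    camera = camera or CameraModel()
    from skimage.draw import ellipse as _ellipse

    h, w = camera.image_height_px, camera.image_width_px
    img = np.empty((h, w, 3), dtype=float)
    img[:] = _WATER_RGB
    rng = np.random.default_rng(seed)

    annotations: list[SceneAnnotation] = []
    for obs in fish_obs:
        box_w = int(round(obs.length_px))
        box_h = int(round(obs.width_px))
        if box_w >= w or box_h >= h:
            raise ValueError(
                f"fish {obs.fish_id} ({box_w}x{box_h} px) does not fit in the "
                f"{w}x{h} frame"
            )
        x_min = int(rng.integers(0, w - box_w + 1))
        y_min = int(rng.integers(0, h - box_h + 1))
        shade = float(rng.uniform(-12.0, 12.0))  # per-fish brightness variation
        rr, cc = _ellipse(
            y_min + box_h / 2.0, x_min + box_w / 2.0,
            box_h / 2.0, box_w / 2.0, shape=(h, w),
        )
        img[rr, cc] = np.clip(_FISH_RGB + shade, 0, 255)
        annotations.append(SceneAnnotation(
            fish_id=obs.fish_id,
            bbox=(float(x_min), float(y_min),
                  float(x_min + box_w), float(y_min + box_h)),
            depth_label_cm=obs.depth_label_cm,
            age_weeks=obs.age_weeks,
        ))

    if turbidity > 0:
        mean = img.mean()
        img = mean + (1.0 - 0.7 * turbidity) * (img - mean)  # contrast loss
        img[..., 1] += 60.0 * turbidity                      # green cast
        sigma = 4.0 * turbidity
        for c in range(3):
            img[..., c] = ndimage.gaussian_filter(img[..., c], sigma)

    image = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return Scene(image=image, annotations=annotations, turbidity=float(turbidity))


def make_file_dataset(n: int, camera: CameraModel | None = None,
                      growth: GrowthModel | None = None, seed: int = 0,
                      ages=(20, 22, 24, 26, 28),
                      pixel_noise_sd: float = 2.0) -> pd.DataFrame:
    """Build the tabular training dataset of ``n`` complete sightings.

    One row per fish carries every cascade training symbol: age, pixel
    dimensions, true and marker-quantised depth, true centimetre
    dimensions, and weight.  Sighting depths are uniform over the camera
    bounds; a depth at which the fish would overflow the frame is redrawn
    until the sighting is valid, so exactly ``n`` rows are returned.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    camera = camera or CameraModel()
    growth = growth or GrowthModel()
    rng = np.random.default_rng(seed)

    fish = _sample_population(rng, n, ages, growth)
    rows = []
    for f in fish:
        while True:
            depth = float(rng.uniform(camera.depth_min_cm, camera.depth_max_cm))
            try:
                obs = _observe(rng, f, camera, depth, pixel_noise_sd)
            except ObservationOutOfFrame:
                continue
            break
        rows.append(obs)
    frame = pd.DataFrame(
        [[o.fish_id, o.age_weeks, o.length_px, o.width_px, o.depth_true_cm,
          o.depth_label_cm, o.length_cm, o.width_cm, o.weight_g] for o in rows],
        columns=FILE_DATASET_COLUMNS,
    )
    return frame
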