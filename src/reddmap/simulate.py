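"""Seeded synthetic lake scenes for end-to-end testing without drone data.

A scene emulates the structure of a subarctic lake shoreline seen from a
UAV at survey altitude: horizontal zones (vegetated land, pale shoreline,
shallow water over light substrate, dark deep water), with spawning redds
rendered as dark, irregular blob clusters inside the shallow zone — redds
read from the air as dark patches of cleaned gravel against the lighter
silt- and algae-covered substrate — and surface rocks as small
yellow-brown blobs on land and shore. Every pixel's colour is drawn from
its true class's Gaussian colour model plus isotropic sensor noise.

The colour models are plausible stand-ins reproducing the contrast
structure of such scenes (dark redds vs light substrate, dark deep water),
not measurements of any real lake. No water optics, sun glint or ripples
are rendered; noise is purely statistical.

Generation is pure given (config, seed): the same seed yields bit-identical
imagery, truth maps and ROI sets. Training and ground-truth ROIs are
sampled pixel-disjoint from class interiors (1 px in from class borders),
mimicking analyst-picked interior polygons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import ClassMap, ClassScheme, RGBImage, ROISet

#: Six endmember classes of a subarctic spawning-ground scene.
REDDS, VEGETATION, UNDERWATER_ROCKS, DEEP_WATER, SHORELINE, SURFACE_ROCKS = \
    1, 2, 3, 4, 5, 6


def default_lake_scheme() -> ClassScheme:
    """The six-class scheme of a lake spawning-ground scene."""
    return ClassScheme([
        (REDDS, "spawning redds", (220, 30, 30)),
        (VEGETATION, "vegetation", (40, 160, 40)),
        (UNDERWATER_ROCKS, "underwater rocks", (90, 200, 210)),
        (DEEP_WATER, "deep water", (20, 40, 140)),
        (SHORELINE, "shoreline", (240, 230, 80)),
        (SURFACE_ROCKS, "surface rocks", (160, 80, 200)),
    ])


#: Mean class colours on the unit scale: redds dark, substrate light,
#: deep water dark blue, shoreline palest, surface rocks yellow-brown.
DEFAULT_CLASS_MEANS: dict[int, tuple[float, float, float]] = {
    REDDS: (0.18, 0.18, 0.18),
    VEGETATION: (0.20, 0.55, 0.20),
    UNDERWATER_ROCKS: (0.55, 0.70, 0.72),
    DEEP_WATER: (0.05, 0.12, 0.35),
    SHORELINE: (0.85, 0.82, 0.75),
    SURFACE_ROCKS: (0.65, 0.55, 0.30),
}


@dataclass
class SceneConfig:
    """Synthetic-scene parameters.

    Zone band fractions (top to bottom: land, shoreline, shallow, deep)
    must sum to 1. The ROI sizes default to the survey design the pipeline
    is built around: ~15 training samples of ~65 pixels per class (975
    pixels) and ~1000 ground-truth pixels per class.
    """

    height: int = 512
    width: int = 512
    class_means: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEANS))
    class_covs: dict[int, np.ndarray] | None = None  # default: (0.01^2) I
    band_fractions: tuple[float, float, float, float] = (0.25, 0.10, 0.40, 0.25)
    redd_blob_count: int = 20
    redd_radius_range: tuple[float, float] = (5.0, 12.0)
    irregularity: float = 0.5
    rock_blob_count: int = 25
    rock_radius_range: tuple[float, float] = (4.0, 9.0)
    noise_sd: float = 0.02
    corruption_rate: float = 0.05
    train_pixels_per_class: int = 975
    truth_pixels_per_class: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        if not np.isclose(sum(self.band_fractions), 1.0):
            raise ValueError("band fractions must sum to 1")
        if self.redd_radius_range[0] <= 0 or self.rock_radius_range[0] <= 0:
            raise ValueError("blob radii must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def cov_for(self, cid: int) -> np.ndarray:
        if self.class_covs and cid in self.class_covs:
            cov = np.asarray(self.class_covs[cid], float)
        else:
            cov = (0.01 ** 2) * np.eye(3)
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-12:
            raise ValueError(f"class {cid}: covariance not PSD")
        return cov


@dataclass
class Scene:
    """One generated fixture: image, truth map, and disjoint ROI sets."""

    image: RGBImage
    truth: ClassMap
    training_rois: ROISet
    ground_truth_rois: ROISet

    def __iter__(self):
        return iter((self.image, self.truth,
                     self.training_rois, self.ground_truth_rois))


def _stamp_blobs(mask: np.ndarray, zone: tuple[int, int], count: int,
                 radius_range: tuple[float, float], irregularity: float,
                 rng: np.random.Generator) -> None:
    """Union of jittered discs: each blob is 5 overlapping discs whose
    centres are jittered by ``irregularity * r``, giving the irregular
    outline characteristic of redd clusters."""
    h, w = mask.shape
    r0, r1 = zone
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(count):
        r = rng.uniform(*radius_range)
        # jittered sub-discs reach (1 + irregularity) * r from the centre
        margin = int(np.ceil((1 + irregularity) * r)) + 1
        if r1 - margin <= r0 + margin:
            raise ValueError("zone too thin for the requested blob radii")
        cy = rng.uniform(r0 + margin, r1 - margin)
        cx = rng.uniform(margin, w - margin)
        for _ in range(5):
            jy = cy + rng.uniform(-1, 1) * irregularity * r
            jx = cx + rng.uniform(-1, 1) * irregularity * r
            rr = r * rng.uniform(0.6, 1.0)
            mask |= (yy - jy) ** 2 + (xx - jx) ** 2 <= rr ** 2
    np.clip(mask, False, True)


def _truth_map(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.height, config.width
    edges = np.cumsum([0] + [f * h for f in config.band_fractions]).astype(int)
    edges[-1] = h
    land, shore, shallow, deep = [(edges[i], edges[i + 1]) for i in range(4)]
    truth = np.zeros((h, w), dtype=np.int64)
    truth[land[0]:land[1]] = VEGETATION
    truth[shore[0]:shore[1]] = SHORELINE
    truth[shallow[0]:shallow[1]] = UNDERWATER_ROCKS
    truth[deep[0]:deep[1]] = DEEP_WATER
    rocks = np.zeros((h, w), dtype=bool)
    _stamp_blobs(rocks, (land[0], shore[1]), config.rock_blob_count,
                 config.rock_radius_range, config.irregularity, rng)
    truth[rocks] = SURFACE_ROCKS
    redds = np.zeros((h, w), dtype=bool)
    _stamp_blobs(redds, shallow, config.redd_blob_count,
                 config.redd_radius_range, config.irregularity, rng)
    truth[redds] = REDDS
    return truth


def _render(truth: np.ndarray, config: SceneConfig,
            rng: np.random.Generator) -> np.ndarray:
    h, w = truth.shape
    unit = np.zeros((h, w, 3))
    noise_cov = (config.noise_sd ** 2) * np.eye(3)
    for cid in np.unique(truth):
        mask = truth == cid
        n = int(mask.sum())
        cov = config.cov_for(int(cid)) + noise_cov
        mean = np.asarray(config.class_means[int(cid)])
        # Cholesky of a PSD matrix with zero-eigenvalue fallback
        eigval, eigvec = np.linalg.eigh(cov)
        root = eigvec * np.sqrt(np.clip(eigval, 0, None))
        unit[mask] = mean + rng.standard_normal((n, 3)) @ root.T
    unit = np.clip(unit, 0.0, 1.0)
    return np.round(unit * 255).astype(np.uint8)


def _sample_rois(truth: np.ndarray, config: SceneConfig,
                 rng: np.random.Generator) -> tuple[ROISet, ROISet]:
    train: dict[int, np.ndarray] = {}
    gt: dict[int, np.ndarray] = {}
    need = config.train_pixels_per_class + config.truth_pixels_per_class
    for cid in range(1, 7):
        mask = truth == cid
        interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3)))
        coords = np.argwhere(interior)
        if len(coords) < need:
            raise ValueError(
                f"class {cid}: only {len(coords)} interior pixels for "
                f"{need} requested ROI pixels — enlarge the scene or blobs")
        pick = rng.choice(len(coords), size=need, replace=False)
        train[cid] = coords[pick[:config.train_pixels_per_class]]
        gt[cid] = coords[pick[config.train_pixels_per_class:]]
    shape = truth.shape
    return (ROISet(train, shape, role="training"),
            ROISet(gt, shape, role="ground_truth"))


def generate_scene(config: SceneConfig | None = None) -> Scene:
    """Generate a seeded lake scene: image, truth map, disjoint ROI sets."""
    config = config or SceneConfig()
    rng = np.random.default_rng(config.rng_seed)
    truth = _truth_map(config, rng)
    pixels = _render(truth, config, rng)
    training, ground_truth = _sample_rois(truth, config, rng)
    scheme = default_lake_scheme()
    return Scene(
        image=RGBImage(pixels, bit_depth=8),
        truth=ClassMap(truth, scheme),
        training_rois=training,
        ground_truth_rois=ground_truth,
    )


def corrupt_labels(truth: ClassMap, rate: float, seed: int) -> ClassMap:
    """Salt-and-pepper label noise: each pixel independently flips with
    probability ``rate`` to a uniformly random *other* class label —
    the spurious isolated pixels the post-classification chain targets."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    labels = truth.labels.copy()
    flip = rng.random(labels.shape) < rate
    k = len(truth.scheme)
    # uniform over the k-1 other classes: draw 1..k-1 and shift past current
    draws = rng.integers(1, k, size=labels.shape)
    new = (labels - 1 + draws) % k + 1
    labels[flip] = new[flip]
    return truth.copy_with(labels)
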