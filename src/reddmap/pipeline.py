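"""End-to-end orchestration: simulate/load -> train -> classify ->
post-process -> assess, as one reproducible run.

A run writes, under its output directory: the class maps before and after
post-classification (with colourized previews), accuracy reports for both
(classification quality is always judged as a before/after pair), the
confusion matrices, a machine-readable run manifest (full config, package
version, seed) and a log of per-stage timings and changed-pixel counts.
The manifest fully determines the outputs of a maximum-likelihood run;
a neural-net run is determined by manifest + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .accuracy import accuracy_report, build_confusion_matrix
from .classify import (MLCConfig, NNConfig, classify_maximum_likelihood,
                       classify_neural_net, train_neural_net)
from .postclass import PostClassConfig, apply_postclassification
from .raster import (ClassMap, ClassScheme, RGBImage, ROISet, read_rgb_image,
                     read_roi_set, write_class_map, write_class_map_preview)
from .simulate import SceneConfig, default_lake_scheme, generate_scene
from .training import check_class_balance, compute_class_statistics

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One reproducible run: inputs, classifier choice, cleanup, seed."""

    output_dir: str | Path = "run"
    classifier: str = "mlc"
    image_path: str | None = None
    training_roi_path: str | None = None
    ground_truth_roi_path: str | None = None
    scene: SceneConfig | None = None
    mlc: MLCConfig = field(default_factory=MLCConfig)
    nn: NNConfig = field(default_factory=NNConfig)
    postclass: PostClassConfig = field(default_factory=PostClassConfig)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.classifier not in ("mlc", "nn"):
            raise ValueError("classifier must be 'mlc' or 'nn'")
        if self.scene is None and self.image_path is None:
            raise ValueError("need either an image path or a scene config")

    def to_manifest(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj
        return {
            "reddmap_version": __version__,
            "seed": self.seed,
            "config": {f.name: enc(getattr(self, f.name))
                       for f in dataclasses.fields(self)},
        }


@dataclass
class PipelineResult:
    """Everything a run produced, in memory plus on disk."""

    run_dir: Path
    pre_map: ClassMap
    post_map: ClassMap
    pre_report: object
    post_report: object
    step_changes: dict[str, int]
    timings: dict[str, float]


def _load_inputs(config: PipelineConfig
                 ) -> tuple[RGBImage, ClassScheme, ROISet, ROISet]:
    if config.scene is not None:
        scene_cfg = dataclasses.replace(config.scene, rng_seed=config.seed)
        scene = generate_scene(scene_cfg)
        return (scene.image, scene.truth.scheme, scene.training_rois,
                scene.ground_truth_rois)
    scheme = default_lake_scheme()
    image = read_rgb_image(config.image_path)
    train = read_roi_set(config.training_roi_path, scheme, image.shape,
                         role="training")
    gt = read_roi_set(config.ground_truth_roi_path, scheme, image.shape,
                      role="ground_truth")
    return image, scheme, train, gt


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; any failure aborts with a stage-tagged error."""
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    raise StageError(name, exc) from exc
        return _Timer()

    with stage("inputs"):
        image, scheme, train_rois, gt_rois = _load_inputs(config)
        if not gt_rois.is_disjoint_from(train_rois):
            raise ValueError("training and ground-truth ROIs overlap")

    with stage("train"):
        balance = check_class_balance(train_rois)
        log.info("%s", balance)
        stats = compute_class_statistics(image, train_rois)
        stats.save(run_dir / "class_statistics.txt")

    with stage("classify"):
        if config.classifier == "mlc":
            pre_map = classify_maximum_likelihood(image, stats, scheme,
                                                  config.mlc)
        else:
            nn_cfg = dataclasses.replace(config.nn, rng_seed=config.seed)
            model = train_neural_net(image, train_rois, nn_cfg)
            model.save(run_dir / "nn_model.json")
            pre_map = classify_neural_net(model, image, scheme)
        write_class_map(pre_map, run_dir / "classmap_pre.tif",
                        preview_path=run_dir / "classmap_pre.png")

    with stage("postprocess"):
        result = apply_postclassification(pre_map, config.postclass)
        post_map = result.map
        write_class_map(post_map, run_dir / "classmap_post.tif",
                        preview_path=run_dir / "classmap_post.png")
        for op, n in result.step_changes.items():
            log.info("  %s changed %d pixels", op, n)

    with stage("assess"):
        pre_cm = build_confusion_matrix(pre_map, gt_rois, training=train_rois)
        post_cm = build_confusion_matrix(post_map, gt_rois,
                                         training=train_rois)
        pre_cm.save_csv(run_dir / "confusion_pre.csv")
        post_cm.save_csv(run_dir / "confusion_post.csv")
        pre_rep = accuracy_report(pre_cm)
        post_rep = accuracy_report(post_cm)
        pre_rep.save_csv(run_dir / "accuracy_pre.csv")
        post_rep.save_csv(run_dir / "accuracy_post.csv")
        _write_comparison(pre_rep, post_rep, run_dir / "accuracy_compare.txt")

    manifest = config.to_manifest()
    manifest["timings_s"] = {k: round(v, 4) for k, v in timings.items()}
    manifest["step_changes"] = result.step_changes
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(run_dir=run_dir, pre_map=pre_map, post_map=post_map,
                          pre_report=pre_rep, post_report=post_rep,
                          step_changes=result.step_changes, timings=timings)


def _write_comparison(pre, post, path: Path) -> None:
    """Before/after table: per-class PA/UA deltas plus OA and kappa."""
    lines = ["class                    PA pre  PA post  dPA    UA pre  UA post  dUA"]
    for c in pre.scheme:
        pa0 = 100 * pre.producer_accuracy[c.id]
        pa1 = 100 * post.producer_accuracy[c.id]
        ua0 = 100 * pre.user_accuracy[c.id]
        ua1 = 100 * post.user_accuracy[c.id]
        lines.append(f"{c.name:<24} {pa0:6.2f} {pa1:8.2f} {pa1 - pa0:+6.2f} "
                     f"{ua0:7.2f} {ua1:8.2f} {ua1 - ua0:+6.2f}")
    lines.append("")
    lines.append(f"overall accuracy: {100 * pre.overall_accuracy:.2f}% -> "
                 f"{100 * post.overall_accuracy:.2f}%")
    lines.append(f"kappa: {pre.kappa:.2f} -> {post.kappa:.2f}")
    path.write_text("\n".join(lines) + "\n")
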