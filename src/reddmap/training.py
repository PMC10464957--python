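"""Per-class spectral statistics estimated from training ROIs.

The maximum-likelihood classifier is parameterized by each endmember
class's mean vector and covariance matrix, estimated from analyst-selected
training pixels. Statistics are always computed on intensities rescaled to
[0, 1] so that 8- and 16-bit imagery train identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .raster import RGBImage, ROISet

log = logging.getLogger(__name__)

#: Minimum training pixels per class for a (3x3) covariance to be estimable.
MIN_PIXELS_PER_CLASS = 4

#: Advisory max/min class-count ratio above which the balance check warns.
BALANCE_WARN_RATIO = 2.0


@dataclass
class ClassStatistics:
    """Per-class sample count, band means and unbiased covariance.

    ``singular`` flags classes whose covariance is not invertible (e.g. a
    constant-colour training set); the classifier regularizes these.
    """

    n: dict[int, int]
    mean: dict[int, np.ndarray]
    cov: dict[int, np.ndarray]
    singular: set[int] = field(default_factory=set)
    band_scaling: str = "unit"  # intensities rescaled to [0, 1]

    def class_ids(self) -> list[int]:
        return sorted(self.n)

    def to_text(self) -> str:
        lines = ["# class statistics (band scaling: %s)" % self.band_scaling,
                 "# class, n, mean[3], cov[3x3] row-major, singular"]
        for cid in self.class_ids():
            m = ",".join(f"{v:.10g}" for v in self.mean[cid])
            c = ",".join(f"{v:.10g}" for v in self.cov[cid].ravel())
            lines.append(f"{cid},{self.n[cid]},{m},{c},"
                         f"{int(cid in self.singular)}")
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "ClassStatistics":
        n, mean, cov, singular = {}, {}, {}, set()
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            cid = int(parts[0])
            n[cid] = int(parts[1])
            mean[cid] = np.array([float(v) for v in parts[2:5]])
            cov[cid] = np.array([float(v) for v in parts[5:14]]).reshape(3, 3)
            if int(parts[14]):
                singular.add(cid)
        return cls(n=n, mean=mean, cov=cov, singular=singular)


def compute_class_statistics(image: RGBImage,
                             training_rois: ROISet) -> ClassStatistics:
    """Estimate mean vector and covariance matrix per endmember class.

    Means are arithmetic band means over the class's ROI pixels; the
    covariance is the unbiased (n-1) sample covariance. Classes whose
    covariance is singular are flagged for downstream regularization.

    Raises ``ValueError`` if any class has fewer than
    ``MIN_PIXELS_PER_CLASS`` pixels.
    """
    unit = image.as_unit_float()
    n, mean, cov, singular = {}, {}, {}, set()
    for cid in training_rois.class_ids():
        coords = training_rois.pixels[cid]
        if len(coords) < MIN_PIXELS_PER_CLASS:
            raise ValueError(
                f"class {cid}: {len(coords)} training pixels, need at least "
                f"{MIN_PIXELS_PER_CLASS}")
        samples = unit[coords[:, 0], coords[:, 1]]  # (n, 3)
        n[cid] = len(samples)
        mean[cid] = samples.mean(axis=0)
        cov[cid] = np.cov(samples, rowvar=False, ddof=1)
        if np.linalg.matrix_rank(cov[cid]) < 3:
            singular.add(cid)
            log.warning("class %d: singular covariance, will be regularized",
                        cid)
    return ClassStatistics(n=n, mean=mean, cov=cov, singular=singular)


@dataclass
class BalanceReport:
    """Per-class training pixel counts and their max/min ratio."""

    counts: dict[int, int]
    ratio: float
    balanced: bool

    def __str__(self) -> str:
        rows = "\n".join(f"  class {c}: {n} px"
                         for c, n in sorted(self.counts.items()))
        verdict = "balanced" if self.balanced else (
            f"imbalanced (ratio {self.ratio:.2f} > {BALANCE_WARN_RATIO:g}); "
            "training classes should hold similar pixel counts")
        return f"training class balance: {verdict}\n{rows}"


def check_class_balance(training_rois: ROISet) -> BalanceReport:
    """Report per-class pixel counts; warn (not error) when max/min > 2.

    Heavily unequal training classes bias the classifier toward the
    over-represented spectra, so counts per class should be similar.
    """
    counts = training_rois.counts()
    if not counts:
        raise ValueError("empty ROISet")
    values = [v for v in counts.values()]
    lo = min(values)
    ratio = float("inf") if lo == 0 else max(values) / lo
    balanced = ratio <= BALANCE_WARN_RATIO
    if not balanced:
        log.warning("training class imbalance: max/min pixel ratio %.2f",
                    ratio)
    return BalanceReport(counts=counts, ratio=ratio, balanced=balanced)
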