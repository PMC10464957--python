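"""Spatial post-classification operators: majority/minority analysis,
sieve, and clump.

Pixel-based classification leaves spurious isolated pixels; the three
operators are applied in sequence to clean the map. Recommended settings
for irregular spawning-redd mosaics: majority analysis with a 3x3 kernel
and centre-pixel weight 1; sieve at 4-connectivity with minimum component
size 2; clump with a 3x3 square structuring element.

Conventions (documented, deterministic):

* majority vote ties keep the centre pixel's label when it is among the
  winners, otherwise the lowest class id wins; windows are clipped at the
  image border;
* sieve sends under-size components to label 0 (unclassified) — this is
  how stray unclassified pixels appear in an otherwise fully classified
  map;
* clump processes classes in descending pixel-count order (ascending id on
  ties); pixels gained by a class's morphological closing adopt the class
  only where the map is unclassified or held a class processed earlier,
  and a pixel changed once is not changed again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import ClassMap

log = logging.getLogger(__name__)

_CONN4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class PostClassConfig:
    """Parameters of the three-operator clean-up chain (defaults are the
    recommended settings for irregular redd mosaics)."""

    majority_kernel: int = 3
    center_pixel_weight: int = 1
    sieve_connectivity: int = 4
    sieve_min_size: int = 2
    clump_size: int = 3
    operator_order: tuple[str, ...] = ("majority", "sieve", "clump")

    def __post_init__(self):
        if self.majority_kernel < 3 or self.majority_kernel % 2 == 0:
            raise ValueError("majority kernel must be an odd integer >= 3")
        if self.center_pixel_weight < 1:
            raise ValueError("centre pixel weight must be positive")
        if self.sieve_connectivity not in (4, 8):
            raise ValueError("sieve connectivity must be 4 or 8")
        if self.sieve_min_size < 1:
            raise ValueError("sieve minimum size must be positive")
        if self.clump_size < 1:
            raise ValueError("clump size must be >= 1")
        unknown = set(self.operator_order) - {"majority", "sieve", "clump"}
        if unknown:
            raise ValueError(f"unknown operators {sorted(unknown)}")


def majority_minority_filter(cmap: ClassMap, kernel: int = 3,
                             center_weight: int = 1,
                             mode: str = "majority") -> ClassMap:
    """Replace each pixel with the locally dominant label.

    Each pixel's output is the label with the largest vote count in its
    ``kernel x kernel`` window, the centre's own label counted
    ``center_weight`` times. Windows are clipped at the border. In
    ``minority`` mode the least-voted present label wins instead (the
    centre keeps its label on ties in either mode).
    """
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 3")
    if center_weight < 1:
        raise ValueError("centre weight must be positive")
    if mode not in ("majority", "minority"):
        raise ValueError("mode must be 'majority' or 'minority'")
    labels = cmap.labels
    present = np.unique(labels)
    footprint = np.ones((kernel, kernel), dtype=np.int64)
    votes = np.empty((len(present),) + labels.shape, dtype=np.int64)
    for i, lab in enumerate(present):
        onehot = (labels == lab).astype(np.int64)
        counts = ndimage.correlate(onehot, footprint, mode="constant", cval=0)
        votes[i] = counts + (center_weight - 1) * onehot
    if mode == "majority":
        best = votes.max(axis=0)
    else:
        masked = np.where(votes > 0, votes, np.iinfo(np.int64).max)
        best = masked.min(axis=0)
    is_best = votes == best
    center_idx = np.searchsorted(present, labels)
    center_is_best = np.take_along_axis(
        is_best, center_idx[None], axis=0)[0]
    # lowest present label among the winners (present is sorted)
    lowest_winner = present[is_best.argmax(axis=0)]
    out = np.where(center_is_best, labels, lowest_winner)
    return cmap.copy_with(out.astype(labels.dtype))


def sieve_classes(cmap: ClassMap, connectivity: int = 4,
                  min_size: int = 2) -> ClassMap:
    """Unclassify connected components smaller than ``min_size``.

    Components are computed per class at 4- or 8-connectivity; components
    with fewer than ``min_size`` pixels are set to 0, everything else is
    untouched. Label 0 itself is never sieved.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if min_size < 1:
        raise ValueError("min_size must be positive")
    structure = _CONN4 if connectivity == 4 else _CONN8
    labels = cmap.labels.copy()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        comp, n = ndimage.label(labels == lab, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]  # component ids 1..n
        small = np.flatnonzero(sizes < min_size) + 1
        if small.size:
            labels[np.isin(comp, small)] = 0
    return cmap.copy_with(labels)


def _closing(mask: np.ndarray, size: int) -> np.ndarray:
    """Binary closing with a size x size square element, background-padded."""
    structure = np.ones((size, size), dtype=bool)
    padded = np.pad(mask, size, mode="constant", constant_values=False)
    dil = ndimage.binary_dilation(padded, structure=structure)
    ero = ndimage.binary_erosion(dil, structure=structure)
    return ero[size:-size, size:-size]


def clump_classes(cmap: ClassMap, size: int = 3) -> ClassMap:
    """Merge adjacent same-class areas by per-class morphological closing.

    Classes are processed in descending pixel-count order (ascending id on
    ties). Pixels gained by a closing adopt the class only where the input
    map holds 0 or a class already processed, and a pixel changed by one
    class is not changed again by a later one.
    """
    if size < 1:
        raise ValueError("clump size must be >= 1")
    labels = cmap.labels
    present = [int(v) for v in np.unique(labels) if v != 0]
    counts = {c: int((labels == c).sum()) for c in present}
    order = sorted(present, key=lambda c: (-counts[c], c))
    out = labels.copy()
    changed = np.zeros(labels.shape, dtype=bool)
    processed: list[int] = []
    for c in order:
        mask = labels == c
        gained = _closing(mask, size) & ~mask
        eligible = gained & ~changed & (
            (labels == 0) | np.isin(labels, processed))
        out[eligible] = c
        changed |= eligible
        processed.append(c)
    return cmap.copy_with(out)


@dataclass
class PostClassResult:
    """Cleaned map plus per-step changed-pixel counts."""

    map: ClassMap
    step_changes: dict[str, int] = field(default_factory=dict)


def apply_postclassification(cmap: ClassMap,
                             config: PostClassConfig | None = None
                             ) -> PostClassResult:
    """Run the operators in ``config.operator_order``, logging per-step
    changed-pixel counts."""
    config = config or PostClassConfig()
    current = cmap
    changes: dict[str, int] = {}
    for op in config.operator_order:
        if op == "majority":
            nxt = majority_minority_filter(
                current, config.majority_kernel, config.center_pixel_weight)
        elif op == "sieve":
            nxt = sieve_classes(current, config.sieve_connectivity,
                                config.sieve_min_size)
        else:
            nxt = clump_classes(current, config.clump_size)
        n = int((nxt.labels != current.labels).sum())
        changes[op] = n
        log.info("post-classification %s: %d pixels changed", op, n)
        current = nxt
    return PostClassResult(map=current, step_changes=changes)
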