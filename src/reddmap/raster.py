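"""Raster containers and file I/O for the redd-mapping pipeline.

Shared spatial conventions, used everywhere in the package:

* pixel coordinates are 0-based ``(row, col)`` with row 0 at the top;
* an RGB image is an ``H x W x 3`` array of intensities at a declared bit
  depth (8- or 16-bit); classifiers operate on the image rescaled to the
  unit interval so imagery from different cameras behaves identically;
* a class map is an ``H x W`` integer raster where label 0 is reserved for
  "unclassified" and labels 1..K are the endmember classes of a scheme.

GeoTIFF georeferencing tags (pixel scale / tiepoint) are carried through
opaquely; this package performs no georeferencing math.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image as PILImage

log = logging.getLogger(__name__)

#: GeoTIFF tags passed through untouched on read/write.
_GEO_TAGS = (33550, 33922, 34264)  # ModelPixelScale, ModelTiepoint, ModelTransformation


class RasterIOError(Exception):
    """Raised when a raster or ROI file cannot be read or validated."""


@dataclass(frozen=True)
class ClassDef:
    """One endmember class: integer label, name and display colour."""

    id: int
    name: str
    color: tuple[int, int, int]


class ClassScheme:
    """Ordered endmember classes with contiguous ids 1..K (0 = unclassified)."""

    def __init__(self, classes: Sequence[ClassDef | tuple]):
        defs = [c if isinstance(c, ClassDef) else ClassDef(c[0], c[1], tuple(c[2]))
                for c in classes]
        if len(defs) < 2:
            raise ValueError("a class scheme needs at least 2 classes")
        ids = [c.id for c in defs]
        if ids != list(range(1, len(defs) + 1)):
            raise ValueError(f"class ids must be contiguous 1..K, got {ids}")
        names = [c.name for c in defs]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        self.classes: tuple[ClassDef, ...] = tuple(defs)

    @property
    def ids(self) -> list[int]:
        return [c.id for c in self.classes]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.classes]

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def __eq__(self, other) -> bool:
        return isinstance(other, ClassScheme) and self.classes == other.classes

    def id_of(self, name: str) -> int:
        for c in self.classes:
            if c.name == name:
                return c.id
        raise KeyError(f"unknown class name {name!r}")

    def name_of(self, class_id: int) -> str:
        if not 1 <= class_id <= len(self):
            raise KeyError(f"class id {class_id} not in scheme")
        return self.classes[class_id - 1].name

    def to_dict(self) -> list[dict]:
        return [{"id": c.id, "name": c.name, "color": list(c.color)}
                for c in self.classes]

    @classmethod
    def from_dict(cls, entries: Sequence[Mapping]) -> "ClassScheme":
        return cls([ClassDef(e["id"], e["name"], tuple(e["color"])) for e in entries])


@dataclass
class RGBImage:
    """A 3-band intensity raster with a declared bit depth.

    ``pixels`` is H x W x 3; ``bit_depth`` is 8 or 16; ``meta`` carries
    opaque georeferencing tags for passthrough.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"RGB image must be H x W x 3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have positive height and width")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit depth must be 8 or 16, got {self.bit_depth}")
        if not np.isfinite(px).all():
            raise ValueError("image contains non-finite values")
        if px.min() < 0 or px.max() > 2 ** self.bit_depth - 1:
            raise ValueError("pixel values exceed the declared bit depth")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def as_unit_float(self) -> np.ndarray:
        """Pixels linearly rescaled to [0, 1] by the declared bit depth."""
        return self.pixels.astype(np.float64) / (2 ** self.bit_depth - 1)


@dataclass
class ClassMap:
    """An H x W categorical raster over a class scheme; 0 = unclassified."""

    labels: np.ndarray
    scheme: ClassScheme

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("class map must be 2-D")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("class map labels must be integers")
        k = len(self.scheme)
        if lab.min() < 0 or lab.max() > k:
            raise ValueError(
                f"labels must lie in 0..{k}, got range "
                f"[{lab.min()}, {lab.max()}]")
        self.labels = lab

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def copy_with(self, labels: np.ndarray) -> "ClassMap":
        return ClassMap(labels, self.scheme)


class ROISet:
    """Labelled pixel coordinate sets per class (training or ground truth).

    Coordinates are 0-based (row, col) within an image of shape
    ``image_shape``. Within a class, duplicate pixels are rejected.
    """

    def __init__(self, pixels: Mapping[int, np.ndarray],
                 image_shape: tuple[int, int], role: str = "training"):
        if role not in ("training", "ground_truth"):
            raise ValueError(f"role must be training|ground_truth, got {role!r}")
        h, w = image_shape
        clean: dict[int, np.ndarray] = {}
        for cid, coords in pixels.items():
            arr = np.atleast_2d(np.asarray(coords, dtype=np.intp))
            if arr.size == 0:
                arr = arr.reshape(0, 2)
            if arr.shape[1] != 2:
                raise ValueError("ROI coordinates must be (row, col) pairs")
            if arr.size and (arr.min() < 0 or arr[:, 0].max() >= h
                             or arr[:, 1].max() >= w):
                bad = arr[(arr[:, 0] < 0) | (arr[:, 0] >= h)
                          | (arr[:, 1] < 0) | (arr[:, 1] >= w)][0]
                raise RasterIOError(
                    f"class {cid}: ROI pixel {tuple(bad)} outside "
                    f"{h}x{w} image")
            if len(np.unique(arr, axis=0)) != len(arr):
                raise RasterIOError(f"class {cid}: duplicate ROI pixels")
            clean[int(cid)] = arr
        self.pixels = clean
        self.image_shape = (int(h), int(w))
        self.role = role

    def class_ids(self) -> list[int]:
        return sorted(self.pixels)

    def count(self, class_id: int) -> int:
        return len(self.pixels.get(class_id, ()))

    def counts(self) -> dict[int, int]:
        return {cid: len(px) for cid, px in self.pixels.items()}

    def total(self) -> int:
        return sum(len(px) for px in self.pixels.values())

    def coordinate_set(self) -> set[tuple[int, int]]:
        return {tuple(rc) for px in self.pixels.values() for rc in px}

    def is_disjoint_from(self, other: "ROISet") -> bool:
        return not (self.coordinate_set() & other.coordinate_set())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ROISet):
            return NotImplemented
        return (self.role == other.role
                and self.image_shape == other.image_shape
                and self.class_ids() == other.class_ids()
                and all(np.array_equal(
                    np.sort(self.pixels[c], axis=0),
                    np.sort(other.pixels[c], axis=0))
                    for c in self.class_ids()))


# ---------------------------------------------------------------------------
# raster read/write

def read_rgb_image(path: str | Path) -> RGBImage:
    """Read a raster, keeping the first three bands.

    TIFFs go through tifffile (preserving georeferencing tags); PNG/JPEG
    through Pillow. Extra bands (e.g. alpha) are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"no such file: {path}")
    meta: dict = {}
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile
            with tifffile.TiffFile(path) as tf:
                arr = tf.pages[0].asarray()
                for tag in _GEO_TAGS:
                    if tag in tf.pages[0].tags:
                        meta[tag] = tf.pages[0].tags[tag].value
        else:
            arr = np.asarray(PILImage.open(path))
    except RasterIOError:
        raise
    except Exception as exc:  # unreadable / undecodable
        raise RasterIOError(f"cannot decode {path}: {exc}") from exc
    if arr.ndim == 2:
        raise RasterIOError(f"{path}: single-band raster, need >= 3 bands")
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise RasterIOError(f"{path}: need >= 3 bands, got shape {arr.shape}")
    if arr.shape[2] > 3:
        log.warning("%s: %d bands, keeping bands 1-3 and dropping the rest",
                    path, arr.shape[2])
        warnings.warn(f"{path.name}: keeping bands 1-3 of {arr.shape[2]}",
                      stacklevel=2)
        arr = arr[:, :, :3]
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return RGBImage(arr, bit_depth=bit_depth, meta=meta)


def write_rgb_image(image: RGBImage, path: str | Path) -> None:
    """Write an RGB image (TIFF via tifffile, PNG/JPEG via Pillow)."""
    path = Path(path)
    dtype = np.uint16 if image.bit_depth == 16 else np.uint8
    arr = image.pixels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        extratags = [(tag, "d" if tag != 33922 else "d", len(np.ravel(v)),
                      tuple(np.ravel(v))) for tag, v in image.meta.items()
                     if tag in _GEO_TAGS]
        tifffile.imwrite(path, arr, extratags=extratags)
    else:
        PILImage.fromarray(arr).save(path)


def write_class_map(cmap: ClassMap, path: str | Path,
                    preview_path: str | Path | None = None) -> None:
    """Write a class map as a single-band categorical raster.

    TIFF output stores raw label ids; an optional PNG preview colourizes
    labels with the scheme colours (background black).
    """
    path = Path(path)
    dtype = np.uint8 if len(cmap.scheme) < 256 else np.uint16
    arr = cmap.labels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, arr)
    else:
        PILImage.fromarray(arr).save(path)
    if preview_path is not None:
        write_class_map_preview(cmap, preview_path)


def write_class_map_preview(cmap: ClassMap, path: str | Path) -> None:
    """Colourized PNG preview of a class map using scheme colours."""
    lut = np.zeros((len(cmap.scheme) + 1, 3), dtype=np.uint8)
    for c in cmap.scheme:
        lut[c.id] = c.color
    rgb = lut[cmap.labels]
    PILImage.fromarray(rgb).save(Path(path))


def read_class_map(path: str | Path, scheme: ClassScheme) -> ClassMap:
    """Read a single-band categorical raster back into a ClassMap."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(PILImage.open(path))
    if arr.ndim != 2:
        raise RasterIOError(f"{path}: class map must be single-band")
    return ClassMap(arr.astype(np.int64), scheme)


# ---------------------------------------------------------------------------
# ROI read/write

def _rasterize_polygon(vertices_rc: np.ndarray,
                       image_shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centres fall inside a polygon given as (row, col) vertices."""
    from skimage.measure import grid_points_in_poly
    inside = grid_points_in_poly(image_shape, np.asarray(vertices_rc, float))
    return np.argwhere(inside)


def read_roi_set(path: str | Path, scheme: ClassScheme,
                 image_shape: tuple[int, int],
                 role: str = "training") -> ROISet:
    """Read an ROI file (GeoJSON polygons or ``class,row,col`` CSV).

    GeoJSON features carry a "class" property (name or id); polygon
    coordinates are (x, y) = (col, row) and are converted to the package's
    (row, col) convention. Polygons are rasterized by centre containment.
    """
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"no such file: {path}")
    if path.suffix.lower() in (".json", ".geojson"):
        return _read_roi_geojson(path, scheme, image_shape, role)
    return _read_roi_csv(path, scheme, image_shape, role)


def _class_id(value, scheme: ClassScheme) -> int:
    if isinstance(value, str) and not value.isdigit():
        return scheme.id_of(value)  # raises KeyError for unknown names
    cid = int(value)
    if cid not in scheme.ids:
        raise RasterIOError(f"class id {cid} not in scheme")
    return cid


def _read_roi_csv(path, scheme, image_shape, role) -> ROISet:
    pixels: dict[int, list] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for line_no, row in enumerate(reader, 1):
            if not row or row[0].strip().lower() == "class":
                continue
            if len(row) != 3:
                raise RasterIOError(f"{path}:{line_no}: expected class,row,col")
            try:
                cid = _class_id(row[0].strip(), scheme)
            except KeyError as exc:
                raise RasterIOError(f"{path}:{line_no}: {exc}") from exc
            pixels.setdefault(cid, []).append((int(row[1]), int(row[2])))
    return ROISet({c: np.array(v) for c, v in pixels.items()}, image_shape, role)


def _read_roi_geojson(path, scheme, image_shape, role) -> ROISet:
    with open(path) as fh:
        gj = json.load(fh)
    pixels: dict[int, list[np.ndarray]] = {}
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if "class" not in props:
            raise RasterIOError(f"{path}: feature missing 'class' property")
        try:
            cid = _class_id(props["class"], scheme)
        except KeyError as exc:
            raise RasterIOError(f"{path}: {exc}") from exc
        geom = feat["geometry"]
        if geom["type"] == "Polygon":
            ring_xy = np.asarray(geom["coordinates"][0], float)
            verts_rc = ring_xy[:, ::-1]  # (x, y) -> (row, col)
            coords = _rasterize_polygon(verts_rc, image_shape)
        elif geom["type"] == "MultiPoint":
            xy = np.asarray(geom["coordinates"], float)
            coords = xy[:, ::-1].astype(np.intp)
        else:
            raise RasterIOError(f"{path}: unsupported geometry {geom['type']}")
        pixels.setdefault(cid, []).append(coords)
    merged = {}
    for cid, chunks in pixels.items():
        allc = np.vstack([c for c in chunks if len(c)]) if chunks else np.empty((0, 2))
        merged[cid] = np.unique(allc.astype(np.intp), axis=0) if len(allc) else allc
    return ROISet(merged, image_shape, role)


def write_roi_set(rois: ROISet, path: str | Path,
                  scheme: ClassScheme | None = None) -> None:
    """Write an ROISet; CSV gets ``class,row,col`` rows, GeoJSON MultiPoints."""
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        feats = []
        for cid in rois.class_ids():
            coords = rois.pixels[cid]
            name = scheme.name_of(cid) if scheme else cid
            feats.append({
                "type": "Feature",
                "properties": {"class": name, "role": rois.role},
                "geometry": {
                    "type": "MultiPoint",
                    # (row, col) -> GeoJSON (x, y)
                    "coordinates": [[int(c), int(r)] for r, c in coords],
                },
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["class", "row", "col"])
            for cid in rois.class_ids():
                for r, c in rois.pixels[cid]:
                    writer.writerow([cid, int(r), int(c)])
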