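"""Readers/writers for detection annotations and mask rasterization.

Two interchange formats are supported:

* ``polygon_json`` — a COCO-style annotation file (images / annotations /
  categories) with polygon segmentations. Tooth categories are named by FDI
  code ("11".."48") or "tooth" for unlabeled detections; alveolar-bone
  polylines use the "alveolar_bone" category.
* ``label_mask`` — one 16-bit integer-labeled PNG per radiograph
  (0 = background) plus a CSV sidecar (instance_id, score, fdi_code).
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import Polygon
from skimage import measure

from .types import (
    AlveolarContour,
    DetectionSet,
    FDILabel,
    Point2D,
    ToothInstance,
)

TOOTH_CATEGORY = "tooth"
BONE_CATEGORY = "alveolar_bone"


class FormatError(ValueError):
    """Raised when an annotation file does not parse under its declared format."""


def instance_center(instance: ToothInstance) -> Point2D:
    """Bounding-box midpoint (the calibration algorithm's notion of a center)."""
    return instance.center


# ---------------------------------------------------------------------------
# polygon_json
# ---------------------------------------------------------------------------

def _segmentation_to_contour(seg) -> np.ndarray:
    if not isinstance(seg, list) or not seg:
        raise FormatError("segmentation must be a non-empty list of polygons")
    flat = seg[0]
    if len(flat) < 6 or len(flat) % 2:
        raise FormatError(f"polygon needs >=3 (x, y) pairs, got {len(flat)} numbers")
    return np.asarray(flat, dtype=float).reshape(-1, 2)


def save_polygon_json(
    path,
    dets: DetectionSet,
    contours: Optional[list[AlveolarContour]] = None,
) -> None:
    categories = [{"id": 0, "name": TOOTH_CATEGORY}, {"id": 100, "name": BONE_CATEGORY}]
    categories += [{"id": c, "name": str(c)} for c in range(11, 49) if c % 10 <= 8 and c % 10 >= 1]
    annotations = []
    for i, t in enumerate(dets.instances, start=1):
        x0, y0, x1, y1 = t.bbox
        annotations.append(
            {
                "id": i,
                "image_id": dets.image_id,
                "instance_id": t.instance_id,
                "category_id": t.label.code if t.label else 0,
                "segmentation": [t.contour.reshape(-1).tolist()],
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "score": t.score,
            }
        )
    for j, bone in enumerate(contours or []):
        annotations.append(
            {
                "id": 10_000 + j,
                "image_id": dets.image_id,
                "category_id": 100,
                "segmentation": [bone.polyline.reshape(-1).tolist()],
                "attributes": {"jaw": bone.jaw},
            }
        )
    doc = {
        "images": [
            {
                "id": dets.image_id,
                "width": dets.image_size[0],
                "height": dets.image_size[1],
                "source": dets.source,
            }
        ],
        "annotations": annotations,
        "categories": categories,
    }
    Path(path).write_text(json.dumps(doc))


def load_polygon_json(path) -> tuple[DetectionSet, list[AlveolarContour]]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    try:
        img = doc["images"][0]
        cat_names = {c["id"]: c["name"] for c in doc["categories"]}
    except (KeyError, IndexError, TypeError) as exc:
        raise FormatError(f"{path}: missing images/categories section") from exc

    instances: list[ToothInstance] = []
    bones: list[AlveolarContour] = []
    for ann in doc.get("annotations", []):
        name = cat_names.get(ann.get("category_id"))
        if name is None:
            raise FormatError(f"{path}: annotation {ann.get('id')} has unknown category")
        if name == BONE_CATEGORY:
            pts = np.asarray(ann["segmentation"][0], dtype=float).reshape(-1, 2)
            bones.append(AlveolarContour(ann.get("attributes", {}).get("jaw", "upper"), pts))
            continue
        label = None
        if name != TOOTH_CATEGORY:
            try:
                label = FDILabel(int(name))
            except ValueError as exc:
                raise FormatError(f"{path}: annotation {ann['id']}: {exc}") from exc
        try:
            contour = _segmentation_to_contour(ann["segmentation"])
            instances.append(
                ToothInstance(
                    instance_id=str(ann.get("instance_id", ann["id"])),
                    contour=contour,
                    score=float(ann.get("score", 1.0)),
                    label=label,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: annotation {ann.get('id')}: {exc}") from exc
    dets = DetectionSet(
        image_id=str(img["id"]),
        image_size=(int(img["width"]), int(img["height"])),
        instances=instances,
        source=img.get("source", "ground_truth"),
    )
    return dets, bones


# ---------------------------------------------------------------------------
# label_mask
# ---------------------------------------------------------------------------

def save_label_mask(png_path, csv_path, dets: DetectionSet) -> None:
    w, h = dets.image_size
    grid = np.zeros((h, w), dtype=np.uint16)
    rows = []
    for k, t in enumerate(dets.instances, start=1):
        grid[rasterize(t, dets.image_size)] = k
        rows.append((t.instance_id, t.score, t.label.code if t.label else ""))
    Image.fromarray(grid).save(png_path)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mask_value", "instance_id", "score", "fdi_code"])
        for k, (iid, score, code) in enumerate(rows, start=1):
            writer.writerow([k, iid, score, code])


def load_label_mask(png_path, csv_path, image_id: str = "", source="binary") -> DetectionSet:
    grid = np.asarray(Image.open(png_path))
    if grid.ndim != 2:
        raise FormatError(f"{png_path}: label mask must be a single-channel image")
    meta: dict[int, tuple[str, float, Optional[int]]] = {}
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            code = row.get("fdi_code", "").strip()
            meta[int(row["mask_value"])] = (
                row["instance_id"],
                float(row["score"]),
                int(code) if code else None,
            )
    instances = []
    for value in np.unique(grid):
        if value == 0:
            continue
        if int(value) not in meta:
            raise FormatError(f"{png_path}: mask value {value} missing from sidecar")
        iid, score, code = meta[int(value)]
        contour = contour_from_mask(grid == value)
        instances.append(
            ToothInstance(
                instance_id=iid,
                contour=contour,
                score=score,
                label=FDILabel(code) if code else None,
            )
        )
    h, w = grid.shape
    return DetectionSet(image_id or Path(png_path).stem, (w, h), instances, source)


def load_instances(path, fmt: str = "polygon_json", **kwargs) -> DetectionSet:
    """Load a DetectionSet from ``polygon_json`` or ``label_mask`` input.

    For ``label_mask``, ``path`` is the PNG and the sidecar CSV is expected
    next to it with suffix ``.csv`` (or passed as ``csv_path=``).
    """
    if fmt == "polygon_json":
        return load_polygon_json(path)[0]
    if fmt == "label_mask":
        csv_path = kwargs.pop("csv_path", Path(path).with_suffix(".csv"))
        return load_label_mask(path, csv_path, **kwargs)
    raise ValueError(f"unknown format: {fmt!r}")


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize(instance: ToothInstance, image_size: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside or on the polygon.

    Pixel (i, j) covers the point (x=j, y=i); the polygon is evaluated at
    pixel centers, so an axis-aligned square with corners (0,0)-(9,9) fills
    exactly 10x10 pixels.
    """
    w, h = image_size
    x, y = instance.contour[:, 0], instance.contour[:, 1]
    if x.min() < -0.5 or y.min() < -0.5 or x.max() > w - 0.5 or y.max() > h - 0.5:
        raise ValueError(
            f"contour of {instance.instance_id!r} extends outside a {w}x{h} image"
        )
    poly = instance.polygon
    if poly.area == 0:
        raise ValueError("degenerate polygon has zero area")
    mask = np.zeros((h, w), dtype=bool)
    j0, j1 = max(0, math.floor(x.min())), min(w - 1, math.ceil(x.max()))
    i0, i1 = max(0, math.floor(y.min())), min(h - 1, math.ceil(y.max()))
    jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
    # covers() (unlike contains) includes the boundary
    inside = shapely.covers(poly, shapely.points(jj.ravel(), ii.ravel()))
    mask[ii.ravel()[inside], jj.ravel()[inside]] = True
    return mask


def contour_from_mask(mask: np.ndarray) -> np.ndarray:
    """Extract the dominant outer contour of a binary mask as (x, y) vertices."""
    padded = np.pad(mask.astype(float), 1)
    found = measure.find_contours(padded, 0.5)
    if not found:
        raise ValueError("mask is empty")
    longest = max(found, key=lambda c: Polygon(c[:, ::-1]).area if len(c) >= 3 else 0.0)
    verts = longest[:, ::-1] - 1.0  # (row, col) -> (x, y), undo padding
    poly = Polygon(verts).simplify(0.1)
    out = np.asarray(poly.exterior.coords[:-1], dtype=float)
    if len(out) < 3:
        raise ValueError("mask region too small to form a polygon")
    return out
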