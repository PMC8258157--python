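"""Core data model for tooth/bone instances and derived measurements.

Coordinate convention: image coordinates, 0-based, pixel-centered.
``x`` is the image column, ``y`` the image row; y increases downward.
Polygons are closed implicitly (last vertex connects back to the first).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, NamedTuple, Optional, Sequence

import numpy as np
from shapely.geometry import Polygon

Jaw = Literal["upper", "lower"]

#: Valid permanent-tooth FDI codes: quadrant (1-4) * 10 + position (1-8).
FDI_CODES: tuple[int, ...] = tuple(
    10 * q + p for q in (1, 2, 3, 4) for p in range(1, 9)
)

#: Canonical feature order of the 32-slot ratio vector: 11..18, 21..28, 31..38, 41..48.
CANONICAL_FDI_ORDER: tuple[int, ...] = FDI_CODES


class Point2D(NamedTuple):
    x: float
    y: float


@dataclass(frozen=True)
class FDILabel:
    """Two-digit FDI tooth code (11-18, 21-28, 31-38, 41-48)."""

    code: int

    def __post_init__(self) -> None:
        if self.code not in FDI_CODES:
            raise ValueError(f"not a permanent-tooth FDI code: {self.code}")

    @property
    def quadrant(self) -> int:
        return self.code // 10

    @property
    def position(self) -> int:
        return self.code % 10

    @property
    def jaw(self) -> Jaw:
        return "upper" if self.quadrant in (1, 2) else "lower"

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return str(self.code)


def _as_contour(points: Iterable) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError(
            f"contour must be an (N>=3, 2) array of points, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("contour contains non-finite coordinates")
    return arr


@dataclass
class ToothInstance:
    """One detected or annotated tooth.

    ``bbox`` is (x_min, y_min, x_max, y_max); ``center`` is the bbox midpoint
    (the calibration algorithm works on bounding-box centers, not centroids).
    Both are recomputed from the contour when not supplied.
    """

    instance_id: str
    contour: np.ndarray
    score: float = 1.0
    label: Optional[FDILabel] = None
    bbox: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        self.contour = _as_contour(self.contour)
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        if self.bbox is None:
            x, y = self.contour[:, 0], self.contour[:, 1]
            self.bbox = (float(x.min()), float(y.min()), float(x.max()), float(y.max()))
        else:
            x0, y0, x1, y1 = self.bbox
            cx, cy = self.contour[:, 0], self.contour[:, 1]
            if cx.min() < x0 - 1e-9 or cx.max() > x1 + 1e-9 or \
               cy.min() < y0 - 1e-9 or cy.max() > y1 + 1e-9:
                raise ValueError("bbox does not enclose the contour")
        if not self.polygon.is_simple:
            raise ValueError(f"contour of {self.instance_id!r} self-intersects")

    @property
    def center(self) -> Point2D:
        x0, y0, x1, y1 = self.bbox
        return Point2D((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.contour)

    def with_label(self, label: Optional[FDILabel]) -> "ToothInstance":
        return replace(self, label=label, contour=self.contour.copy())


Source = Literal["binary", "multiclass", "ground_truth"]


@dataclass
class DetectionSet:
    """All tooth instances detected (or annotated) on one radiograph."""

    image_id: str
    image_size: tuple[int, int]  # (width, height) pixels
    instances: list[ToothInstance] = field(default_factory=list)
    source: Source = "ground_truth"

    def __post_init__(self) -> None:
        ids = [t.instance_id for t in self.instances]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate instance ids in {self.image_id!r}")

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)

    def get(self, instance_id: str) -> ToothInstance:
        for t in self.instances:
            if t.instance_id == instance_id:
                return t
        raise KeyError(instance_id)

    def labeled(self) -> list[ToothInstance]:
        return [t for t in self.instances if t.label is not None]


@dataclass
class AlveolarContour:
    """Polyline tracing one jaw's alveolar-bone crest."""

    jaw: Jaw
    polyline: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.polyline, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise ValueError("alveolar polyline needs >=2 (x, y) points")
        self.polyline = arr


@dataclass(frozen=True)
class ReferenceLine:
    """Bone reference line through two distinct points of the alveolar contour."""

    p1: Point2D
    p2: Point2D

    def __post_init__(self) -> None:
        if self.p1 == self.p2:
            raise ValueError("reference line points must be distinct")

    def coefficients(self) -> tuple[float, float, float]:
        """Return (a, b, c) of the normalized line a*x + b*y + c = 0."""
        (x1, y1), (x2, y2) = self.p1, self.p2
        a, b = y2 - y1, x1 - x2
        norm = float(np.hypot(a, b))
        return a / norm, b / norm, (x2 * y1 - x1 * y2) / norm


@dataclass(frozen=True)
class ABLMeasurement:
    """Per-tooth alveolar-bone-loss quantities.

    d_c: bone line to crown top (pixels); d_r: root bottom to bone line;
    crr = d_c/d_r (crown-to-root ratio); d = crr/(1+crr) = d_c/(d_c+d_r).
    """

    d_c: float
    d_r: float

    def __post_init__(self) -> None:
        if self.d_c < 0:
            raise ValueError("d_c must be >= 0")
        if self.d_r <= 0:
            raise ValueError("d_r must be > 0 (d undefined at zero root height)")

    @property
    def crr(self) -> float:
        return self.d_c / self.d_r

    @property
    def d(self) -> float:
        return self.d_c / (self.d_c + self.d_r)


class SeverityGrade(enum.IntEnum):
    """Ordinal 4-class periodontitis severity."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    def __str__(self) -> str:
        return self.name.lower()

    @classmethod
    def from_name(cls, name: str) -> "SeverityGrade":
        return cls[name.upper()]


@dataclass
class RatioVector:
    """32-slot ABL feature vector D in canonical FDI order, with imputation flags."""

    values: np.ndarray
    imputed: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if self.values.shape != (32,) or self.imputed.shape != (32,):
            raise ValueError("ratio vector must have exactly 32 slots")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratio vector values must be finite")
        if np.any(self.values < 0) or np.any(self.values >= 1):
            raise ValueError("ratios must lie in [0, 1)")

    def measured_max(self) -> float:
        """Maximum over non-imputed slots (0.0 if every slot is imputed)."""
        obs = self.values[~self.imputed]
        return float(obs.max()) if obs.size else 0.0


def fdi_index(code: int) -> int:
    """Index of an FDI code in the canonical 32-slot order."""
    FDILabel(code)  # validates
    return CANONICAL_FDI_ORDER.index(code)


# ---------------------------------------------------------------------------
# Arch-slot geometry: position of each FDI code along a jaw, left to right in
# image coordinates. Default orientation places the patient's right side on
# the image left, so the upper jaw reads 18..11 then 21..28 and the lower jaw
# 48..41 then 31..38. ``mirrored=True`` flips both.
# ---------------------------------------------------------------------------

def fdi_to_slot(code: int, mirrored: bool = False) -> int:
    lab = FDILabel(code)
    q, p = lab.quadrant, lab.position
    left = {False: (1, 4), True: (2, 3)}[mirrored]  # quadrants on image left
    if q in left:
        return 8 - p
    return 7 + p


def slot_to_fdi(slot: int, jaw: Jaw, mirrored: bool = False) -> int:
    if not 0 <= slot <= 15:
        raise ValueError(f"arch slot out of range: {slot}")
    if jaw == "upper":
        q_left, q_right = (2, 1) if mirrored else (1, 2)
    else:
        q_left, q_right = (3, 4) if mirrored else (4, 3)
    if slot <= 7:
        return 10 * q_left + (8 - slot)
    return 10 * q_right + (slot - 7)
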