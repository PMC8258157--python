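"""Per-tooth alveolar-bone-loss (ABL) ratio from tooth and bone contours.

The bone crest near a tooth is locally smooth, so a reference line drawn
through two randomly chosen vertices of the local alveolar segment stands in
for the crest level. The crown-side extent d_c (line to crown top) and the
root-side extent d_r (root bottom to line) are estimated as the largest
distance from a random sample of crown/root contour points to that line.
The crown-to-root ratio CRR = d_c/d_r yields the normalized loss ratio

    d = CRR / (1 + CRR) = d_c / (d_c + d_r),

which is 1/3 for a healthy tooth whose crown is a third of its height and
approaches 1 as the bone recedes toward the root apex.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .types import (
    ABLMeasurement,
    AlveolarContour,
    Jaw,
    Point2D,
    ReferenceLine,
    ToothInstance,
)


def _local_segment(
    contour: AlveolarContour, tooth_bbox: tuple[float, float, float, float]
) -> np.ndarray:
    """Alveolar vertices within the tooth bbox extended by one bbox width
    on each side (a whole-jaw line is meaningless on a curved arch)."""
    x0, _, x1, _ = tooth_bbox
    w = x1 - x0
    pts = contour.polyline
    sel = (pts[:, 0] >= x0 - w) & (pts[:, 0] <= x1 + w)
    return pts[sel]


def fit_reference_line(
    contour: AlveolarContour,
    tooth_bbox: tuple[float, float, float, float],
    seed: int = 0,
) -> ReferenceLine:
    """Draw two distinct vertices (uniformly, seeded) from the tooth-local
    alveolar segment and return the line through them."""
    local = _local_segment(contour, tooth_bbox)
    # distinct coordinates, not just distinct indices
    uniq = np.unique(local, axis=0) if local.size else local
    if len(uniq) < 2:
        raise ValueError(
            "fewer than 2 alveolar vertices near the tooth: widen the window "
            "or densify the bone contour"
        )
    rng = np.random.default_rng(seed)
    i, j = rng.choice(len(uniq), size=2, replace=False)
    return ReferenceLine(Point2D(*uniq[i]), Point2D(*uniq[j]))


def _signed_distances(points: np.ndarray, line: ReferenceLine) -> np.ndarray:
    a, b, c = line.coefficients()
    return a * points[:, 0] + b * points[:, 1] + c


def split_crown_root(
    tooth: ToothInstance, line: ReferenceLine, jaw: Jaw
) -> tuple[np.ndarray, np.ndarray]:
    """Partition contour vertices into (crown, root) by the bone line.

    The crown lies on the occlusal side: downward (larger y) for an upper
    tooth, upward for a lower one, in image coordinates. Vertices exactly on
    the line count as crown. Raises if the line misses the tooth.
    """
    pts = tooth.contour
    s = _signed_distances(pts, line)
    # orient the signed distance so positive means larger y (image downward)
    _, b, _ = line.coefficients()
    if b < 0:
        s = -s
    elif b == 0:
        raise ValueError("bone reference line is vertical; cannot split crown/root")
    crown_side = s >= 0 if jaw == "upper" else s <= 0
    crown, root = pts[crown_side], pts[~crown_side]
    if len(crown) == 0 or len(root) == 0:
        raise ValueError("bone line does not cross the tooth contour")
    return crown, root


def _max_sampled_distance(
    points: np.ndarray,
    line: ReferenceLine,
    fraction: float,
    rng: np.random.Generator,
    vertical: bool,
) -> float:
    k = math.ceil(fraction * len(points))
    idx = rng.choice(len(points), size=k, replace=False) if k < len(points) else np.arange(len(points))
    sample = points[idx]
    if vertical:
        # strict image-vertical distance to the line (for comparison only)
        (x1, y1), (x2, y2) = line.p1, line.p2
        if x1 == x2:
            raise ValueError("vertical reference line has no vertical distance")
        slope = (y2 - y1) / (x2 - x1)
        d = np.abs(sample[:, 1] - (y1 + slope * (sample[:, 0] - x1)))
    else:
        d = np.abs(_signed_distances(sample, line))
    return float(d.max())


def estimate_abl(
    tooth: ToothInstance,
    contour: AlveolarContour,
    jaw: Jaw,
    sample_fraction: float = 0.5,
    n_draws: int = 1,
    seed: int = 0,
    line: Optional[ReferenceLine] = None,
    vertical_distance: bool = False,
) -> ABLMeasurement:
    """Estimate the ABL ratio of one tooth.

    Per draw, ``ceil(sample_fraction * n)`` crown vertices are sampled
    without replacement and d_c is their largest (perpendicular, by
    default) distance to the bone reference line; d_r analogously over the
    root vertices. With ``n_draws > 1`` the distances are averaged over
    independent draws, which tightens the estimate without biasing it.
    ``sample_fraction=1`` is the deterministic all-vertex maximum.
    """
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    if line is None:
        line = fit_reference_line(contour, tooth.bbox, seed=int(rng.integers(2**31)))
    crown, root = split_crown_root(tooth, line, jaw)
    dcs, drs = [], []
    for _ in range(n_draws):
        dcs.append(_max_sampled_distance(crown, line, sample_fraction, rng, vertical_distance))
        drs.append(_max_sampled_distance(root, line, sample_fraction, rng, vertical_distance))
    d_c, d_r = float(np.mean(dcs)), float(np.mean(drs))
    if d_r <= 0:
        raise ValueError("zero root extent below the bone line: ratio undefined")
    return ABLMeasurement(d_c=d_c, d_r=d_r)
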