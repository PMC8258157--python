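"""Synthetic fixtures for every pipeline stage.

Three generators, all seeded and deterministic:

* :func:`simulate_arch_detections` — dental-arch detection scenes: up to 16
  teeth per jaw placed along parabolic arcs with missing teeth, center
  jitter and a sparse, partially wrong set of FDI seed labels, emulating
  the complete-unlabeled / sparse-labeled detector pair the calibration
  stage consumes.
* :func:`simulate_tooth_geometry` — a single tooth contour (flat occlusal
  edge, tapered root with a small apex plateau) crossed by a bone contour
  at a known loss fraction, so the ABL estimate has an analytic truth.
* :func:`simulate_ratio_cohort` — cohorts of 32-slot ratio vectors whose
  worst-tooth values sit inside the staging bands, for classifier tests.

:func:`simulate_full_scene` composes the first two into an end-to-end
radiograph stand-in: positioned teeth with crown/root geometry, an alveolar
polyline per jaw, detection sets, and per-tooth analytic loss ratios.

None of this models image intensities; only geometry and topology matter to
the downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grading import MILD_THRESHOLD, SEVERE_THRESHOLD, assemble_ratio_vector
from .types import (
    AlveolarContour,
    DetectionSet,
    FDILabel,
    Jaw,
    RatioVector,
    SeverityGrade,
    ToothInstance,
    fdi_to_slot,
    slot_to_fdi,
)

IMAGE_SIZE = (1024, 1024)
_MIDLINE_X = 512.0
_SPACING = 50.0  # nominal horizontal center-to-center spacing, px
_UPPER_Y, _LOWER_Y, _CURVE = 350.0, 650.0, 60.0
_TOOTH_W, _TOOTH_H = 36.0, 70.0


# ---------------------------------------------------------------------------
# arch detection scenes
# ---------------------------------------------------------------------------

@dataclass
class ArchSimConfig:
    """Scene parameters.

    ``spacing_jitter`` is the maximum fractional deviation of an adjacent
    center gap from the nominal spacing (each tooth's x is shifted by
    U(-j/2, j/2) spacings). ``label_fraction`` of the present teeth appear
    in the sparse multiclass set; ``label_error_rate`` of those carry a
    code moved to an adjacent arch station, the realistic detector failure.
    """

    teeth_per_quadrant: int = 8
    missing: frozenset[int] = frozenset()
    spacing_jitter: float = 0.1
    center_noise: float = 2.0
    label_fraction: float = 0.4
    label_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.teeth_per_quadrant <= 8:
            raise ValueError("teeth_per_quadrant must be in 1..8")
        for name in ("spacing_jitter", "label_fraction", "label_error_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.spacing_jitter >= 0.5:
            raise ValueError("spacing_jitter must be < 0.5")
        self.missing = frozenset(FDILabel(c).code for c in self.missing)


@dataclass
class ArchScene:
    ground_truth: DetectionSet
    binary: DetectionSet
    multiclass: DetectionSet
    truth: dict[str, int] = field(default_factory=dict)  # binary id -> FDI code

    def __iter__(self):
        return iter((self.ground_truth, self.binary, self.multiclass))


def _arch_centers(jaw: Jaw, slots, rng, jitter: float):
    xs, ys = [], []
    for s in slots:
        t = (s - 7.5) / 7.5
        x = _MIDLINE_X + (s - 7.5) * _SPACING + rng.uniform(-0.5, 0.5) * jitter * _SPACING
        if jaw == "upper":
            y = _UPPER_Y - _CURVE * t * t
        else:
            y = _LOWER_Y + _CURVE * t * t
        xs.append(x)
        ys.append(y)
    return np.array(xs), np.array(ys)


def _rect_contour(cx, cy, w, h, rng=None, noise=0.0):
    base = np.array(
        [
            (cx - w / 2, cy - h / 2),
            (cx + w / 2, cy - h / 2),
            (cx + w / 2, cy + h / 2),
            (cx - w / 2, cy + h / 2),
        ]
    )
    if rng is not None and noise > 0:
        base = base + rng.normal(0, noise, base.shape)
    return base


def simulate_arch_detections(cfg: ArchSimConfig) -> ArchScene:
    """Generate (ground_truth, binary, multiclass) detection sets.

    The ground-truth set carries exact contours and FDI labels; the binary
    set is the same teeth with jittered contours, stripped labels and
    detector-like scores; the multiclass set keeps ``label_fraction`` of
    the teeth (centers perturbed by ``center_noise``), with
    ``label_error_rate`` of the surviving labels corrupted to a neighboring
    code. ``truth`` maps binary instance ids to true codes.
    """
    rng = np.random.default_rng(cfg.seed)
    present: list[tuple[Jaw, int]] = []
    for jaw in ("upper", "lower"):
        for slot in range(8 - cfg.teeth_per_quadrant, 8 + cfg.teeth_per_quadrant):
            code = slot_to_fdi(slot, jaw)
            if code not in cfg.missing:
                present.append((jaw, slot))
    if not present:
        raise ValueError("all teeth are missing; nothing to simulate")

    gt_instances, bin_instances, truth = [], [], {}
    mc_candidates = []
    for jaw in ("upper", "lower"):
        slots = [s for j, s in present if j == jaw]
        if not slots:
            continue
        xs, ys = _arch_centers(jaw, slots, rng, cfg.spacing_jitter)
        for slot, x, y in zip(slots, xs, ys):
            code = slot_to_fdi(slot, jaw)
            gt_instances.append(
                ToothInstance(
                    f"gt_{code}",
                    _rect_contour(x, y, _TOOTH_W, _TOOTH_H),
                    label=FDILabel(code),
                )
            )
            bid = f"b_{code}"
            bin_instances.append(
                ToothInstance(
                    bid,
                    _rect_contour(x, y, _TOOTH_W, _TOOTH_H, rng, 1.0),
                    score=float(rng.uniform(0.75, 1.0)),
                )
            )
            truth[bid] = code
            mc_candidates.append((jaw, slot, x, y, code))

    n_keep = int(round(cfg.label_fraction * len(mc_candidates)))
    keep_idx = rng.choice(len(mc_candidates), size=n_keep, replace=False)
    mc_instances = []
    for i in sorted(keep_idx):
        jaw, slot, x, y, code = mc_candidates[i]
        if cfg.label_error_rate > 0 and rng.uniform() < cfg.label_error_rate:
            shift = int(rng.choice([-1, 1]))
            wrong = slot + shift if 0 <= slot + shift <= 15 else slot - shift
            code = slot_to_fdi(wrong, jaw)
        cx = x + rng.normal(0, cfg.center_noise)
        cy = y + rng.normal(0, cfg.center_noise)
        mc_instances.append(
            ToothInstance(
                f"m_{i}",
                _rect_contour(cx, cy, _TOOTH_W, _TOOTH_H),
                score=float(rng.uniform(0.6, 1.0)),
                label=FDILabel(code),
            )
        )

    image_id = f"arch_{cfg.seed}"
    return ArchScene(
        DetectionSet(image_id, IMAGE_SIZE, gt_instances, "ground_truth"),
        DetectionSet(image_id, IMAGE_SIZE, bin_instances, "binary"),
        DetectionSet(image_id, IMAGE_SIZE, mc_instances, "multiclass"),
        truth,
    )


# ---------------------------------------------------------------------------
# single-tooth geometry with analytic ABL
# ---------------------------------------------------------------------------

@dataclass
class ToothSimConfig:
    """Crown-over-tapered-root tooth crossed by a bone contour.

    ``bone_loss_fraction`` f is the exposed fraction of the root: the bone
    line sits at distance (1-f) * root_height from the apex, so the
    analytic loss ratio is d = (crown_height + f*root_height) / total.
    """

    crown_height: float = 25.0
    root_height: float = 50.0
    width: float = 30.0
    bone_loss_fraction: float = 0.2
    jaw: Jaw = "upper"
    shape_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crown_height <= 0 or self.root_height <= 0 or self.width <= 0:
            raise ValueError("tooth dimensions must be positive")
        if not 0 <= self.bone_loss_fraction < 1:
            raise ValueError("bone_loss_fraction must be in [0, 1)")

    @property
    def true_d(self) -> float:
        total = self.crown_height + self.root_height
        return (self.crown_height + self.bone_loss_fraction * self.root_height) / total


def _tooth_contour(cfg: ToothSimConfig, cx: float, apex_y: float, sign: float, rng):
    """Vertex loop for one tooth. ``sign=+1`` grows the tooth downward from
    the apex (upper jaw in image coordinates), ``-1`` upward. The occlusal
    edge and the apex plateau are flat and densely sampled so that subsets
    of vertices still contain the extremal distances."""
    w, ch, rh = cfg.width, cfg.crown_height, cfg.root_height
    H = ch + rh
    cej_y = apex_y + sign * rh
    occ_y = apex_y + sign * H
    pts = []
    # apex plateau, left to right
    for x in np.linspace(-w / 8, w / 8, 5):
        pts.append((cx + x, apex_y))
    # right root taper down to the CEJ
    for f in np.linspace(0, 1, 14)[1:]:
        pts.append((cx + w / 8 + f * (w / 2 - w / 8), apex_y + sign * f * rh))
    # right crown side
    for f in np.linspace(0, 1, 5)[1:-1]:
        pts.append((cx + w / 2, cej_y + sign * f * ch))
    # occlusal edge, right to left
    for x in np.linspace(w / 2, -w / 2, 9):
        pts.append((cx + x, occ_y))
    # left crown side
    for f in np.linspace(1, 0, 5)[1:-1]:
        pts.append((cx - w / 2, cej_y + sign * f * ch))
    # left root taper back toward the apex
    for f in np.linspace(1, 0, 14)[1:-1]:
        pts.append((cx - w / 8 - f * (w / 2 - w / 8), apex_y + sign * f * rh))
    arr = np.array(pts)
    if rng is not None and cfg.shape_noise > 0:
        for _ in range(8):
            jittered = arr + rng.normal(0, cfg.shape_noise, arr.shape)
            from shapely.geometry import Polygon

            if Polygon(jittered).is_simple:
                return jittered
        return arr  # noise too aggressive to stay simple; fall back to clean
    return arr


def simulate_tooth_geometry(
    cfg: ToothSimConfig, center_x: float = 100.0, apex_y: float = 100.0
) -> tuple[ToothInstance, AlveolarContour, float]:
    """One tooth, the bone contour crossing it, and the analytic ratio d."""
    rng = np.random.default_rng(cfg.seed)
    sign = 1.0 if cfg.jaw == "upper" else -1.0
    contour = _tooth_contour(cfg, center_x, apex_y, sign, rng)
    tooth = ToothInstance(f"sim_{cfg.seed}", contour)
    bone_y = apex_y + sign * (1.0 - cfg.bone_loss_fraction) * cfg.root_height
    xs = np.linspace(center_x - 1.5 * cfg.width, center_x + 1.5 * cfg.width, 13)
    bone = AlveolarContour(cfg.jaw, np.column_stack([xs, np.full_like(xs, bone_y)]))
    return tooth, bone, cfg.true_d


# ---------------------------------------------------------------------------
# ratio-vector cohorts
# ---------------------------------------------------------------------------

#: Default grade priors: the 52/189/43/14 class mix of a 298-image clinical
#: cohort (none, mild, moderate, severe).
DEFAULT_PRIORS = (52 / 298, 189 / 298, 43 / 298, 14 / 298)

_BANDS = {
    SeverityGrade.MILD: (0.0, MILD_THRESHOLD),
    SeverityGrade.MODERATE: (MILD_THRESHOLD, SEVERE_THRESHOLD),
    SeverityGrade.SEVERE: (SEVERE_THRESHOLD, 0.9),
}


@dataclass
class CohortSimConfig:
    n: int = 500
    class_priors: tuple[float, float, float, float] = DEFAULT_PRIORS
    noise_sigma: float = 0.02
    missing_rate: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size must be positive")
        if abs(sum(self.class_priors) - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        # the worst tooth must stay strictly inside its band after noise
        if 2 * self.noise_sigma >= (SEVERE_THRESHOLD - MILD_THRESHOLD) / 3:
            raise ValueError("noise_sigma too large to respect the staging bands")


def _band_vector(grade: SeverityGrade, sigma: float, missing_rate: float, rng):
    """One radiograph's measured per-tooth ratios, consistent with ``grade``."""
    from .types import CANONICAL_FDI_ORDER

    codes = list(CANONICAL_FDI_ORDER)
    if grade == SeverityGrade.NONE:
        measured = {c: 0.0 for c in codes}
    else:
        lo, hi = _BANDS[grade]
        delta = 2 * sigma if sigma > 0 else 0.02 * (hi - lo)
        m = rng.uniform(lo + delta, hi - delta)
        measured = {}
        for c in codes:
            v = rng.uniform(0.0, 0.8 * m) + rng.normal(0, sigma)
            measured[c] = float(np.clip(v, 0.0, max(0.0, m - 1e-9)))
        worst = codes[rng.integers(0, 32)]
        measured[worst] = float(m)
    if missing_rate > 0:
        worst_code = max(measured, key=measured.get)
        drop = [
            c
            for c in codes
            if c != worst_code and rng.uniform() < missing_rate
        ]
        if len(drop) == len(codes) - 1 and grade == SeverityGrade.NONE:
            drop = drop[:-1]
        for c in drop:
            del measured[c]
    return measured


def simulate_ratio_cohort(
    cfg: CohortSimConfig,
) -> tuple[list[RatioVector], list[SeverityGrade]]:
    """Cohort of ratio vectors whose rule-based stage equals the drawn grade.

    Per image a grade is drawn from the priors; the worst-tooth ratio is
    drawn inside that grade's threshold band (shrunk by 2 sigma so noise
    cannot cross a boundary), the other teeth below it with Gaussian noise,
    and a ``missing_rate`` fraction of the remaining teeth is dropped and
    left to neighbor-mean imputation.
    """
    rng = np.random.default_rng(cfg.seed)
    grades = [
        SeverityGrade(int(g))
        for g in rng.choice(4, size=cfg.n, p=np.asarray(cfg.class_priors))
    ]
    vectors = []
    for i, g in enumerate(grades):
        measured = _band_vector(g, cfg.noise_sigma, cfg.missing_rate, rng)
        vectors.append(assemble_ratio_vector(measured, image_id=f"cohort_{cfg.seed}_{i}"))
    return vectors, grades


# ---------------------------------------------------------------------------
# full end-to-end scenes
# ---------------------------------------------------------------------------

@dataclass
class FullScene:
    """A complete simulated radiograph: labeled tooth geometries, per-jaw
    alveolar contours, the detector-like inputs, per-tooth analytic loss
    ratios, and the image-level severity grade."""

    image_id: str
    ground_truth: DetectionSet
    binary: DetectionSet
    multiclass: DetectionSet
    bones: list[AlveolarContour]
    true_d: dict[int, float]
    grade: SeverityGrade
    truth: dict[str, int]


#: Loss-positive grade priors for geometric scenes (a zero-loss jaw has no
#: bone crossing inside any tooth contour, so ``none`` is not generable).
SCENE_PRIORS = (0.0, 0.55, 0.28, 0.17)


def simulate_full_scene(
    seed: int,
    grade: Optional[SeverityGrade] = None,
    teeth_per_quadrant: int = 8,
    missing: frozenset[int] = frozenset(),
    label_fraction: float = 0.4,
    spacing_jitter: float = 0.08,
) -> FullScene:
    """Compose an end-to-end scene with known per-tooth loss ratios.

    Each jaw gets a constant root-exposure fraction f (so the alveolar
    polyline is smooth and each tooth's analytic d = (ch + f*rh)/(ch + rh)
    is exact). The image-level grade is *clinical*: the staging thresholds
    applied to the worst tooth's root-exposure fraction — the quantity a
    dentist reads against the cemento-enamel junction — while the geometric
    d vector is what the pipeline measures and the classifier learns from.
    The worst jaw's f is drawn inside the grade's band.
    """
    rng = np.random.default_rng(seed)
    if grade is None:
        grade = SeverityGrade(int(rng.choice(4, p=np.asarray(SCENE_PRIORS))))
    if grade == SeverityGrade.NONE:
        raise ValueError("geometric scenes cannot represent a zero-loss jaw")

    tooth_cfg = ToothSimConfig()
    ch, rh = tooth_cfg.crown_height, tooth_cfg.root_height
    H = ch + rh
    lo, hi = _BANDS[grade]
    hi = min(hi, 0.85)  # keep the bone line clear of the root apex
    f_worst = rng.uniform(lo + 0.01, hi - 0.01)
    worst_jaw = "upper" if rng.uniform() < 0.5 else "lower"
    f_other = rng.uniform(0.3, 0.9) * f_worst
    f_by_jaw = {
        worst_jaw: f_worst,
        ("lower" if worst_jaw == "upper" else "upper"): f_other,
    }

    gt, bins, mcs, truth, true_d, bones = [], [], [], {}, {}, []
    mc_count = 0
    for jaw in ("upper", "lower"):
        slots = [
            s
            for s in range(8 - teeth_per_quadrant, 8 + teeth_per_quadrant)
            if slot_to_fdi(s, jaw) not in missing
        ]
        if not slots:
            continue
        xs, ys = _arch_centers(jaw, slots, rng, spacing_jitter)
        f = f_by_jaw[jaw]
        sign = 1.0 if jaw == "upper" else -1.0
        # bone crest follows the arch smoothly at a constant offset, so the
        # tooth-local reference line is an accurate local tangent
        base_y = _UPPER_Y if jaw == "upper" else _LOWER_Y
        offset = sign * ((1.0 - f) * rh - H / 2)
        bx_grid = np.linspace(xs.min() - tooth_cfg.width, xs.max() + tooth_cfg.width, 80)
        t_grid = (bx_grid - _MIDLINE_X) / (7.5 * _SPACING)
        arch_y = base_y - sign * _CURVE * t_grid * t_grid
        bone_pts = list(zip(bx_grid, arch_y + offset))
        for slot, x, y in zip(slots, xs, ys):
            code = slot_to_fdi(slot, jaw)
            apex_y = y - sign * H / 2
            contour = _tooth_contour(tooth_cfg, x, apex_y, sign, None)
            gt.append(ToothInstance(f"gt_{code}", contour, label=FDILabel(code)))
            bid = f"b_{code}"
            bins.append(
                ToothInstance(bid, contour.copy(), score=float(rng.uniform(0.75, 1.0)))
            )
            truth[bid] = code
            true_d[code] = (ch + f * rh) / H
            if rng.uniform() < label_fraction:
                mcs.append(
                    ToothInstance(
                        f"m_{mc_count}",
                        contour.copy(),
                        score=float(rng.uniform(0.6, 1.0)),
                        label=FDILabel(code),
                    )
                )
                mc_count += 1
        bones.append(AlveolarContour(jaw, np.array(bone_pts)))

    if not mcs:  # guarantee at least one seed label per scene
        t = gt[int(rng.integers(0, len(gt)))]
        mcs.append(ToothInstance("m_0", t.contour.copy(), score=0.9, label=t.label))

    image_id = f"scene_{seed}"
    return FullScene(
        image_id,
        DetectionSet(image_id, IMAGE_SIZE, gt, "ground_truth"),
        DetectionSet(image_id, IMAGE_SIZE, bins, "binary"),
        DetectionSet(image_id, IMAGE_SIZE, mcs, "multiclass"),
        bones,
        true_d,
        grade,
        truth,
    )
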