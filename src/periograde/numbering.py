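"""FDI numbering calibration.

Combines a complete-but-unlabeled detection set (B, from a binary tooth
detector) with a sparse-but-labeled one (M, from a multi-class detector):
labels are transferred from M to the nearest B centers, then propagated to
unlabeled teeth using the ratio of horizontal neighbor distances, and
finally repaired so the numbering is total, injective and consistent with
the FDI order along each arch.

Arch geometry works in *slot* space: slot 0..15 indexes tooth stations left
to right along one jaw (see :func:`periograde.types.fdi_to_slot`). Under the
default orientation the patient's right is on the image left, so the upper
jaw reads 18..11 then 21..28.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import (
    DetectionSet,
    FDILabel,
    Jaw,
    ToothInstance,
    fdi_to_slot,
    slot_to_fdi,
)

log = logging.getLogger(__name__)


@dataclass
class ArchAssignment:
    """Per-instance jaw, quadrant and left-to-right rank along its jaw."""

    jaw: dict[str, Jaw]
    quadrant: dict[str, int]
    arch_order: dict[str, int]

    def jaw_sequence(self, jaw: Jaw) -> list[str]:
        ids = [i for i, j in self.jaw.items() if j == jaw]
        return sorted(ids, key=lambda i: self.arch_order[i])


@dataclass
class NumberingAssignment:
    """Complete instance -> FDI mapping with provenance per instance.

    Provenance: ``transferred`` (seed label kept), ``inferred``
    (neighbor-offset propagation) or ``fallback`` (positional repair).
    """

    labels: dict[str, FDILabel]
    provenance: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Violation:
    kind: str  # duplicate | order | domain
    instance_ids: tuple[str, ...]
    detail: str


def assign_arches(
    dets: DetectionSet,
    midline_x: Optional[float] = None,
    jaw_split_y: Optional[float] = None,
    mirrored: bool = False,
) -> ArchAssignment:
    """Split instances into jaws/quadrants and rank them along each arch.

    Upper jaw: center.y < ``jaw_split_y``. The default split is the
    midpoint of the largest vertical gap between sorted center ys (the
    median misclassifies molars whenever the two jaws have unequal tooth
    counts). Quadrant: from the jaw and the side of ``midline_x`` (default:
    median center x) the center falls on.
    """
    if len(dets) == 0:
        raise ValueError("cannot assign arches for an empty detection set")
    centers = {t.instance_id: t.center for t in dets}
    ys = np.array([c.y for c in centers.values()])
    xs = np.array([c.x for c in centers.values()])
    if jaw_split_y is None:
        ys_sorted = np.sort(ys)
        if len(ys_sorted) > 1:
            gaps = np.diff(ys_sorted)
            k = int(np.argmax(gaps))
            split = float((ys_sorted[k] + ys_sorted[k + 1]) / 2.0)
        else:
            split = float(ys_sorted[0])  # single instance: it reads as lower
    else:
        split = float(jaw_split_y)
    mid = float(np.median(xs)) if midline_x is None else float(midline_x)

    jaw: dict[str, Jaw] = {}
    quadrant: dict[str, int] = {}
    for iid, c in centers.items():
        j: Jaw = "upper" if c.y < split else "lower"
        jaw[iid] = j
        left = c.x < mid
        if j == "upper":
            quadrant[iid] = (2 if left else 1) if mirrored else (1 if left else 2)
        else:
            quadrant[iid] = (3 if left else 4) if mirrored else (4 if left else 3)

    arch_order: dict[str, int] = {}
    for j in ("upper", "lower"):
        ids = [i for i in jaw if jaw[i] == j]
        for rank, iid in enumerate(sorted(ids, key=lambda i: centers[i].x)):
            arch_order[iid] = rank
    return ArchAssignment(jaw, quadrant, arch_order)


def transfer_labels(
    B: DetectionSet, M: DetectionSet, max_dist: Optional[float] = None
) -> DetectionSet:
    """Assign each labeled M instance's FDI code to the nearest B center.

    ``max_dist`` rejects far spurious matches; the default is half the
    median bounding-box width of B. When two M teeth map to the same B
    tooth, the closer M wins; unmatched M labels are dropped with a warning.
    """
    if max_dist is None:
        widths = [t.bbox[2] - t.bbox[0] for t in B]
        max_dist = 0.5 * float(np.median(widths)) if widths else math.inf
    b_ids = [t.instance_id for t in B]
    b_centers = np.array([[t.center.x, t.center.y] for t in B]).reshape(-1, 2)

    best: dict[str, tuple[float, FDILabel]] = {}
    for m in M.labeled():
        if len(b_ids) == 0:
            log.warning("label %s from %s unmatched: B is empty", m.label, M.image_id)
            continue
        deltas = b_centers - np.array([m.center.x, m.center.y])
        dists = np.hypot(deltas[:, 0], deltas[:, 1])
        k = int(np.argmin(dists))
        if dists[k] > max_dist:
            log.warning(
                "label %s at (%.0f, %.0f) unmatched: nearest B center %.1f px away "
                "(max %.1f)", m.label, m.center.x, m.center.y, dists[k], max_dist,
            )
            continue
        bid = b_ids[k]
        if bid not in best or dists[k] < best[bid][0]:
            best[bid] = (float(dists[k]), m.label)

    out = [
        t.with_label(best[t.instance_id][1]) if t.instance_id in best else t.with_label(None)
        for t in B
    ]
    return DetectionSet(B.image_id, B.image_size, out, B.source)


def infer_offset(D_r: float, D_rr: float) -> int:
    """Number of tooth stations spanned by the gap ``D_r``.

    ``D_rr`` is the reference single-tooth spacing; the ratio is rounded
    half-up and clamped to a minimum of 1 (a detected neighbor is at least
    one station away).
    """
    if D_rr <= 0:
        raise ValueError(f"reference spacing must be positive, got {D_rr}")
    return max(1, math.floor(D_r / D_rr + 0.5))


def _unit_spacing(xs: np.ndarray) -> Optional[float]:
    """Single-tooth spacing estimate from adjacent-center gaps.

    Missing teeth inflate some gaps to ~2x or 3x the true spacing, so the
    plain median is unreliable on short jaws. The smallest gap is (almost
    surely) a true-adjacent pair; averaging the cluster of gaps within
    1.4x of it rejects every gap that spans a missing tooth.
    """
    if len(xs) < 2:
        return None
    gaps = np.diff(np.sort(xs))
    g0 = float(gaps.min())
    if g0 <= 0:
        g0 = float(gaps[gaps > 0].min()) if np.any(gaps > 0) else 1.0
    cluster = gaps[gaps <= 1.4 * g0]
    return float(cluster.mean()) if cluster.size else g0


def _reference_spacing(
    xs: np.ndarray,
    slots: dict[int, int],
    jn: int,
    away: int,
    unit: Optional[float],
) -> float:
    """D_rr for propagating from labeled neighbor ``jn``: the distance from
    the neighbor to *its* next neighbor on the side away from the tooth
    being labeled, normalized by their slot difference when both are
    labeled, and replaced by the jaw unit spacing when absent or when it is
    inconsistent with the unit (it then almost certainly spans a gap)."""
    k = jn + away
    if 0 <= k < len(xs):
        d = abs(float(xs[k] - xs[jn]))
        if k in slots and jn in slots and slots[k] != slots[jn]:
            return d / abs(slots[k] - slots[jn])
        if unit is None or 0.75 * unit <= d <= 1.35 * unit:
            return d
    if unit is not None:
        return unit
    # single isolated pair with nothing else to go on
    return abs(float(xs[min(k, len(xs) - 1)] - xs[jn])) or 1.0


def _dp_repair(
    n_teeth: int,
    proposals: dict[int, int],
    weights: dict[int, float],
) -> list[int]:
    """Minimum-weight repair: strictly increasing slots s_0 < ... < s_{n-1}
    in 0..15 that disagree with the proposals as little as possible.

    Cost of tooth i at slot s: weights[i] if s != proposals[i] (0 if i has
    no proposal), plus a small |s - proposal| term so that among equal-cost
    repairs the nearest slots win, and an epsilon favoring low slots for
    determinism."""
    S = 16
    if n_teeth > S:
        raise ValueError(f"jaw has {n_teeth} teeth but only {S} FDI stations")
    INF = float("inf")
    cost = np.zeros((n_teeth, S))
    for i in range(n_teeth):
        for s in range(S):
            c = 1e-6 * s
            if i in proposals:
                if s != proposals[i]:
                    c += weights.get(i, 1.0) + 1e-3 * abs(s - proposals[i])
            cost[i, s] = c
    f = np.full((n_teeth, S), INF)
    arg = np.zeros((n_teeth, S), dtype=int)
    f[0] = cost[0]
    for i in range(1, n_teeth):
        # prefix minimum of f[i-1] over slots < s
        best, best_s = INF, -1
        for s in range(S):
            if s > 0 and f[i - 1, s - 1] < best:
                best, best_s = f[i - 1, s - 1], s - 1
            if best < INF:
                f[i, s] = cost[i, s] + best
                arg[i, s] = best_s
    s = int(np.argmin(f[-1]))
    out = [s]
    for i in range(n_teeth - 1, 0, -1):
        s = int(arg[i, s])
        out.append(s)
    return out[::-1]


def calibrate_numbering(
    partial: DetectionSet,
    arches: ArchAssignment,
    mirrored: bool = False,
) -> NumberingAssignment:
    """Produce a complete, unique, order-consistent FDI numbering.

    Three phases per jaw, following the iterate-until-consistent scheme:

    1. *Seeds*: transferred labels become fixed slot proposals (duplicate
       codes keep the higher-score instance).
    2. *Propagation sweeps*: each unlabeled tooth with a labeled neighbor
       receives ``slot_neighbor +/- infer_offset(D_r, D_rr)`` where D_r is
       the horizontal center distance to that neighbor and D_rr the
       reference spacing beyond it; with both neighbors labeled the nearer
       one (ties: the mesial one) is used. Sweeps repeat until a pass
       changes nothing.
    3. *Repair*: teeth that are still unproposed get positional proposals
       from the jaw's unit spacing, then a dynamic program finds the
       strictly increasing slot assignment minimizing weighted disagreement
       with all proposals — this guarantees totality, injectivity and FDI
       order, changing seeds only when they violate those rules.
    """
    labels: dict[str, FDILabel] = {}
    provenance: dict[str, str] = {}
    by_id = {t.instance_id: t for t in partial}

    for jaw in ("upper", "lower"):
        ids = arches.jaw_sequence(jaw)
        if not ids:
            continue
        xs = np.array([by_id[i].center.x for i in ids])
        n = len(ids)
        unit = _unit_spacing(xs)

        # --- phase 1: seeds -------------------------------------------------
        slots: dict[int, int] = {}
        seed_slot: dict[int, int] = {}
        for i, iid in enumerate(ids):
            lab = by_id[iid].label
            if lab is None:
                continue
            if lab.jaw != jaw:
                log.warning("seed %s on %s ignored: wrong jaw", lab, iid)
                continue
            s = fdi_to_slot(lab.code, mirrored)
            clash = next((k for k, v in seed_slot.items() if v == s), None)
            if clash is not None:
                if by_id[iid].score <= by_id[ids[clash]].score:
                    log.warning("duplicate seed %s on %s dropped", lab, iid)
                    continue
                log.warning("duplicate seed %s on %s dropped", lab, ids[clash])
                del seed_slot[clash], slots[clash]
            seed_slot[i] = s
            slots[i] = s

        # --- phase 2: propagation sweeps ------------------------------------
        for _ in range(max(1, n)):
            changed = False
            for i in range(n):
                if i in slots:
                    continue
                nbrs = [j for j in (i - 1, i + 1) if 0 <= j < n and j in slots]
                if not nbrs:
                    continue
                if len(nbrs) == 2:
                    # nearer neighbor; tie-break toward the midline (mesial)
                    jn = min(
                        nbrs,
                        key=lambda j: (abs(xs[j] - xs[i]), abs(slots[j] - 7.5)),
                    )
                else:
                    jn = nbrs[0]
                away = 1 if jn > i else -1  # direction from tooth i past jn
                D_r = abs(float(xs[jn] - xs[i]))
                D_rr = _reference_spacing(xs, slots, jn, away, unit)
                off = infer_offset(D_r, D_rr)
                s = slots[jn] + (off if i > jn else -off)
                if not 0 <= s <= 15:
                    log.warning(
                        "inferred slot %d for tooth %s past the arch end; "
                        "deferring to positional fallback", s, ids[i],
                    )
                    continue
                slots[i] = s
                changed = True
            if not changed:
                break
        inferred = {i: s for i, s in slots.items() if i not in seed_slot}

        # --- phase 3: positional fallback + repair --------------------------
        proposals = dict(slots)
        if proposals:
            for i in range(n):
                if i in proposals:
                    continue
                jn = min(proposals, key=lambda j: abs(j - i))
                step = unit if unit else 1.0
                off = max(
                    abs(i - jn), infer_offset(abs(float(xs[i] - xs[jn])), step)
                )
                proposals[i] = proposals[jn] + (off if i > jn else -off)
        else:
            # jaw with zero seeds: relative positional numbering, centered
            rel = [0]
            for i in range(1, n):
                step = unit if unit else 1.0
                rel.append(rel[-1] + infer_offset(float(xs[i] - xs[i - 1]), step))
            shift = max(0, min(15 - rel[-1], round((15 - rel[-1]) / 2)))
            proposals = {i: r + shift for i, r in enumerate(rel)}
        proposals = {i: min(15, max(0, s)) for i, s in proposals.items()}

        weights = {
            i: (2.0 + by_id[ids[i]].score if i in seed_slot else 1.0)
            for i in range(n)
        }
        final = _dp_repair(n, proposals, weights)

        for i, s in enumerate(final):
            labels[ids[i]] = FDILabel(slot_to_fdi(s, jaw, mirrored))
            if i in seed_slot and s == seed_slot[i]:
                provenance[ids[i]] = "transferred"
            elif i in inferred and s == inferred[i]:
                provenance[ids[i]] = "inferred"
            else:
                provenance[ids[i]] = "fallback"

    return NumberingAssignment(labels, provenance)


def validate_fdi(
    assignment: NumberingAssignment,
    arches: ArchAssignment,
    mirrored: bool = False,
) -> list[Violation]:
    """Check totality is the caller's concern; this reports duplicates,
    out-of-domain codes, and adjacent pairs whose FDI order contradicts the
    left-to-right arch order. Empty result == valid assignment."""
    violations: list[Violation] = []
    seen: dict[int, str] = {}
    for iid, lab in assignment.labels.items():
        if lab.code not in {c for c in range(11, 49)} or lab.code % 10 in (0, 9):
            violations.append(Violation("domain", (iid,), f"code {lab.code}"))
        if lab.code in seen:
            violations.append(
                Violation("duplicate", (seen[lab.code], iid), f"code {lab.code}")
            )
        else:
            seen[lab.code] = iid
    for jaw in ("upper", "lower"):
        seq = [i for i in arches.jaw_sequence(jaw) if i in assignment.labels]
        for a, b in zip(seq, seq[1:]):
            sa = fdi_to_slot(assignment.labels[a].code, mirrored)
            sb = fdi_to_slot(assignment.labels[b].code, mirrored)
            if sa >= sb:
                violations.append(
                    Violation(
                        "order",
                        (a, b),
                        f"{assignment.labels[a]} !< {assignment.labels[b]} along {jaw} arch",
                    )
                )
    return violations
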