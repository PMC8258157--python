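import itertools

import numpy as np
import pytest

from periograde.numbering import (
    NumberingAssignment,
    assign_arches,
    calibrate_numbering,
    infer_offset,
    transfer_labels,
    validate_fdi,
)
from periograde.types import DetectionSet, FDILabel, fdi_to_slot, slot_to_fdi

from conftest import rect_tooth


class TestAssignArches:
    def test_two_separated_rows(self, two_row_scene):
        ar = assign_arches(two_row_scene)
        for i in range(16):
            assert ar.jaw[f"u{i}"] == "upper"
            assert ar.jaw[f"l{i}"] == "lower"
            assert ar.arch_order[f"u{i}"] == i

    def test_single_instance_explicit_split(self):
        ds = DetectionSet("s", (200, 200), [rect_tooth("a", 60, 40)], "binary")
        ar = assign_arches(ds, midline_x=100, jaw_split_y=100)
        assert ar.jaw["a"] == "upper"
        assert ar.quadrant["a"] == 1  # image-left, default orientation

    def test_unbalanced_jaws_split_correctly(self):
        # 14 upper vs 6 lower: the median center-y lies inside the upper
        # cluster, the largest-gap split does not
        teeth = [rect_tooth(f"u{i}", 50 + 50 * i, 100 + 3 * i) for i in range(14)]
        teeth += [rect_tooth(f"l{i}", 200 + 50 * i, 400) for i in range(6)]
        ar = assign_arches(DetectionSet("u", (1024, 512), teeth, "binary"))
        assert all(ar.jaw[f"u{i}"] == "upper" for i in range(14))
        assert all(ar.jaw[f"l{i}"] == "lower" for i in range(6))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            assign_arches(DetectionSet("e", (10, 10), [], "binary"))


class TestTransferLabels:
    def test_nearest_center_receives_label(self):
        B = DetectionSet(
            "b", (1000, 1000), [rect_tooth("p", 98, 52), rect_tooth("q", 150, 50)], "binary"
        )
        M = DetectionSet(
            "m", (1000, 1000), [rect_tooth("m1", 100, 50, label=16)], "multiclass"
        )
        out = transfer_labels(B, M)
        assert out.get("p").label == FDILabel(16)
        assert out.get("q").label is None

    def test_empty_m_leaves_b_unlabeled(self):
        B = DetectionSet("b", (100, 100), [rect_tooth("p", 50, 50)], "binary")
        M = DetectionSet("m", (100, 100), [], "multiclass")
        assert all(t.label is None for t in transfer_labels(B, M))

    def test_matches_brute_force_nearest_assignment(self, rng):
        from periograde.types import CANONICAL_FDI_ORDER

        codes = rng.choice(CANONICAL_FDI_ORDER, size=10, replace=False)
        B = DetectionSet(
            "b",
            (2000, 2000),
            [rect_tooth(f"b{i}", x, y) for i, (x, y) in enumerate(
                rng.uniform(100, 1900, (14, 2)))],
            "binary",
        )
        M = DetectionSet(
            "m",
            (2000, 2000),
            [rect_tooth(f"m{i}", x, y, label=int(codes[i])) for i, (x, y) in
             enumerate(rng.uniform(100, 1900, (10, 2)))],
            "multiclass",
        )
        out = transfer_labels(B, M, max_dist=np.inf)
        # brute force: each M labels its nearest B; per B keep the closest M
        expect = {}
        for m in M:
            dists = {b.instance_id: np.hypot(b.center.x - m.center.x,
                                             b.center.y - m.center.y) for b in B}
            bid = min(dists, key=dists.get)
            if bid not in expect or dists[bid] < expect[bid][0]:
                expect[bid] = (dists[bid], m.label)
        for t in out:
            want = expect.get(t.instance_id)
            assert t.label == (want[1] if want else None)

    def test_far_label_rejected_by_max_dist(self):
        B = DetectionSet("b", (1000, 1000), [rect_tooth("p", 100, 100)], "binary")
        M = DetectionSet(
            "m", (1000, 1000), [rect_tooth("m1", 800, 800, label=25)], "multiclass"
        )
        out = transfer_labels(B, M)  # default radius: half median bbox width
        assert out.get("p").label is None


class TestInferOffset:
    @pytest.mark.parametrize(
        "d_r,d_rr,expected",
        [(40, 38, 1), (80, 40, 2), (10, 40, 1), (60, 40, 2), (59, 40, 1)],
    )
    def test_rounded_ratio(self, d_r, d_rr, expected):
        assert infer_offset(d_r, d_rr) == expected

    def test_half_up_rounding(self):
        assert infer_offset(100, 40) == 3  # 2.5 rounds up

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            infer_offset(10, 0)


def _jaw_scene(xs, seed_codes, jaw="upper", y=100.0):
    """One-jaw scene; seed_codes maps index -> FDI code (None = unlabeled)."""
    teeth = [
        rect_tooth(f"t{i}", x, y, label=seed_codes.get(i)) for i, x in enumerate(xs)
    ]
    ds = DetectionSet("jaw", (4096, 1024), teeth, "binary")
    ar = assign_arches(ds, midline_x=-1e9, jaw_split_y=y + 100 if jaw == "upper" else y - 100)
    return ds, ar


class TestCalibrateNumbering:
    def test_fully_labeled_consistent_is_fixed_point(self):
        codes = [18, 17, 16, 15, 14, 13, 12, 11, 21, 22, 23, 24, 25, 26, 27, 28]
        teeth = [rect_tooth(f"u{i}", 100 + 50 * i, 100, label=c) for i, c in enumerate(codes)]
        codes_l = [48, 47, 46, 45, 44, 43, 42, 41, 31, 32, 33, 34, 35, 36, 37, 38]
        teeth += [rect_tooth(f"l{i}", 100 + 50 * i, 500, label=c) for i, c in enumerate(codes_l)]
        ds = DetectionSet("full", (1200, 1024), teeth, "binary")
        ar = assign_arches(ds)
        na = calibrate_numbering(ds, ar)
        for t in ds:
            assert na.labels[t.instance_id] == t.label
            assert na.provenance[t.instance_id] == "transferred"

    def test_double_gap_skips_a_code(self):
        # uniform spacing 50 with one double gap: positions 1,2,3,5
        ds, ar = _jaw_scene([0, 50, 100, 200], {0: 21})
        na = calibrate_numbering(ds, ar)
        assert [na.labels[f"t{i}"].code for i in range(4)] == [21, 22, 23, 25]

    def test_single_end_seed_labels_whole_arch(self):
        ds, ar = _jaw_scene([100 + 50 * i for i in range(14)], {0: 18})
        na = calibrate_numbering(ds, ar)
        expected = [slot_to_fdi(s, "upper") for s in range(14)]
        assert [na.labels[f"t{i}"].code for i in range(14)] == expected

    def test_output_always_validates(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 15))
            xs = np.sort(rng.uniform(0, 1000, n))
            n_seed = int(rng.integers(0, min(n, 3) + 1))
            seed_idx = rng.choice(n, size=n_seed, replace=False)
            seeds = {
                int(i): int(rng.choice([c for c in range(21, 29)]))
                for i in seed_idx
            }
            ds, ar = _jaw_scene(list(xs), seeds)
            na = calibrate_numbering(ds, ar)
            assert len(na.labels) == n  # total
            assert validate_fdi(na, ar) == []

    def test_duplicate_seeds_resolved_by_score(self):
        teeth = [
            rect_tooth("a", 100, 100, label=24, score=0.9),
            rect_tooth("b", 150, 100, label=24, score=0.5),
            rect_tooth("c", 200, 100),
        ]
        ds = DetectionSet("dup", (1024, 1024), teeth, "binary")
        ar = assign_arches(ds, midline_x=0, jaw_split_y=500)
        na = calibrate_numbering(ds, ar)
        assert na.labels["a"].code == 24
        assert validate_fdi(na, ar) == []

    def test_recalibration_is_idempotent(self, rng):
        ds, ar = _jaw_scene([100 + 52 * i for i in range(10)], {3: 24})
        na1 = calibrate_numbering(ds, ar)
        relabeled = DetectionSet(
            ds.image_id,
            ds.image_size,
            [t.with_label(na1.labels[t.instance_id]) for t in ds],
            ds.source,
        )
        na2 = calibrate_numbering(relabeled, ar)
        assert na1.labels == na2.labels


class TestValidateFdi:
    def test_valid_assignment_empty(self):
        ds, ar = _jaw_scene([0, 50, 100], {0: 21})
        na = calibrate_numbering(ds, ar)
        assert validate_fdi(na, ar) == []

    def test_duplicate_label_reported(self):
        ds, ar = _jaw_scene([0, 50], {})
        na = NumberingAssignment({"t0": FDILabel(24), "t1": FDILabel(24)})
        kinds = [v.kind for v in validate_fdi(na, ar)]
        assert kinds.count("duplicate") == 1

    def test_order_violation_reported(self):
        # arch order t0 < t1 < t2 but codes 16, 15, 17 break monotone slots
        ds, ar = _jaw_scene([0, 50, 100], {})
        na = NumberingAssignment(
            {"t0": FDILabel(16), "t1": FDILabel(15), "t2": FDILabel(17)}
        )
        viol = validate_fdi(na, ar)
        assert sum(v.kind == "order" for v in viol) == 1


def exhaustive_oracle(xs, seed_slots, n_slots=16):
    """Minimum-total-gap-displacement order-preserving labeling by search.

    Scores a candidate slot tuple by how far each adjacent center gap is
    from the implied whole-tooth multiple of the jaw's unit spacing, the
    unit being the mean of the cluster of near-minimal gaps.
    """
    xs = np.asarray(xs, dtype=float)
    k = len(xs)
    gaps = np.diff(xs)
    g0 = gaps.min()
    unit = gaps[gaps <= 1.4 * g0].mean()
    best, best_s = np.inf, None
    for combo in itertools.combinations(range(n_slots), k):
        if any(combo[i] != s for i, s in seed_slots.items()):
            continue
        score = sum(
            abs(gaps[i] - (combo[i + 1] - combo[i]) * unit) for i in range(k - 1)
        )
        if score < best - 1e-12:
            best, best_s = score, combo
    return best_s


class TestOracleEquivalence:
    def test_matches_exhaustive_search_on_random_jaws(self, rng):
        for _ in range(60):
            miss = set()
            for base in (4, 8):
                for s in rng.choice(range(base, base + 4), size=rng.integers(0, 3),
                                    replace=False):
                    miss.add(int(s))
            slots = [s for s in range(4, 12) if s not in miss]
            if len(slots) < 2 or not any(b - a == 1 for a, b in zip(slots, slots[1:])):
                continue
            xs = [100 + s * 50 + rng.uniform(-2.5, 2.5) for s in slots]
            seed_pos = rng.choice(len(slots), size=int(rng.integers(1, 4)), replace=False)
            seeds = {int(i): slot_to_fdi(slots[i], "upper") for i in set(seed_pos)}
            ds, ar = _jaw_scene(xs, seeds)
            na = calibrate_numbering(ds, ar)
            got = tuple(fdi_to_slot(na.labels[f"t{i}"].code) for i in range(len(xs)))
            expected = exhaustive_oracle(xs, {i: slots[i] for i in set(seed_pos)})
            assert got == expected
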