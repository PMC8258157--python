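import numpy as np
import pytest

from periograde.grading import (
    _LOWER_CHAIN,
    _UPPER_CHAIN,
    assemble_ratio_vector,
    fit_severity_model,
    predict_severity,
    smote_oversample,
    stage_rule_based,
)
from periograde.types import (
    CANONICAL_FDI_ORDER,
    RatioVector,
    SeverityGrade,
    fdi_index,
)


def make_vector(max_value, imputed_slots=()):
    values = np.zeros(32)
    values[5] = max_value
    imputed = np.zeros(32, bool)
    for s in imputed_slots:
        imputed[s] = True
    return RatioVector(values, imputed)


class TestAssembleRatioVector:
    def test_two_neighbor_mean(self):
        v = assemble_ratio_vector({15: 0.2, 17: 0.4})
        assert v.values[fdi_index(16)] == pytest.approx(0.3)
        assert v.imputed[fdi_index(16)]
        assert not v.imputed[fdi_index(15)]

    def test_all_present_identity(self):
        measured = {c: 0.01 * (i + 1) for i, c in enumerate(CANONICAL_FDI_ORDER)}
        v = assemble_ratio_vector(measured)
        assert not v.imputed.any()
        for i, c in enumerate(CANONICAL_FDI_ORDER):
            assert v.values[fdi_index(c)] == measured[c]

    def test_empty_jaw_borrows_other_jaw_mean(self):
        v = assemble_ratio_vector({11: 0.2, 16: 0.4})
        for c in (31, 38, 45):
            assert v.values[fdi_index(c)] == pytest.approx(0.3)
            assert v.imputed[fdi_index(c)]

    def test_zero_measurements_rejected(self):
        with pytest.raises(ValueError):
            assemble_ratio_vector({})

    def test_random_patterns_match_bruteforce_neighbor_oracle(self, rng):
        for _ in range(30):
            n_present = int(rng.integers(1, 32))
            codes = rng.choice(CANONICAL_FDI_ORDER, size=n_present, replace=False)
            measured = {int(c): float(rng.uniform(0, 0.8)) for c in codes}
            v = assemble_ratio_vector(measured)
            for chain in (_UPPER_CHAIN, _LOWER_CHAIN):
                present = [p for p, idx in enumerate(chain)
                           if CANONICAL_FDI_ORDER[idx] in measured]
                for p, idx in enumerate(chain):
                    code = CANONICAL_FDI_ORDER[idx]
                    if code in measured:
                        assert v.values[idx] == measured[code]
                        continue
                    if not present:
                        expected = np.mean(list(measured.values()))
                    else:
                        nbrs = []
                        left = [q for q in present if q < p]
                        right = [q for q in present if q > p]
                        if left:
                            nbrs.append(measured[CANONICAL_FDI_ORDER[chain[max(left)]]])
                        if right:
                            nbrs.append(measured[CANONICAL_FDI_ORDER[chain[min(right)]]])
                        expected = np.mean(nbrs)
                    assert v.values[idx] == pytest.approx(expected)
                    assert v.imputed[idx]

    def test_imputation_never_alters_measured_values(self, rng):
        measured = {11: 0.1, 24: 0.5, 38: 0.25}
        v = assemble_ratio_vector(measured)
        for c, val in measured.items():
            assert v.values[fdi_index(c)] == val


class TestRuleStager:
    @pytest.mark.parametrize(
        "max_value,expected",
        [
            (0.0, SeverityGrade.NONE),
            (0.10, SeverityGrade.MILD),
            (0.20, SeverityGrade.MODERATE),
            (0.40, SeverityGrade.SEVERE),
            (0.149999, SeverityGrade.MILD),
            (0.15, SeverityGrade.MODERATE),  # boundary -> higher grade
            (0.33, SeverityGrade.SEVERE),
        ],
    )
    def test_threshold_bands(self, max_value, expected):
        assert stage_rule_based(make_vector(max_value)) == expected

    def test_imputed_values_excluded_from_max(self):
        values = np.zeros(32)
        values[0], values[5] = 0.1, 0.5
        imputed = np.zeros(32, bool)
        imputed[5] = True
        assert stage_rule_based(RatioVector(values, imputed)) == SeverityGrade.MILD

    def test_monotone_in_every_coordinate(self, rng):
        for _ in range(30):
            values = rng.uniform(0, 0.5, 32)
            v = RatioVector(values.copy(), np.zeros(32, bool))
            g0 = stage_rule_based(v)
            i = int(rng.integers(0, 32))
            values[i] = min(0.95, values[i] + rng.uniform(0, 0.4))
            assert stage_rule_based(RatioVector(values, np.zeros(32, bool))) >= g0


class TestSmote:
    def test_counts_balanced(self, rng):
        X = rng.uniform(0, 1, (12, 4))
        y = np.array([0] * 10 + [1] * 2)
        with pytest.warns(UserWarning):
            X2, y2 = smote_oversample(X, y, seed=0)
        assert np.bincount(y2).tolist() == [10, 10]
        assert np.array_equal(X2[:12], X)  # originals untouched, first

    def test_two_point_minority_synthetics_on_segment(self, rng):
        X = np.vstack([rng.uniform(0, 1, (8, 3)), [[0, 0, 0], [1, 2, 3]]])
        y = np.array([0] * 8 + [1] * 2)
        with pytest.warns(UserWarning):
            X2, y2 = smote_oversample(X, y, k=5, seed=1)
        synth = X2[10:][y2[10:] == 1]
        p, q = np.zeros(3), np.array([1.0, 2.0, 3.0])
        for s in synth:
            t = s[2] / 3.0  # parameter along the segment
            assert np.allclose(s, p + t * (q - p))
            assert 0.0 <= t <= 1.0

    def test_synthetics_bracketed_by_parents(self, rng):
        X = rng.uniform(0, 1, (40, 32))
        y = np.array([0] * 25 + [1] * 15)
        X2, y2 = smote_oversample(X, y, seed=3)
        minority = X[y == 1]
        for s in X2[40:]:
            # bracketing: within the min/max envelope of the minority class
            assert np.all(s >= minority.min(axis=0) - 1e-12)
            assert np.all(s <= minority.max(axis=0) + 1e-12)

    def test_singleton_class_rejected(self, rng):
        X = rng.uniform(0, 1, (5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="1"):
            smote_oversample(X, y)

    def test_deterministic_per_seed(self, rng):
        X = rng.uniform(0, 1, (20, 5))
        y = np.array([0] * 15 + [1] * 5)
        a = smote_oversample(X, y, seed=9)
        b = smote_oversample(X, y, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def _threshold_cohort(rng, n):
    """Vectors whose grade is exactly the rule stager of max(v)."""
    X, y = [], []
    for _ in range(n):
        g = int(rng.integers(0, 4))
        values = np.zeros(32)
        if g > 0:
            lo, hi = [(0.002, 0.14), (0.16, 0.32), (0.34, 0.85)][g - 1]
            m = rng.uniform(lo, hi)
            values = rng.uniform(0, 0.8 * m, 32)
            values[rng.integers(0, 32)] = m
        X.append(values)
        y.append(g)
    return np.array(X), np.array(y)


class TestSeverityModel:
    def test_learns_rule_stager_generative_oracle(self, rng):
        X, y = _threshold_cohort(rng, 500)
        model = fit_severity_model(X[:400], y[:400], seed=0)
        acc = (model.predict(X[400:]) == y[400:]).mean()
        assert acc >= 0.95

    def test_predicts_duplicated_sample_class(self):
        X = np.vstack([np.full((5, 32), 0.1), np.full((5, 32), 0.6)])
        y = np.array([1] * 5 + [3] * 5)
        model = fit_severity_model(X, y, seed=0)
        grade, _ = predict_severity(model, np.full(32, 0.6))
        assert grade == SeverityGrade.SEVERE

    def test_same_seed_identical_predictions(self, rng):
        X, y = _threshold_cohort(rng, 200)
        Xt = rng.uniform(0, 0.5, (40, 32))
        p1 = fit_severity_model(X, y, seed=5).predict(Xt)
        p2 = fit_severity_model(X, y, seed=5).predict(Xt)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        X = np.zeros((10, 32))
        y = np.ones(10, dtype=int)
        with pytest.raises(ValueError):
            fit_severity_model(X, y)

    def test_probability_simplex_and_argmax(self, rng):
        X, y = _threshold_cohort(rng, 200)
        model = fit_severity_model(X, y, seed=0)
        for _ in range(10):
            grade, probs = predict_severity(model, rng.uniform(0, 0.8, 32))
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert int(grade) == int(np.argmax(probs))

    def test_unfitted_model_rejected(self):
        from periograde.grading import SeverityModel

        with pytest.raises(ValueError):
            predict_severity(SeverityModel(), np.zeros(32))

    def test_save_load_roundtrip(self, tmp_path, rng):
        X, y = _threshold_cohort(rng, 200)
        model = fit_severity_model(X, y, seed=0)
        model.save(tmp_path / "model.ubj")
        from periograde.grading import SeverityModel

        loaded = SeverityModel.load(tmp_path / "model.ubj")
        Xt = rng.uniform(0, 0.5, (20, 32))
        assert np.array_equal(model.predict(Xt), loaded.predict(Xt))
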