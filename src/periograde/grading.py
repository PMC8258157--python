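"""4-class periodontitis severity from the 32-tooth ABL ratio vector.

Staging thresholds (worst tooth): no loss -> none; below 15% -> mild;
15-33% -> moderate; 33% and above -> severe. Boundary values go to the
higher grade. A gradient-boosted classifier trained on ratio vectors is the
learned counterpart of the rule-based stager; class imbalance in training
data is handled by SMOTE oversampling of the minority grades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors
from xgboost import XGBClassifier

from .types import (
    CANONICAL_FDI_ORDER,
    FDILabel,
    RatioVector,
    SeverityGrade,
    fdi_index,
    fdi_to_slot,
)

MILD_THRESHOLD = 0.15
SEVERE_THRESHOLD = 0.33

# Arch neighbor structure of the 32 canonical slots: each jaw is one chain
# of 16 stations ordered left to right in the image.
_UPPER_CHAIN = [
    fdi_index(c)
    for c in sorted((c for c in CANONICAL_FDI_ORDER if c < 30), key=fdi_to_slot)
]
_LOWER_CHAIN = [
    fdi_index(c)
    for c in sorted((c for c in CANONICAL_FDI_ORDER if c > 30), key=fdi_to_slot)
]


def assemble_ratio_vector(
    measurements: Mapping, image_id: str = ""
) -> RatioVector:
    """Build the 32-slot feature vector D from per-tooth ratios.

    ``measurements`` maps FDI codes (or FDILabel) to measured d values.
    Each absent tooth is imputed with the mean of its nearest *measured*
    neighbor on each side along the same jaw's arch (one-sided at arch
    ends); a jaw with no measured teeth borrows the other jaw's mean.
    """
    d: dict[int, float] = {}
    for key, val in measurements.items():
        code = key.code if isinstance(key, FDILabel) else int(key)
        d[fdi_index(code)] = float(val)
    if not d:
        raise ValueError("cannot assemble a ratio vector with zero measured teeth")

    values = np.zeros(32)
    imputed = np.ones(32, dtype=bool)
    for idx, val in d.items():
        values[idx] = val
        imputed[idx] = False

    all_measured = np.array(sorted(d))
    for chain in (_UPPER_CHAIN, _LOWER_CHAIN):
        present = [p for p, idx in enumerate(chain) if idx in d]
        for p, idx in enumerate(chain):
            if idx in d:
                continue
            if present:
                left = [q for q in present if q < p]
                right = [q for q in present if q > p]
                nbrs = []
                if left:
                    nbrs.append(d[chain[max(left)]])
                if right:
                    nbrs.append(d[chain[min(right)]])
                values[idx] = float(np.mean(nbrs))
            else:
                values[idx] = float(np.mean([d[i] for i in all_measured]))
    return RatioVector(values=values, imputed=imputed, image_id=image_id)


def stage_rule_based(v: RatioVector) -> SeverityGrade:
    """Grade from the worst measured tooth (imputed slots are neighborhood
    means, not observations, and are excluded)."""
    m = v.measured_max()
    if m == 0.0:
        return SeverityGrade.NONE
    if m < MILD_THRESHOLD:
        return SeverityGrade.MILD
    if m < SEVERE_THRESHOLD:
        return SeverityGrade.MODERATE
    return SeverityGrade.SEVERE


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance class counts by synthetic minority oversampling.

    Each synthetic sample is x + u * (x_nn - x) with u ~ U(0, 1), where
    x_nn is one of the k nearest same-class neighbors of a minority sample
    x; every class is brought up to the majority count. k is lowered (with
    a warning) for classes smaller than k + 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    out_X, out_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = int(target - cnt)
        if need == 0:
            continue
        if cnt < 2:
            raise ValueError(
                f"class {cls!r} has a single sample; SMOTE needs >= 2 to interpolate"
            )
        Xc = X[y == cls]
        k_eff = min(k, cnt - 1)
        if k_eff < k:
            import warnings

            warnings.warn(
                f"class {cls!r} has {cnt} samples; lowering SMOTE k to {k_eff}",
                stacklevel=2,
            )
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # column 0 is the point itself
        base = rng.integers(0, cnt, size=need)
        pick = rng.integers(1, k_eff + 1, size=need)
        u = rng.uniform(0.0, 1.0, size=need)
        parents = Xc[base]
        partners = Xc[idx[base, pick]]
        out_X.append(parents + u[:, None] * (partners - parents))
        out_y.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(out_X), np.concatenate(out_y)


@dataclass
class SeverityModel:
    """Gradient-boosted 4-class severity classifier with its training seed.

    ``booster`` holds either the fitted sklearn-style classifier or, after
    :meth:`load`, the native booster; prediction goes through the native
    booster in both cases.
    """

    booster: Optional[object] = None
    classes_: Sequence[int] = field(default_factory=list)
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    @property
    def fitted(self) -> bool:
        return self.booster is not None

    def _raw_booster(self):
        import xgboost as xgb

        return (
            self.booster
            if isinstance(self.booster, xgb.Booster)
            else self.booster.get_booster()
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-sample probabilities over self.classes_ (rows sum to 1)."""
        if not self.fitted:
            raise ValueError("severity model is not fitted")
        raw = self._raw_booster().inplace_predict(np.asarray(X, dtype=float))
        if raw.ndim == 1:  # binary objective emits p(class 1) only
            raw = np.column_stack([1.0 - raw, raw])
        raw = raw.astype(float)
        return raw / raw.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted grades (as ints) for a feature matrix."""
        enc = np.argmax(self.predict_proba(X), axis=1)
        return np.asarray([int(self.classes_[int(e)]) for e in enc])

    def save(self, path) -> None:
        """Native booster file plus a JSON sidecar with the class order."""
        if not self.fitted:
            raise ValueError("cannot save an unfitted model")
        self._raw_booster().save_model(str(path))
        import json
        from pathlib import Path

        Path(f"{path}.meta.json").write_text(
            json.dumps({"classes": [int(c) for c in self.classes_], "seed": self.seed})
        )

    @classmethod
    def load(cls, path) -> "SeverityModel":
        import json
        from pathlib import Path

        import xgboost as xgb

        booster = xgb.Booster()
        booster.load_model(str(path))
        meta_path = Path(f"{path}.meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            return cls(booster=booster, classes_=meta["classes"], seed=meta.get("seed", 0))
        return cls(booster=booster, classes_=list(range(4)))


DEFAULT_HYPERPARAMS = dict(
    n_estimators=100, max_depth=4, learning_rate=0.1, objective="multi:softprob"
)


def fit_severity_model(
    X: np.ndarray,
    y: Sequence[SeverityGrade],
    hyperparams: Optional[dict] = None,
    seed: int = 0,
) -> SeverityModel:
    """Train the boosted-tree severity classifier (deterministic per seed)."""
    X = np.asarray(X, dtype=float)
    y_int = np.asarray([int(g) for g in y])
    classes, y_enc = np.unique(y_int, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single severity class")
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    if len(classes) == 2 and hp.get("objective", "").startswith("multi"):
        hp["objective"] = "binary:logistic"
    clf = XGBClassifier(random_state=seed, n_jobs=1, **hp)
    clf.fit(X, y_enc)
    return SeverityModel(
        booster=clf, classes_=[int(c) for c in classes], seed=seed, hyperparams=hp
    )


def predict_severity(
    model: SeverityModel, v: RatioVector | np.ndarray
) -> tuple[SeverityGrade, np.ndarray]:
    """Predict (grade, 4-class probability vector) for one ratio vector."""
    if not model.fitted:
        raise ValueError("severity model is not fitted")
    x = v.values if isinstance(v, RatioVector) else np.asarray(v, dtype=float)
    raw = model.predict_proba(x.reshape(1, -1))[0]
    probs = np.zeros(4)
    for p, cls in zip(raw, model.classes_):
        probs[int(cls)] = p
    grade = SeverityGrade(int(np.argmax(probs)))
    return grade, probs
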