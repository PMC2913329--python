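"""C-SVC / RBF statistical layer: training, cross-validation, grid search.

The solver is scikit-learn's libsvm binding; the value added here is the
calibration and cross-validation bookkeeping the cascade needs, plus a
serializable bundle carrying the scaling factors, descriptor order and
rulebase partition alongside the fitted classifier.

Default hyperparameters are (C, gamma) = (8, 16), the grid-search optimum
of the reference calibration on the Bursi training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .descriptors import ScalingFactors, apply_scaling

DEFAULT_C = 8.0
DEFAULT_GAMMA = 16.0

#: default exponential grids for hyperparameter search
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** k for k in range(-15, 4, 2))

BUNDLE_FORMAT_VERSION = 1


@dataclass
class SvmModel:
    clf: SVC
    C: float
    gamma: float
    scaling: ScalingFactors
    descriptor_order: list[str]
    metadata: dict = field(default_factory=dict)

    def scale(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return apply_scaling(matrix[self.descriptor_order], self.scaling)


def _as_binary(labels: Sequence) -> np.ndarray:
    """Map mutagen/nonmutagen labels to +1/-1 (mutagen positive)."""
    from .records import AmesLabel

    out = []
    for lab in labels:
        value = lab.value if hasattr(lab, "value") else str(lab)
        if value == "mutagen":
            out.append(1)
        elif value == "nonmutagen":
            out.append(-1)
        else:
            raise ValueError(f"cannot train on label {value!r}")
    return np.asarray(out)


def train(
    matrix: pd.DataFrame,
    labels: Sequence,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    scaling: ScalingFactors | None = None,
) -> SvmModel:
    """Fit a soft-margin C-SVC with RBF kernel on a scaled matrix.

    ``matrix`` must already be scaled; pass the factors so they travel with
    the model.  Single-class label sets are an error.
    """
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = SVC(C=C, gamma=gamma, kernel="rbf")
    clf.fit(matrix.to_numpy(float), y)
    if scaling is None:
        scaling = ScalingFactors(pd.Series(1.0, index=matrix.columns))
    return SvmModel(clf, C, gamma, scaling, list(matrix.columns))


def predict(model: SvmModel, matrix: pd.DataFrame, ok=None) -> list[str]:
    """Per-row label: ``mutagen``/``nonmutagen``, or ``unpredicted`` for
    rows whose descriptors failed (``ok`` false)."""
    if list(matrix.columns) != model.descriptor_order:
        raise ValueError("descriptor columns do not match the model's descriptor order")
    X = matrix.to_numpy(float)
    out = ["unpredicted"] * len(matrix)
    ok_mask = np.ones(len(matrix), bool) if ok is None else np.asarray(ok, bool)
    if ok_mask.any():
        pred = model.clf.predict(X[ok_mask])
        labels = np.where(pred > 0, "mutagen", "nonmutagen")
        j = 0
        for i in range(len(matrix)):
            if ok_mask[i]:
                out[i] = str(labels[j])
                j += 1
    return out


def cross_validated_predictions(
    matrix: pd.DataFrame,
    labels: Sequence,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    k: int = 10,
    seed: int = 0,
    max_retries: int = 10,
) -> list[str]:
    """Out-of-fold predictions: each compound is predicted by the fold
    model that did not train on it.  Stratified by label, reproducible
    from ``seed``.  Folds degenerating to a single class are redrawn a
    bounded number of times."""
    if k < 2:
        raise ValueError("fold count must be >= 2")
    y = _as_binary(labels)
    X = matrix.to_numpy(float)
    n = len(y)
    out = np.empty(n, dtype=object)
    for attempt in range(max_retries):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        try:
            for train_idx, test_idx in skf.split(X, y):
                if len(np.unique(y[train_idx])) < 2:
                    raise ValueError("single-class fold")
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(X[train_idx], y[train_idx])
                pred = clf.predict(X[test_idx])
                out[test_idx] = np.where(pred > 0, "mutagen", "nonmutagen")
            return [str(v) for v in out]
        except ValueError:
            continue
    raise ValueError(f"could not draw {k} two-class folds in {max_retries} attempts")


def tune_hyperparameters(
    matrix: pd.DataFrame,
    labels: Sequence,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Grid-search (C, gamma) by k-fold cross-validation accuracy.

    Ties go to smaller C, then smaller gamma (favour regularization).
    Returns (C, gamma, cv_accuracy).
    """
    if not C_grid or not gamma_grid:
        raise ValueError("empty hyperparameter grid")
    y_true = _as_binary(labels)
    best = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            preds = cross_validated_predictions(matrix, labels, C, gamma, k, seed)
            acc = float(np.mean(_as_binary(preds) == y_true))
            if best is None or acc > best[2] + 1e-12:
                best = (C, gamma, acc)
    return best


# ---------------------------------------------------------------- bundles

def save_bundle(path: str | Path, model: SvmModel, rulebase_partition=None, extra=None) -> None:
    """Persist model + scaling + descriptor order (+ partition) to disk."""
    payload = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "clf": model.clf,
        "C": model.C,
        "gamma": model.gamma,
        "scaling": model.scaling.to_dict(),
        "descriptor_order": model.descriptor_order,
        "partition": {k: getattr(v, "value", v) for k, v in (rulebase_partition or {}).items()},
        "metadata": {**model.metadata, **(extra or {})},
    }
    joblib.dump(payload, path)


def load_bundle(path: str | Path) -> tuple[SvmModel, dict]:
    """Load a bundle; returns (model, partition)."""
    payload = joblib.load(path)
    if payload.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError("unsupported bundle format")
    model = SvmModel(
        payload["clf"],
        payload["C"],
        payload["gamma"],
        ScalingFactors.from_dict(payload["scaling"]),
        payload["descriptor_order"],
        payload.get("metadata", {}),
    )
    return model, payload.get("partition", {})
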