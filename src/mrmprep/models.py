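"""Training and application of the peak-picking and peak-reporting classifiers.

Both tasks are binary classification on fixed-order feature vectors: the
peak picker sees the 20 quality scores of a candidate and decides whether
it is the correct chromatographic peak; the peak reporter sees those scores
plus the picking score of the sample and its batch percentiles (26 features)
and decides whether the integrated peak is trustworthy enough to report.

Training follows a fixed recipe: a stratified 80/20 train/validation split,
a small hyperparameter grid searched by 3-fold cross-validated F1 on the
training split, and a single F1 evaluation on the held-out 20%.  Random
forest is the default algorithm; gradient-boosted trees, an RBF support
vector machine (with internal probability calibration so scores live on
[0, 1]) and a one-hidden-layer neural network are available for comparison.

Without any trained model the pipeline falls back to scoring candidates by
the plain average of their quality scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import f1_score as _sk_f1
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .chromatogram import PeakCandidate
from .quality import QS_NAMES, REPORTING_FEATURE_NAMES

logger = logging.getLogger("mrmprep")

__all__ = [
    "TrainingExample",
    "TrainedClassifier",
    "LabelingError",
    "derive_picking_labels",
    "derive_reporting_labels",
    "train_classifier",
    "predict_score",
    "fallback_score",
    "f1_from_counts",
    "feature_importance",
    "save_model",
    "load_model",
]

ALGORITHMS = ("random_forest", "gradient_boosted_trees", "svm", "neural_net")

# Small fixed hyperparameter grids, searched by 3-fold CV F1.
_GRIDS = {
    "random_forest": {"n_estimators": [200, 500], "max_depth": [None, 10]},
    "gradient_boosted_trees": {"max_depth": [3, 6]},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "neural_net": {"hidden_layer_sizes": [(8,), (32,)]},
}


class LabelingError(ValueError):
    """Raised when training solutions do not cover the extracted candidates."""


@dataclass
class TrainingExample:
    features: np.ndarray
    label: int
    metabolite: str = ""
    sample_id: str = ""


@dataclass
class TrainedClassifier:
    task: str                       # "picking" | "reporting"
    algorithm: str
    feature_names: tuple[str, ...]
    model: object
    validation_f1: float
    tuned_hyperparams: dict = field(default_factory=dict)
    train_seed: int = 0


def _solution_key(value) -> str:
    return str(value)


def derive_picking_labels(
    candidates: Sequence[PeakCandidate],
    solution: pd.DataFrame,
) -> list[TrainingExample]:
    """Label candidates against the expert solution table.

    ``solution`` has one row per (metabolite, sample) with columns
    ``metabolite, sample, area, start, end``; absent peaks carry area 0.
    A candidate is correct (label 1) iff the solution area is positive and
    its apex lies within [start, end].
    """
    required = {"metabolite", "sample", "area", "start", "end"}
    missing = required - set(solution.columns)
    if missing:
        raise LabelingError(f"picking solution missing columns {sorted(missing)}")
    index = {
        (_solution_key(r.metabolite), _solution_key(r.sample)): r
        for r in solution.itertuples()
    }
    out: list[TrainingExample] = []
    for cand in candidates:
        key = (cand.metabolite, cand.sample_id)
        if key not in index:
            raise LabelingError(f"no solution row for {key}")
        row = index[key]
        positive = (
            row.area > 0
            and np.isfinite(row.start)
            and np.isfinite(row.end)
            and row.start <= cand.apex_time <= row.end
        )
        if cand.qs is None:
            raise ValueError(f"candidate {key} has no quality scores")
        out.append(
            TrainingExample(
                features=np.asarray(cand.qs, dtype=float),
                label=int(positive),
                metabolite=cand.metabolite,
                sample_id=cand.sample_id,
            )
        )
    return out


def derive_reporting_labels(
    features: Mapping[tuple[str, str], np.ndarray],
    solution: pd.DataFrame,
) -> list[TrainingExample]:
    """Label reporting feature vectors from the 0/1/2 review table.

    2 = report (label 1), 0 = do not report (label 0), 1 = excluded from
    training; any other value is a validation error naming the cell.
    """
    required = {"metabolite", "sample", "value"}
    missing = required - set(solution.columns)
    if missing:
        raise LabelingError(f"reporting solution missing columns {sorted(missing)}")
    index = {}
    for i, r in enumerate(solution.itertuples()):
        v = int(r.value)
        if v not in (0, 1, 2):
            raise LabelingError(
                f"reporting solution row {i} ({r.metabolite}, {r.sample}): "
                f"value must be 0, 1 or 2, got {r.value}"
            )
        index[(_solution_key(r.metabolite), _solution_key(r.sample))] = v
    out: list[TrainingExample] = []
    for key, feats in features.items():
        if key not in index:
            raise LabelingError(f"no reporting solution row for {key}")
        v = index[key]
        if v == 1:
            continue
        out.append(
            TrainingExample(
                features=np.asarray(feats, dtype=float),
                label=1 if v == 2 else 0,
                metabolite=key[0],
                sample_id=key[1],
            )
        )
    return out


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "gradient_boosted_trees":
        try:
            from xgboost import XGBClassifier

            return XGBClassifier(
                random_state=seed, n_estimators=200, n_jobs=1,
                eval_metric="logloss",
            )
        except ImportError:
            return GradientBoostingClassifier(random_state=seed)
    if algorithm == "svm":
        # probability=True fits an internal Platt calibration so that
        # downstream gates get [0, 1] scores
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if algorithm == "neural_net":
        return MLPClassifier(max_iter=1000, random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def train_classifier(
    examples: Sequence[TrainingExample],
    algorithm: str = "random_forest",
    seed: int = 0,
    task: str = "picking",
) -> TrainedClassifier:
    """Fit one classifier with the fixed split/tuning/validation recipe."""
    if len(examples) < 20:
        raise ValueError(
            f"need at least 20 training examples, got {len(examples)}"
        )
    X = np.vstack([e.features for e in examples])
    y = np.array([e.label for e in examples])
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires examples of both classes")
    n_features = X.shape[1]
    if n_features == len(QS_NAMES):
        feature_names = QS_NAMES
    elif n_features == len(REPORTING_FEATURE_NAMES):
        feature_names = REPORTING_FEATURE_NAMES
    else:
        raise ValueError(f"unexpected feature length {n_features}")

    X_train, X_val, y_train, y_val = train_test_split(
        X, y, test_size=0.2, stratify=y, random_state=seed
    )
    search = GridSearchCV(
        _make_estimator(algorithm, seed),
        _GRIDS[algorithm],
        scoring="f1",
        cv=3,
        n_jobs=1,
    )
    search.fit(X_train, y_train)
    model = search.best_estimator_
    val_f1 = float(_sk_f1(y_val, model.predict(X_val)))
    logger.info(
        "trained %s %s model: validation F1 %.4f (params %s)",
        algorithm, task, val_f1, search.best_params_,
    )
    return TrainedClassifier(
        task=task,
        algorithm=algorithm,
        feature_names=tuple(feature_names),
        model=model,
        validation_f1=val_f1,
        tuned_hyperparams=dict(search.best_params_),
        train_seed=seed,
    )


def predict_score(model: TrainedClassifier, features) -> float | np.ndarray:
    """Class-1 probability for one feature vector (or a matrix of them)."""
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"{model.task} model expects {len(model.feature_names)} features, "
            f"got {X.shape[1]}"
        )
    proba = model.model.predict_proba(X)[:, 1]
    return float(proba[0]) if single else proba


def fallback_score(qs: np.ndarray) -> float:
    """No-model classification score: the plain mean of the 20 quality scores."""
    qs = np.asarray(qs, dtype=float)
    if qs.shape != (len(QS_NAMES),):
        raise ValueError(f"expected {len(QS_NAMES)} quality scores")
    return float(qs.mean())


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    """F1 = 2 * precision * recall / (precision + recall) from raw counts."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn == 0:
        raise ValueError("F1 undefined: no positives predicted or present")
    if tp == 0:
        return 0.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def feature_importance(model: TrainedClassifier) -> dict[str, float]:
    """Impurity-based importances (tree models), normalized and sorted."""
    importances = getattr(model.model, "feature_importances_", None)
    if importances is None:
        raise TypeError(
            f"feature importance unsupported for algorithm {model.algorithm!r}"
        )
    imp = np.asarray(importances, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = np.argsort(-imp, kind="stable")
    return {model.feature_names[i]: float(imp[i]) for i in order}


def save_model(model: TrainedClassifier, path: str | Path) -> Path:
    """Persist a trained classifier with its feature schema and metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(
        {
            "format": "mrmprep-classifier-v1",
            "task": model.task,
            "algorithm": model.algorithm,
            "feature_names": list(model.feature_names),
            "model": model.model,
            "validation_f1": model.validation_f1,
            "tuned_hyperparams": model.tuned_hyperparams,
            "train_seed": model.train_seed,
        },
        path,
    )
    return path


def load_model(path: str | Path) -> TrainedClassifier:
    payload = joblib.load(path)
    if payload.get("format") != "mrmprep-classifier-v1":
        raise ValueError(f"{path}: not a mrmprep classifier artifact")
    return TrainedClassifier(
        task=payload["task"],
        algorithm=payload["algorithm"],
        feature_names=tuple(payload["feature_names"]),
        model=payload["model"],
        validation_f1=payload["validation_f1"],
        tuned_hyperparams=payload["tuned_hyperparams"],
        train_seed=payload["train_seed"],
    )
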