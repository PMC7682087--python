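"""Classifiers: the RBF-kernel SVM and four classical baselines.

The SVM (penalty ``c``, kernel width ``g``) is the pipeline's
classifier of record; published presets are shipped for the three
feature setups it was tuned on.  The baselines — k-nearest neighbours
(k=2, Euclidean), Gaussian naive Bayes, random forest (20 trees) and a
bagged decision-tree ensemble (50 trees) — mirror the comparison setup
used when benchmarking the SVM.

All trainers are deterministic given (data, config, seed).  Scores are
oriented so larger means more likely positive; a model's decision
threshold is stored in its metadata, and ``predict`` labels positive
exactly when the score exceeds it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MODEL_FORMAT = "malprec-model-1"

#: Published (c, g) presets per feature setup.
SVM_PRESETS = {
    "cksaap_only": (10.0, 2.0),
    "all_features": (1.9, 0.07),
    "no_pca": (2.0, 0.1),
}

#: Default hyperparameter grid for grid_search; contains every preset.
DEFAULT_C_GRID = (0.1, 0.5, 1.0, 1.9, 2.0, 5.0, 10.0, 50.0)
DEFAULT_G_GRID = (0.01, 0.07, 0.1, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters: penalty c and kernel width g.

    ``g`` may be a positive number or ``"scale"`` (the default), which
    resolves to ``1 / (n_features * X.var())`` at fit time so the kernel
    width tracks the scale of the training features.  The published
    numeric presets in :data:`SVM_PRESETS` were tuned on a specific
    dataset and feature scaling; they are meaningful only on data
    prepared the same way.
    """

    c: float = 1.9
    g: float | str = "scale"
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")
        if isinstance(self.g, str):
            if self.g != "scale":
                raise ValueError(f"g must be positive or 'scale', got {self.g!r}")
        elif self.g <= 0:
            raise ValueError("g must be positive")
        if self.kernel != "rbf":
            raise ValueError("only the RBF kernel is supported")


@dataclass(frozen=True)
class BaselineConfig:
    """One of the four classical comparison classifiers."""

    name: str = "knn"
    knn_k: int = 2
    rf_trees: int = 20
    ensemble_trees: int = 50

    def __post_init__(self) -> None:
        if self.name not in ("knn", "nb", "rf", "ensemble"):
            raise ValueError(f"unknown baseline {self.name!r}")


@dataclass
class TrainedModel:
    """A fitted classifier plus the metadata needed to reproduce it."""

    estimator: object
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {"format": MODEL_FORMAT, "estimator": self.estimator, "metadata": self.metadata},
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = joblib.load(path)
        if payload.get("format") != MODEL_FORMAT:
            raise ValueError(f"unknown model format {payload.get('format')!r}")
        return cls(estimator=payload["estimator"], metadata=payload["metadata"])


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y length")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    classes = set(np.unique(y).tolist())
    if classes != {0, 1}:
        raise ValueError(f"need both classes 0 and 1, got {sorted(classes)}")
    return X, y


def _data_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train_svm(
    X: np.ndarray, y: Sequence[int], config: SVMConfig | None = None, seed: int = 0
) -> TrainedModel:
    """Fit the RBF-SVM; decision-function scores back the ROC analysis."""
    if config is None:
        config = SVMConfig()
    X, y = _check_xy(np.asarray(X), np.asarray(y))
    est = SVC(C=config.c, gamma=config.g, kernel="rbf", random_state=seed)
    est.fit(X, y)
    meta = {
        "classifier": "svm",
        "hyperparameters": {"c": config.c, "g": config.g, "kernel": "rbf"},
        "score_kind": "decision_function",
        "threshold": 0.0,
        "training_hash": _data_hash(X, y),
        "seed": int(seed),
    }
    return TrainedModel(estimator=est, metadata=meta)


def train_baseline(
    X: np.ndarray, y: Sequence[int], config: BaselineConfig, seed: int = 0
) -> TrainedModel:
    """Fit one of the comparison classifiers with its standard settings."""
    X, y = _check_xy(np.asarray(X), np.asarray(y))
    if config.name == "knn":
        est = KNeighborsClassifier(n_neighbors=config.knn_k, metric="euclidean")
    elif config.name == "nb":
        est = GaussianNB()
    elif config.name == "rf":
        est = RandomForestClassifier(n_estimators=config.rf_trees, random_state=seed)
    else:
        est = BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=config.ensemble_trees,
            random_state=seed,
        )
    est.fit(X, y)
    meta = {
        "classifier": config.name,
        "hyperparameters": {
            "knn": {"k": config.knn_k},
            "nb": {},
            "rf": {"trees": config.rf_trees},
            "ensemble": {"trees": config.ensemble_trees},
        }[config.name],
        "score_kind": "predict_proba",
        "threshold": 0.5,
        "training_hash": _data_hash(X, y),
        "seed": int(seed),
    }
    return TrainedModel(estimator=est, metadata=meta)


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and positively-oriented scores; label = score > threshold."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n_feat = getattr(model.estimator, "n_features_in_", None)
    if n_feat is not None and X.shape[1] != n_feat:
        raise ValueError(f"X has {X.shape[1]} columns, model expects {n_feat}")
    if X.shape[0] == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    if model.metadata["score_kind"] == "decision_function":
        scores = model.estimator.decision_function(X)
    else:
        scores = model.estimator.predict_proba(X)[:, 1]
    labels = (scores > model.metadata["threshold"]).astype(int)
    return labels, scores


def grid_search(
    X: np.ndarray,
    y: Sequence[int],
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    g_grid: Sequence[float] = DEFAULT_G_GRID,
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
) -> tuple[float, float, list[dict]]:
    """Pick (c, g) maximizing mean CV accuracy over the grid.

    Returns the winning pair plus the full grid table (one dict per
    cell: c, g, mean_accuracy, valid).  Ties break toward smaller c,
    then smaller g.  A cell whose CV folds cannot be evaluated (e.g. a
    single-class fold) is marked invalid rather than raising.
    """
    if not len(c_grid) or not len(g_grid):
        raise ValueError("grids must be non-empty")
    X, y = _check_xy(np.asarray(X), np.asarray(y))
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s) for s in ss.generate_state(repeats) >> 1]
    table: list[dict] = []
    for c in sorted(c_grid):
        for g in sorted(g_grid):
            accs: list[float] = []
            valid = True
            try:
                for fs in fold_seeds:
                    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fs)
                    for tr, te in skf.split(X, y):
                        if len(np.unique(y[tr])) < 2:
                            raise ValueError("single-class training fold")
                        est = SVC(C=c, gamma=g, kernel="rbf")
                        est.fit(X[tr], y[tr])
                        accs.append(float((est.predict(X[te]) == y[te]).mean()))
            except ValueError:
                valid = False
            mean_acc = float(np.mean(accs)) if valid and accs else float("nan")
            table.append({"c": c, "g": g, "mean_accuracy": mean_acc, "valid": valid})
    best = max(
        (r for r in table if r["valid"]),
        key=lambda r: (r["mean_accuracy"], -r["c"], -r["g"]),
        default=None,
    )
    if best is None:
        raise ValueError("no valid grid cell")
    return best["c"], best["g"], table
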