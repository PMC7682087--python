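"""Principal component analysis for feature reduction.

Feature matrices from the sequence encoders are high-dimensional (2274
columns for the default 17-mer configuration) and strongly collinear;
PCA projects them onto the top ``d`` directions of variance (default
d=100) before classification.  Fitting is deterministic: components are
computed by a full SVD of the mean-centered data and each component's
sign is canonicalized so its largest-magnitude loading is positive.

The projection is always fitted on training rows only and applied
unchanged to held-out rows; :class:`PCAProjection` serializes to JSON so
a fit can be stored alongside a model and reapplied bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .encoders import FeatureMatrix

FORMAT_VERSION = "malprec-pca-1"


@dataclass
class PCAProjection:
    """A fitted PCA: column mean, orthonormal component rows, variances.

    ``scale`` holds the per-column standard deviations divided out
    before centering when the fit used unit-variance scaling; None for
    an unscaled fit.
    """

    mean: np.ndarray  # (n_features,)
    components: np.ndarray  # (d, n_features), orthonormal rows
    explained_variance: np.ndarray  # (d,), non-increasing
    d: int
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.scale is not None:
            self.scale = np.asarray(self.scale, dtype=float)
        if self.components.shape != (self.d, self.mean.size):
            raise ValueError("components shape inconsistent with d and mean")
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.d), atol=1e-8):
            raise ValueError("component rows are not orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-12):
            raise ValueError("explained_variance must be non-increasing")

    @property
    def n_features(self) -> int:
        return self.mean.size

    def fingerprint(self) -> str:
        """Short content hash used to tie a model to the projection it used."""
        import hashlib

        h = hashlib.sha256()
        arrays = [self.mean, self.components, self.explained_variance]
        if self.scale is not None:
            arrays.append(self.scale)
        for a in arrays:
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        payload = {
            "format": FORMAT_VERSION,
            "d": self.d,
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PCAProjection":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != FORMAT_VERSION:
            raise ValueError(f"unknown projection format {payload.get('format')!r}")
        return cls(
            mean=np.array(payload["mean"]),
            components=np.array(payload["components"]),
            explained_variance=np.array(payload["explained_variance"]),
            d=payload["d"],
            scale=None if payload.get("scale") is None else np.array(payload["scale"]),
        )


def _as_array(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def fit_pca(X: FeatureMatrix | np.ndarray, d: int, scale: bool = False) -> PCAProjection:
    """Fit a d-component PCA on the rows of X.

    Requires ``d <= min(n_rows - 1, n_features)`` and non-constant data.
    Columns are mean-centered; with ``scale`` they are also divided by
    their standard deviation (constant columns excluded from scaling).
    Component signs are canonicalized: the largest-magnitude loading of
    each component is made positive, so the fit is fully deterministic.
    """
    A = _as_array(X)
    n, p = A.shape
    if n < 2:
        raise ValueError("need at least 2 rows to fit PCA")
    dmax = min(n - 1, p)
    if not 1 <= d <= dmax:
        raise ValueError(f"d={d} out of range; admissible maximum is {dmax}")
    if np.allclose(A, A[0], atol=0.0):
        raise ValueError("constant matrix has zero variance; nothing to fit")
    if scale:
        sd = A.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        A = A / sd
    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(A)
    components = pca.components_.copy()
    # Canonical sign: largest |loading| positive; first index wins ties.
    for row in components:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    return PCAProjection(
        mean=pca.mean_,
        components=components,
        explained_variance=pca.explained_variance_,
        d=d,
        scale=sd if scale else None,
    )


def transform(projection: PCAProjection, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Project rows of X: ``(X - mean) @ components.T``."""
    A = _as_array(X)
    if A.ndim == 1:
        A = A[None, :]
    if A.shape[1] != projection.n_features:
        raise ValueError(
            f"X has {A.shape[1]} columns but the projection expects "
            f"{projection.n_features}"
        )
    if projection.scale is not None:
        A = A / projection.scale
    return (A - projection.mean) @ projection.components.T


def inverse_transform(projection: PCAProjection, Z: np.ndarray) -> np.ndarray:
    """Map reduced coordinates back to feature space (lossless at full rank)."""
    Z = np.asarray(Z, dtype=float)
    A = Z @ projection.components + projection.mean
    if projection.scale is not None:
        A = A * projection.scale
    return A
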