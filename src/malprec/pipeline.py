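"""Wiring of the full prediction pipeline: encode -> PCA -> classifier.

:class:`PipelineConfig` bundles every stage's settings; ``fit_fold``
fits the reducible stages (PCA, classifier) on training rows only and
returns a :class:`FittedPipeline` that can score held-out windows, which
is the unit both cross-validation and the train/evaluate commands reuse.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .classify import (
    BaselineConfig,
    SVMConfig,
    TrainedModel,
    predict,
    train_baseline,
    train_svm,
)
from .encoders import (
    AAindexTable,
    CKSAAPConfig,
    ENCODER_ORDER,
    FeatureMatrix,
    encode_combined,
    load_aaindex_table,
)
from .reduction import PCAProjection, fit_pca, transform
from .windows import PeptideWindow


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings for encode -> reduce -> classify."""

    encoders: tuple[str, ...] = ENCODER_ORDER
    cksaap: CKSAAPConfig = field(default_factory=CKSAAPConfig)
    pca_dim: int | None = 100
    # Unit-variance scaling before PCA: the feature blocks mix counts,
    # indicators and physicochemical scales spanning two orders of
    # magnitude; without scaling the largest-unit block dominates the
    # principal directions and the RBF kernel geometry.
    scale: bool = True
    classifier: str = "svm"  # svm | knn | nb | rf | ensemble
    svm: SVMConfig = field(default_factory=SVMConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)

    def with_classifier(self, name: str) -> "PipelineConfig":
        if name == "svm":
            return replace(self, classifier="svm")
        return replace(self, classifier=name, baseline=BaselineConfig(name=name))

    def config_hash(self) -> str:
        payload = {
            "encoders": list(self.encoders),
            "cksaap": [list(self.cksaap.k_list), self.cksaap.normalize,
                       self.cksaap.pad_beyond_window],
            "pca_dim": self.pca_dim,
            "scale": self.scale,
            "classifier": self.classifier,
            "svm": [self.svm.c, self.svm.g],
            "baseline": [self.baseline.name, self.baseline.knn_k,
                         self.baseline.rf_trees, self.baseline.ensemble_trees],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def encode_windows(
    windows: Sequence[PeptideWindow],
    config: PipelineConfig,
    table: AAindexTable | None = None,
) -> FeatureMatrix:
    """Encode windows with the configured feature blocks (stateless)."""
    if table is None and "aaindex" in config.encoders:
        table = load_aaindex_table()
    return encode_combined(
        list(windows), config=config.cksaap, encoders=config.encoders, table=table
    )


@dataclass
class FittedPipeline:
    """PCA projection (optional) plus a trained classifier."""

    config: PipelineConfig
    projection: PCAProjection | None
    model: TrainedModel
    pca_dim_used: int | None

    def score(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Z = transform(self.projection, X) if self.projection is not None else np.asarray(X)
        return predict(self.model, Z)


def fit_fold(
    X_train: np.ndarray,
    y_train: Sequence[int],
    config: PipelineConfig,
    seed: int = 0,
) -> FittedPipeline:
    """Fit PCA and the classifier on training rows only.

    The requested PCA dimension is clamped to the admissible maximum
    ``min(n_rows - 1, n_features)`` for small training sets; the
    dimension actually used is recorded.
    """
    X_train = np.asarray(X_train, dtype=float)
    projection = None
    d_used = None
    Z = X_train
    if config.pca_dim is not None:
        d_used = min(config.pca_dim, X_train.shape[0] - 1, X_train.shape[1])
        projection = fit_pca(X_train, d_used, scale=config.scale)
        Z = transform(projection, X_train)
    if config.classifier == "svm":
        model = train_svm(Z, y_train, config.svm, seed=seed)
    else:
        model = train_baseline(Z, y_train, config.baseline, seed=seed)
    if projection is not None:
        model.metadata["pca_fingerprint"] = projection.fingerprint()
        model.metadata["pca_dim"] = d_used
    model.metadata["pipeline_hash"] = config.config_hash()
    return FittedPipeline(config=config, projection=projection, model=model,
                          pca_dim_used=d_used)


@dataclass
class RunConfig:
    """Fully resolved settings for an end-to-end run.

    Input is either a windows TSV or a FASTA + site-annotation pair.
    Every field has a flag mirror in the CLI and the resolved config is
    echoed into every artifact, so a run is reproducible from its
    outputs plus the input files.
    """

    out_dir: str = "malprec_run"
    windows_tsv: str | None = None
    fasta: str | None = None
    annotations: str | None = None
    n: int = 8
    eps: int = 8
    encoders: tuple[str, ...] = ENCODER_ORDER
    k_list: tuple[int, ...] = (0, 1, 2, 3)
    normalize: bool = False
    pca_dim: int | None = 100
    scale: bool = True
    classifier: str = "svm"
    c: float = 1.9
    g: float | str = "scale"
    folds: int = 5
    repeats: int = 5
    split_fraction: float = 0.2
    deduplicate: bool = True
    run_cv: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("encoders", "k_list"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def pipeline_config(self) -> PipelineConfig:
        cfg = PipelineConfig(
            encoders=tuple(self.encoders),
            cksaap=CKSAAPConfig(k_list=tuple(self.k_list), normalize=self.normalize),
            pca_dim=self.pca_dim,
            scale=self.scale,
            svm=SVMConfig(c=self.c, g=self.g),
        )
        return cfg.with_classifier(self.classifier)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["encoders"] = list(self.encoders)
        d["k_list"] = list(self.k_list)
        return d


def _stage_seeds(seed: int, names: tuple[str, ...]) -> dict[str, int]:
    """Expand one top-level seed into independent per-stage seeds."""
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(len(names)) >> 1
    return {name: int(s) for name, s in zip(names, states)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute extract -> encode -> split -> (PCA fit on train) -> train ->
    evaluate, writing artifacts under ``config.out_dir``.

    Artifacts: ``model.joblib`` + ``projection.json`` (the fitted
    pipeline), ``metrics.json`` (independent-set metrics and optional
    CV summary), ``roc.tsv`` (independent-set ROC points), and
    ``config.json`` (the resolved run configuration, config hash and
    seed).  Returns the metrics dict.
    """
    from . import evaluate as _evaluate
    from .dataset import deduplicate as _dedup, split_train_independent
    from .windows import extract_annotated_windows, read_annotations, read_fasta, read_windows

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ("split", "fit", "cv"))

    if config.windows_tsv:
        windows = read_windows(config.windows_tsv, n=config.n, eps=config.eps)
    elif config.fasta and config.annotations:
        proteins = read_fasta(config.fasta)
        annotations = read_annotations(config.annotations)
        windows = extract_annotated_windows(proteins, annotations,
                                            n=config.n, eps=config.eps)
    else:
        raise ValueError("provide windows_tsv or fasta + annotations")
    if any(w.label is None for w in windows):
        raise ValueError("run_pipeline requires labeled windows")
    counts = {"windows_in": len(windows)}
    if config.deduplicate:
        windows = _dedup(windows)
    counts["windows_after_dedup"] = len(windows)

    split = split_train_independent(windows, fraction=config.split_fraction,
                                    seed=seeds["split"])
    counts["training"] = len(split.training)
    counts["independent"] = len(split.independent)

    pcfg = config.pipeline_config()
    X_train = encode_windows(split.training, pcfg).values
    y_train = np.array([w.label for w in split.training], dtype=int)
    fitted = fit_fold(X_train, y_train, pcfg, seed=seeds["fit"])

    X_ind = encode_windows(split.independent, pcfg).values
    y_ind = np.array([w.label for w in split.independent], dtype=int)
    labels, scores = fitted.score(X_ind)
    report = _evaluate.metrics(_evaluate.confusion(y_ind, labels))
    roc = _evaluate.roc_auc(y_ind, scores)
    roc.to_tsv(out / "roc.tsv")

    fitted.model.save(out / "model.joblib")
    if fitted.projection is not None:
        fitted.projection.save(out / "projection.json")

    results = {
        "config_hash": pcfg.config_hash(),
        "seed": config.seed,
        "counts": counts,
        "independent": {**report.as_dict(), "auc": roc.auc,
                        "undefined": sorted(report.undefined)},
    }
    if config.run_cv:
        cv = _evaluate.cross_validate(split.training, pcfg, k=config.folds,
                                      repeats=config.repeats, seed=seeds["cv"])
        results["cv"] = {"mean": cv.mean, "sd": cv.sd,
                         "n_undefined": cv.n_undefined}
        (out / "cv_summary.tsv").write_text(cv.summary_tsv())
    (out / "metrics.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2,
                                                sort_keys=True))
    return results
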