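"""Performance evaluation: confusion metrics, ROC/AUC, repeated k-fold CV.

Five confusion-derived metrics are reported:

    Acc  = (TP + TN) / (TP + FP + TN + FN)
    Sen  = TP / (TP + FN)
    Spec = TN / (TN + FP)
    F1   = 2 * Sen * PPV / (Sen + PPV),  PPV = TP / (TP + FP)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

A 0/0 denominator yields NaN, flagged in ``undefined`` and excluded
from cross-validation averages (with an exclusion count reported).

ROC curves sweep every distinct score as a threshold; AUC is the
trapezoidal area, which equals the Mann-Whitney U statistic divided by
n+ * n- with ties counted half.

``cross_validate`` runs repeated stratified 5-fold CV of the full
encode -> PCA -> classifier pipeline, fitting PCA and the classifier on
the training folds only in every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .pipeline import PipelineConfig, encode_windows, fit_fold
from .windows import PeptideWindow

METRIC_NAMES = ("acc", "sen", "spec", "ppv", "f1", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative tallies."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five confusion metrics plus precision; NaN entries flagged."""

    acc: float
    sen: float
    spec: float
    ppv: float
    f1: float
    mcc: float
    counts: ConfusionCounts
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}

    def as_percent(self) -> dict[str, float]:
        return {m: 100.0 * getattr(self, m) for m in METRIC_NAMES}


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Exact TP/TN/FP/FN tallies for binary label vectors."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if not (set(np.unique(yt)) | set(np.unique(yp))) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Derive the five metrics from the confusion counts."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    undefined: set[str] = set()
    acc = _ratio(tp + tn, counts.total, "acc", undefined)
    sen = _ratio(tp, tp + fn, "sen", undefined)
    spec = _ratio(tn, tn + fp, "spec", undefined)
    ppv = _ratio(tp, tp + fp, "ppv", undefined)
    if np.isnan(sen) or np.isnan(ppv) or (sen + ppv) == 0:
        undefined.add("f1")
        f1 = float("nan")
    else:
        f1 = 2.0 * sen * ppv / (sen + ppv)
    den = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    if den == 0:
        undefined.add("mcc")
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(den))
    return MetricsReport(acc=acc, sen=sen, spec=spec, ppv=ppv, f1=f1, mcc=mcc,
                         counts=counts, undefined=frozenset(undefined))


@dataclass(frozen=True)
class ROCCurve:
    """ROC points with the thresholds that generated them and the AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold\tfpr\ttpr\n")
            for t, x, y in zip(self.thresholds, self.fpr, self.tpr):
                fh.write(f"{t}\t{x}\t{y}\n")


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> ROCCurve:
    """ROC by sweeping every distinct score; AUC by the trapezoid rule."""
    yt = np.asarray(y_true, dtype=int)
    sc = np.asarray(scores, dtype=float)
    if yt.shape != sc.shape:
        raise ValueError("length mismatch")
    if len(np.unique(yt)) < 2:
        raise ValueError("both classes required for a ROC curve")
    if not np.isfinite(sc).all():
        raise ValueError("scores must be finite")
    fpr, tpr, thresholds = _sk_roc_curve(yt, sc, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


@dataclass
class CVResult:
    """Per-fold metric table plus aggregate mean/SD per metric.

    ``records`` holds one dict per (repeat, fold) with the six metrics,
    the AUC, the confusion counts, and the fold seed.  Aggregates are
    NaN-aware: undefined metric values are excluded and counted in
    ``n_undefined``.
    """

    records: list[dict]
    k: int
    repeats: int
    seed: int
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    n_undefined: dict[str, int] = field(default_factory=dict)

    def aggregate(self) -> None:
        names = METRIC_NAMES + ("auc",)
        for m in names:
            vals = np.array([r[m] for r in self.records], dtype=float)
            ok = np.isfinite(vals)
            self.n_undefined[m] = int((~ok).sum())
            self.mean[m] = float(vals[ok].mean()) if ok.any() else float("nan")
            self.sd[m] = float(vals[ok].std(ddof=1)) if ok.sum() > 1 else float("nan")

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "mean": self.mean,
            "sd": self.sd,
            "n_undefined": self.n_undefined,
            "records": self.records,
        }

    def summary_tsv(self) -> str:
        """Mean +/- SD per metric, in percent with 2 decimals."""
        lines = ["metric\tmean_pct\tsd_pct"]
        for m in METRIC_NAMES + ("auc",):
            lines.append(f"{m}\t{100 * self.mean[m]:.2f}\t{100 * self.sd[m]:.2f}")
        return "\n".join(lines) + "\n"


def cross_validate(
    windows: Sequence[PeptideWindow],
    pipeline_config: PipelineConfig | None = None,
    k: int = 5,
    repeats: int = 50,
    seed: int = 0,
    X: np.ndarray | None = None,
) -> CVResult:
    """Repeated stratified k-fold CV of the encode -> PCA -> classifier pipeline.

    Every fold fits PCA and the classifier on its training rows only and
    evaluates on the held-out rows.  ``X`` may carry a pre-computed
    encoding of ``windows`` (the encoders are stateless, so encoding
    once is equivalent); it is recomputed when omitted.
    """
    if pipeline_config is None:
        pipeline_config = PipelineConfig()
    y = np.array([w.label for w in windows])
    if any(lab is None for lab in y):
        raise ValueError("all windows must be labeled")
    y = y.astype(int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"need at least {k} windows per class for {k}-fold stratification, "
            f"got {n_pos} positive / {n_neg} negative"
        )
    if X is None:
        X = encode_windows(windows, pipeline_config).values
    X = np.asarray(X, dtype=float)

    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s) for s in ss.generate_state(2 * repeats) >> 1]
    records: list[dict] = []
    for rep in range(repeats):
        split_seed = repeat_seeds[2 * rep]
        fit_seed = repeat_seeds[2 * rep + 1]
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=split_seed)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            fitted = fit_fold(X[tr], y[tr], pipeline_config, seed=fit_seed)
            labels, scores = fitted.score(X[te])
            rep_metrics = metrics(confusion(y[te], labels))
            rec = {"repeat": rep, "fold": fold, "split_seed": split_seed,
                   **rep_metrics.as_dict(),
                   "auc": roc_auc(y[te], scores).auc,
                   "counts": [rep_metrics.counts.tp, rep_metrics.counts.tn,
                              rep_metrics.counts.fp, rep_metrics.counts.fn]}
            records.append(rec)
    result = CVResult(records=records, k=k, repeats=repeats, seed=seed)
    result.aggregate()
    return result
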