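"""Dataset assembly: deduplication, class balancing, hold-out split.

Candidate lysine windows vastly outnumber verified modification sites,
so the working dataset is built by (1) collapsing exact-duplicate
peptides, (2) down-sampling the negatives to the positive count, and
(3) carving a stratified independent (hold-out) partition — 20% by
default — that stays untouched during training and model selection.
Every step logs its in/out counts so the provenance of the final
dataset reconciles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .windows import PeptideWindow

logger = logging.getLogger(__name__)


@dataclass
class DatasetSplit:
    """Training/independent partitions plus a provenance log of counts."""

    training: list[PeptideWindow]
    independent: list[PeptideWindow]
    seed: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        train_keys = {w.residues for w in self.training}
        indep_keys = {w.residues for w in self.independent}
        overlap = train_keys & indep_keys
        if overlap:
            warnings.warn(
                f"{len(overlap)} identical peptides appear in both partitions "
                "(deduplicate first to guarantee disjointness)"
            )


def deduplicate(windows: Sequence[PeptideWindow]) -> list[PeptideWindow]:
    """Collapse exact-duplicate peptides, keeping the first occurrence.

    A peptide that recurs with conflicting labels is dropped entirely
    (all its copies), with a warning: a sequence observed both
    modified and unmodified cannot train a sequence-only model.
    """
    by_seq: dict[str, list[PeptideWindow]] = {}
    order: list[str] = []
    for w in windows:
        if w.residues not in by_seq:
            order.append(w.residues)
            by_seq[w.residues] = []
        by_seq[w.residues].append(w)
    out = []
    n_conflict = 0
    for seq in order:
        group = by_seq[seq]
        labels = {w.label for w in group}
        if len(labels) > 1:
            n_conflict += 1
            continue
        out.append(group[0])
    if n_conflict:
        warnings.warn(f"dropped {n_conflict} peptides with conflicting labels")
    logger.info("deduplicate: %d windows in, %d out (%d label conflicts)",
                len(windows), len(out), n_conflict)
    return out


def balance_downsample(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    seed: int = 0,
) -> list[PeptideWindow]:
    """Keep all positives; sample an equal number of negatives uniformly."""
    if len(negatives) < len(positives):
        raise ValueError(
            f"{len(negatives)} negatives < {len(positives)} positives; "
            "swap the roles of the two sets to down-sample"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negatives), size=len(positives), replace=False)
    sampled = [negatives[i] for i in sorted(idx)]
    logger.info("balance_downsample: %d positives kept, %d of %d negatives sampled",
                len(positives), len(sampled), len(negatives))
    return list(positives) + sampled


def split_train_independent(
    balanced: Sequence[PeptideWindow],
    fraction: float = 0.2,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified random split into training and independent partitions.

    Per class, ``round(fraction * n_class)`` windows go to the
    independent set (banker's rounding), so the two partitions keep the
    class balance within one window.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {}
    for i, w in enumerate(balanced):
        if w.label is None:
            raise ValueError("all windows must be labeled before splitting")
        by_class.setdefault(int(w.label), []).append(i)
    indep_idx: set[int] = set()
    for label, idxs in sorted(by_class.items()):
        n_ind = round(fraction * len(idxs))
        if n_ind == 0 or n_ind == len(idxs):
            raise ValueError(
                f"fraction {fraction} would leave class {label} empty in one partition"
            )
        chosen = rng.choice(len(idxs), size=n_ind, replace=False)
        indep_idx.update(idxs[i] for i in chosen)
    training = [w for i, w in enumerate(balanced) if i not in indep_idx]
    independent = [w for i, w in enumerate(balanced) if i in indep_idx]
    prov = {
        "n_input": len(balanced),
        "n_training": len(training),
        "n_independent": len(independent),
        "fraction": fraction,
        "per_class_input": {lab: len(idxs) for lab, idxs in sorted(by_class.items())},
        "per_class_independent": {
            lab: sum(1 for w in independent if w.label == lab)
            for lab in sorted(by_class)
        },
    }
    logger.info("split_train_independent: %s", prov)
    return DatasetSplit(training=training, independent=independent, seed=seed,
                        provenance=prov)


def write_split(split: DatasetSplit, path) -> None:
    """Windows TSV with an extra partition column (train | independent)."""
    from .windows import WINDOW_HEADER

    with open(path, "w") as fh:
        fh.write("\t".join(WINDOW_HEADER + ["partition"]) + "\n")
        for part, ws in (("train", split.training), ("independent", split.independent)):
            for w in ws:
                lab = "?" if w.label is None else str(w.label)
                if isinstance(w.source, tuple):
                    pid, pos = w.source
                elif w.source is None:
                    pid, pos = "", 0
                else:
                    pid, pos = str(w.source), 0
                fh.write(f"{w.residues}\t{lab}\t{pid}\t{pos}\t{part}\n")
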