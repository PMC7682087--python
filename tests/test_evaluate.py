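"""Metrics, ROC/AUC, and cross-validation wiring (leakage, determinism)."""

import json

import numpy as np
import pytest
from scipy import stats

from malprec.evaluate import (
    ConfusionCounts,
    confusion,
    cross_validate,
    metrics,
    roc_auc,
)
from malprec.pipeline import PipelineConfig
from malprec.synthetic import GeneratorConfig, generate_windows


def rank_auc_oracle(y, scores):
    """AUC as the probability a positive outscores a negative, ties half."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_direct_count(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_identical_vectors(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    def test_complemented_vectors(self):
        c = confusion([1, 0], [0, 1])
        assert c.tp == 0 and c.tn == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_hand_evaluated_case(self):
        # frozen expectations from direct formula evaluation on these counts
        m = metrics(ConfusionCounts(tp=50, tn=40, fp=10, fn=0))
        assert m.acc == pytest.approx(0.90)
        assert m.sen == pytest.approx(1.00)
        assert m.spec == pytest.approx(0.80)
        assert m.ppv == pytest.approx(50 / 60)
        assert m.f1 == pytest.approx(10 / 11)
        assert m.mcc == pytest.approx(2000 / np.sqrt(50 * 50 * 60 * 40))

    def test_no_association(self):
        assert metrics(ConfusionCounts(25, 25, 25, 25)).mcc == pytest.approx(0.0)

    def test_perfect_prediction(self):
        m = metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert (m.acc, m.sen, m.spec, m.f1, m.mcc) == (1, 1, 1, 1, 1)

    def test_undefined_sentinels_flagged(self):
        m = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert np.isnan(m.ppv) and "ppv" in m.undefined
        assert np.isnan(m.mcc) and "mcc" in m.undefined

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)

    def test_matches_independent_formulas_on_random_tables(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            total = tp + tn + fp + fn
            assert m.acc == pytest.approx((tp + tn) / total, abs=1e-12)
            assert m.sen == pytest.approx(tp / (tp + fn), abs=1e-12)
            assert m.spec == pytest.approx(tn / (tn + fp), abs=1e-12)
            if tp + fp > 0:
                sen, ppv = tp / (tp + fn), tp / (tp + fp)
                if sen + ppv > 0:
                    # F1 is the harmonic mean of Sen and PPV
                    assert m.f1 == pytest.approx(stats.hmean([sen, ppv]), abs=1e-12)

    def test_mcc_antisymmetric_under_label_complement(self):
        m1 = metrics(ConfusionCounts(tp=30, tn=20, fp=5, fn=10))
        m2 = metrics(ConfusionCounts(tp=5, tn=10, fp=30, fn=20))
        assert m2.mcc == pytest.approx(-m1.mcc, abs=1e-12)


class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]).auc == pytest.approx(1.0)

    def test_all_equal_scores_is_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5] * 4).auc == pytest.approx(0.5, abs=1e-12)

    def test_pair_counting_example(self):
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.1]).auc == pytest.approx(0.75)

    def test_endpoints_and_monotonicity(self, rng):
        roc = roc_auc(rng.integers(0, 2, 50) | np.array([1] + [0] * 49),
                      rng.normal(size=50))
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.1, 0.2])

    def test_auc_equals_rank_statistic_oracle(self, rng):
        for _ in range(500):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            scores = np.round(rng.normal(size=n), 1)  # coarse -> many ties
            assert roc_auc(y, scores).auc == pytest.approx(
                rank_auc_oracle(y, scores), abs=1e-12
            )

    def test_tsv_export(self, tmp_path):
        roc = roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.1])
        out = tmp_path / "roc.tsv"
        roc.to_tsv(out)
        lines = out.read_text().strip().split("\n")
        assert lines[0] == "threshold\tfpr\ttpr"
        assert len(lines) == len(roc.fpr) + 1


FAST_CFG = PipelineConfig(pca_dim=20)


class TestCrossValidate:
    def test_strong_signal_beats_chance(self, small_labeled_windows):
        res = cross_validate(small_labeled_windows, FAST_CFG, k=5, repeats=1, seed=5)
        assert res.mean["acc"] > 0.7
        assert res.mean["auc"] > 0.8

    def test_label_shuffle_leakage_guard(self, small_labeled_windows, rng):
        # shuffling labels must drive accuracy to chance; failure would
        # indicate train/test contamination in the fold wiring
        from malprec.windows import PeptideWindow

        labels = rng.permutation([w.label for w in small_labeled_windows])
        shuffled = [
            PeptideWindow(residues=w.residues, n=w.n, eps=w.eps, label=int(l),
                          source=w.source)
            for w, l in zip(small_labeled_windows, labels)
        ]
        res = cross_validate(shuffled, FAST_CFG, k=5, repeats=2, seed=5)
        assert abs(res.mean["acc"] - 0.5) < 0.12

    def test_deterministic_repeat(self, small_labeled_windows):
        a = cross_validate(small_labeled_windows, FAST_CFG, k=5, repeats=2, seed=9)
        b = cross_validate(small_labeled_windows, FAST_CFG, k=5, repeats=2, seed=9)
        assert json.dumps(a.to_json_dict(), sort_keys=True) == json.dumps(
            b.to_json_dict(), sort_keys=True
        )

    def test_fold_partition_invariants(self, small_labeled_windows):
        res = cross_validate(small_labeled_windows, FAST_CFG, k=5, repeats=1, seed=2)
        sizes = [sum(r["counts"]) for r in res.records]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == len(small_labeled_windows)

    def test_aggregates_recomputable_from_records(self, small_labeled_windows):
        res = cross_validate(small_labeled_windows, FAST_CFG, k=5, repeats=1, seed=2)
        accs = np.array([r["acc"] for r in res.records])
        assert res.mean["acc"] == pytest.approx(accs.mean(), abs=1e-12)
        assert res.sd["acc"] == pytest.approx(accs.std(ddof=1), abs=1e-12)

    def test_class_too_small_rejected(self):
        ws = generate_windows(GeneratorConfig(n_pos=3, n_neg=30, seed=0))
        with pytest.raises(ValueError, match="per class"):
            cross_validate(ws, FAST_CFG, k=5, repeats=1, seed=0)

    def test_summary_tsv_format(self, small_labeled_windows):
        res = cross_validate(small_labeled_windows, FAST_CFG, k=5, repeats=1, seed=2)
        lines = res.summary_tsv().strip().split("\n")
        assert lines[0] == "metric\tmean_pct\tsd_pct"
        assert len(lines) == 8  # six metrics + auc
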