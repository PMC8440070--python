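"""Metric arithmetic against hand counts and identities; cross-validation
structure; end-to-end pipeline reproducibility."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ecgfuse as ef
from ecgfuse.evaluate import (
    ConfusionCounts,
    PipelineConfig,
    confusion_counts,
    confusion_matrix,
    cross_validate,
    match_to_ground_truth,
    metrics,
    run_pipeline,
)


class TestConfusionCounts:
    def test_perfect_prediction(self):
        c = confusion_counts(["N", "V", "L"], ["N", "V", "L"], "N")
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 2, 0, 0)

    def test_hand_counted_example(self):
        c = confusion_counts(["N", "N", "V"], ["N", "V", "V"], "N")
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 0)

    def test_matches_vectorised_tally(self):
        rng = np.random.default_rng(0)
        true = rng.choice(list(ef.CLASSES), 200)
        pred = rng.choice(list(ef.CLASSES), 200)
        for k in ef.CLASSES:
            c = confusion_counts(true, pred, k)
            t, p = (true == k), (pred == k)
            assert c.TP == int(np.sum(t & p))
            assert c.FP == int(np.sum(~t & p))
            assert c.FN == int(np.sum(t & ~p))
            assert c.TN == int(np.sum(~t & ~p))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(["N"], ["N", "V"], "N")


class TestMetrics:
    def test_worked_example(self):
        m = metrics(ConfusionCounts(TP=9, FP=1, FN=1, TN=89))
        assert m.PPV == pytest.approx(90.0)
        assert m.SE == pytest.approx(90.0)
        assert m.SP == pytest.approx(100 * 89 / 90)
        assert m.Acc == pytest.approx(98.0)
        assert m.F1 == pytest.approx(90.0)
        assert not m.degenerate

    def test_perfect_case(self):
        m = metrics(ConfusionCounts(TP=10, FP=0, FN=0, TN=90))
        assert m.PPV == m.SE == m.F1 == 100.0

    def test_degenerate_flagged(self):
        m = metrics(ConfusionCounts(TP=0, FP=0, FN=5, TN=95))
        assert m.PPV == 0.0 and m.degenerate

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    @given(st.integers(1, 500), st.integers(0, 500),
           st.integers(0, 500), st.integers(0, 500))
    def test_f1_is_harmonic_mean_of_ppv_and_se(self, tp, fp, fn, tn):
        m = metrics(ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn))
        harmonic = 2 * m.PPV * m.SE / (m.PPV + m.SE)
        assert m.F1 == pytest.approx(harmonic, abs=1e-9)


@pytest.fixture(scope="module")
def small_report():
    beats, labels = ef.make_benchmark_dataset(15, rng_seed=0)
    cfg = PipelineConfig(epochs=3, folds=3)
    return cross_validate(beats, labels, k=3, seed=0, pipeline_config=cfg), len(beats)


class TestCrossValidate:
    def test_structural_completeness(self, small_report):
        report, _ = small_report
        assert len(report["folds"]) == 3
        for fr in report["folds"]:
            for system in ("cnn", "svr", "fused"):
                block = fr["systems"][system]
                assert set(block["per_class"]) == set(ef.CLASSES)
                for cls in ef.CLASSES:
                    assert set(block["per_class"][cls]["metrics"]) >= {
                        "PPV", "SE", "SP", "Acc", "F1"}

    def test_folds_partition_the_data(self, small_report):
        report, n = small_report
        seen = [d["beat_index"] for d in report["decisions"]]
        assert sorted(seen) == list(range(n))

    def test_averaged_equals_mean_of_folds(self, small_report):
        report, _ = small_report
        for system in ("cnn", "svr", "fused"):
            per_fold = [f["systems"][system]["overall_acc"] for f in report["folds"]]
            assert report["averaged"][system]["overall_acc"] == pytest.approx(
                np.mean(per_fold), abs=1e-9)

    def test_micro_consistency_of_overall_accuracy(self, small_report):
        report, _ = small_report
        for fr in report["folds"]:
            fold_dec = [d for d in report["decisions"] if d["fold"] == fr["fold_index"]]
            correct = sum(d["true"] == d["fused"] for d in fold_dec)
            assert fr["systems"]["fused"]["overall_acc"] == pytest.approx(
                100 * correct / len(fold_dec))

    def test_insufficient_per_class_rejected(self):
        beats, labels = ef.make_benchmark_dataset(10, rng_seed=0)
        with pytest.raises(ValueError):
            cross_validate(beats, labels, k=20, seed=0)


def test_match_to_ground_truth_tolerance():
    det = np.array([100, 205, 400])
    true_r = np.array([102, 200, 300])
    kept, labels, matched = match_to_ground_truth(det, true_r, ["N", "V", "L"], tol=10)
    assert list(kept) == [100, 205]
    assert labels == ["N", "V"]
    assert matched == 2


def test_confusion_matrix_layout():
    cm = confusion_matrix(["N", "V", "V"], ["N", "V", "N"])
    assert cm[0, 0] == 1  # true N predicted N
    assert cm[3, 3] == 1  # true V predicted V
    assert cm[3, 0] == 1  # true V predicted N
    assert cm.sum() == 3


class TestRunPipeline:
    def test_end_to_end_report_and_mass_validity(self, tmp_path):
        cfg = PipelineConfig(n_beats=60, folds=3, epochs=5, seed=0)
        report = run_pipeline(cfg, tmp_path / "run")
        assert (tmp_path / "run" / "report.json").exists()
        for d in report["decisions"]:
            for key in ("cnn_mass", "svr_mass", "fused_mass"):
                m = np.asarray(d[key])
                assert np.all(m >= -1e-12)
                assert m.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = PipelineConfig(n_beats=60, folds=3, epochs=5, seed=1)
        run_pipeline(cfg, tmp_path / "a")
        run_pipeline(cfg, tmp_path / "b")
        for name in ("report.json", "decisions.csv", "confusion_fused.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()
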