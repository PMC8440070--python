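"""Evaluation harness: per-class metrics, cross-validation, pipeline runner.

Metrics are one-vs-rest per class, in percent::

    PPV = TP / (TP + FP)            positive predictivity
    SE  = TP / (TP + FN)            sensitivity
    SP  = TN / (TN + FP)            specificity
    Acc = (TP + TN) / total         accuracy
    F1  = 2 TP / (2 TP + FP + FN)   harmonic mean of PPV and SE

Zero-denominator cases return 0 with a degenerate flag so reports stay total.
Cross-validation is stratified k-fold; per-fold metrics are averaged with a
plain mean. Three systems are scored side by side: the CNN stream alone, the
SVR stream alone, and their Dempster-Shafer fusion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import features as feat
from . import fusion, qrs, svr, synthetic
from .preprocess import preprocess as preprocess_signal
from .cnn import TrainingConfig, predict_mass_cnn, train_cnn
from .types import CLASSES

SYSTEMS = ("cnn", "svr", "fused")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class ClassMetrics:
    PPV: float
    SE: float
    SP: float
    Acc: float
    F1: float
    degenerate: bool = False


def confusion_counts(true_labels, predicted_labels, class_k: str) -> ConfusionCounts:
    """One-vs-rest confusion counts for ``class_k``."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    tp = fp = fn = tn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == class_k and p == class_k:
            tp += 1
        elif t != class_k and p == class_k:
            fp += 1
        elif t == class_k and p != class_k:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def metrics(counts: ConfusionCounts) -> ClassMetrics:
    """The five per-class metrics, in percent."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on all-zero counts")
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return 100.0 * num / den

    ppv = ratio(counts.TP, counts.TP + counts.FP)
    se = ratio(counts.TP, counts.TP + counts.FN)
    sp = ratio(counts.TN, counts.TN + counts.FP)
    acc = ratio(counts.TP + counts.TN, counts.total)
    f1 = ratio(2 * counts.TP, 2 * counts.TP + counts.FP + counts.FN)
    return ClassMetrics(PPV=ppv, SE=se, SP=sp, Acc=acc, F1=f1, degenerate=degenerate)


def confusion_matrix(true_labels, predicted_labels) -> np.ndarray:
    """5x5 matrix, true rows x predicted columns, canonical class order."""
    mat = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        mat[CLASSES.index(t), CLASSES.index(p)] += 1
    return mat


def _system_report(true_labels, predicted_labels) -> dict:
    per_class = {}
    for cls in CLASSES:
        counts = confusion_counts(true_labels, predicted_labels, cls)
        per_class[cls] = {"counts": asdict(counts), "metrics": asdict(metrics(counts))}
    correct = sum(t == p for t, p in zip(true_labels, predicted_labels))
    return {
        "per_class": per_class,
        "overall_acc": 100.0 * correct / len(true_labels),
    }


@dataclass
class PipelineConfig:
    """Settings shared by cross-validation and the end-to-end runner."""

    epochs: int = 600
    batch_size: int = 64
    learning_rate: float = 0.01
    g: float = 3.2
    c: float = 2.9
    epsilon: float = 0.1
    folds: int = 10
    seed: int = 0
    # end-to-end synthetic source settings
    n_beats: int = 200
    mean_rr_s: float = 0.8
    noise: synthetic.NoiseSpec = field(default_factory=synthetic.NoiseSpec)


def cross_validate(beats, labels, k: int = 10, seed: int = 0,
                   pipeline_config: PipelineConfig | None = None) -> dict:
    """Stratified k-fold evaluation of the three systems.

    Per fold: train the CNN on raw beats and the SVR ensemble on the wavelet-
    packet features of the training part, predict mass functions on the test
    part, fuse and decide. Returns per-fold and fold-averaged reports.
    """
    cfg = pipeline_config or PipelineConfig()
    labels = list(labels)
    counts = {c: labels.count(c) for c in set(labels)}
    if min(counts.values()) < k:
        raise ValueError(f"need at least k={k} beats per class, got {counts}")
    X = np.vstack([b.samples for b in beats])
    y = np.asarray(labels)
    F = feat.feature_matrix(beats)  # per-beat features are fold-independent

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports = []
    all_decisions = []
    for fold_index, (tr, te) in enumerate(skf.split(X, y)):
        tc = TrainingConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                            learning_rate=cfg.learning_rate,
                            rng_seed=seed + fold_index)
        model = train_cnn(X[tr], y[tr], tc)
        ensemble = svr.train_svr_ensemble(F[tr], y[tr], g=cfg.g, c=cfg.c,
                                          epsilon=cfg.epsilon)
        cnn_mass = predict_mass_cnn(model, X[te])
        svr_mass = svr.predict_mass_svr(ensemble, F[te])
        fused_mass, fused_labels, fallbacks = fusion.fuse_streams(cnn_mass, svr_mass)
        preds = {
            "cnn": [fusion.decide(m) for m in cnn_mass],
            "svr": [fusion.decide(m) for m in svr_mass],
            "fused": fused_labels,
        }
        true = list(y[te])
        fold_reports.append({
            "fold_index": fold_index,
            "conflict_fallbacks": fallbacks,
            "systems": {s: _system_report(true, preds[s]) for s in SYSTEMS},
        })
        for j, i_te in enumerate(te):
            all_decisions.append({
                "beat_index": int(i_te), "fold": fold_index, "true": true[j],
                **{s: preds[s][j] for s in SYSTEMS},
                "cnn_mass": cnn_mass[j].tolist(),
                "svr_mass": svr_mass[j].tolist(),
                "fused_mass": fused_mass[j].tolist(),
            })

    averaged = {}
    for s in SYSTEMS:
        avg: dict = {"per_class": {}, "overall_acc": float(np.mean(
            [fr["systems"][s]["overall_acc"] for fr in fold_reports]))}
        for cls in CLASSES:
            avg["per_class"][cls] = {
                m: float(np.mean([
                    fr["systems"][s]["per_class"][cls]["metrics"][m]
                    for fr in fold_reports
                ]))
                for m in ("PPV", "SE", "SP", "Acc", "F1")
            }
        averaged[s] = avg
    return {"folds": fold_reports, "averaged": averaged,
            "decisions": all_decisions, "k": k, "seed": seed}


def match_to_ground_truth(detected: np.ndarray, true_r: np.ndarray,
                          true_labels, tol: int = 10):
    """Assign each detected R index the label of the nearest ground-truth R
    within ``tol`` samples; unmatched detections are dropped.

    Returns (kept detected indices, labels, n_matched_truth)."""
    detected = np.asarray(detected)
    true_r = np.asarray(true_r)
    kept, labels = [], []
    used = set()
    for d in detected:
        j = int(np.argmin(np.abs(true_r - d)))
        if abs(int(true_r[j]) - int(d)) <= tol and j not in used:
            kept.append(int(d))
            labels.append(true_labels[j])
            used.add(j)
    return np.asarray(kept, dtype=int), labels, len(used)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """End-to-end synthetic run: simulate -> preprocess -> detect -> segment
    -> both streams -> fuse -> evaluate. Writes report.json, decisions.csv
    and confusion_fused.csv under ``out_dir``; returns the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    uniform = {c: 1.0 / len(CLASSES) for c in CLASSES}
    rec = synthetic.generate_record(
        n_beats=config.n_beats, class_mix=uniform, mean_rr_s=config.mean_rr_s,
        noise=config.noise, rng_seed=config.seed,
    )
    clean = preprocess_signal(rec.signal)
    detected = qrs.detect_r_peaks(clean)
    matched, labels, _ = match_to_ground_truth(
        detected, rec.true_r_indices, rec.true_labels)
    # drop R peaks too close to the record edges before segmenting, so the
    # label list stays aligned with the emitted segments
    n = len(clean.samples)
    valid = [(r, lab) for r, lab in zip(matched, labels)
             if r >= 99 and r + 151 <= n]
    skipped = len(labels) - len(valid)
    matched = np.asarray([r for r, _ in valid], dtype=int)
    labels = [lab for _, lab in valid]
    segments, _ = qrs.segment_beats(clean, matched)

    report = cross_validate(segments, labels, k=config.folds,
                            seed=config.seed, pipeline_config=config)
    report["n_detected"] = int(detected.size)
    report["n_segments"] = len(segments)
    report["skipped_edge_beats"] = skipped

    decisions = report.pop("decisions")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    import pandas as pd

    pd.DataFrame(decisions).to_csv(out / "decisions.csv", index=False)
    fused_cm = confusion_matrix([d["true"] for d in decisions],
                                [d["fused"] for d in decisions])
    pd.DataFrame(fused_cm, index=list(CLASSES),
                 columns=list(CLASSES)).to_csv(out / "confusion_fused.csv")
    report["decisions"] = decisions
    return report
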