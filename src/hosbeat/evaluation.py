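"""Dataset splitting, sensitivity/specificity scoring, robustness runs.

Metrics follow the one-vs-rest convention: for each class, TP are that
class's beats correctly labelled, FN its beats labelled otherwise, FP other
beats labelled as the class, TN the rest.  Sensitivity = 100*TP/(TP+FN) and
specificity = 100*TN/(TN+FP) per class; pooled values micro-average the
counts over classes before taking the ratio (when the classes partition the
test set, pooled sensitivity equals overall accuracy).  Reported values are
computed at full precision and formatted to two decimals with
round-half-away-from-zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .beats import Beat, CLASSES, PerturbationSpec, perturb


def round2(x: float) -> float:
    """Round to 2 decimals, halves away from zero."""
    return math.copysign(math.floor(abs(x) * 100.0 + 0.5) / 100.0, x)


@dataclass(frozen=True)
class ClassCounts:
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts per class over one test set."""

    per_class: dict[str, ClassCounts]

    def total(self) -> int:
        c = next(iter(self.per_class.values()))
        return c.tp + c.tn + c.fp + c.fn


@dataclass(frozen=True)
class EvaluationReport:
    """Per-class and pooled sensitivity/specificity with their counts."""

    counts: ConfusionCounts
    per_class_se: dict[str, Optional[float]]
    per_class_sp: dict[str, Optional[float]]
    pooled_se: float
    pooled_sp: float
    macro_se: float
    metadata: dict = field(default_factory=dict)


def split(beats: Sequence[Beat], train_fraction: float = 0.6,
          seed: int = 0) -> tuple[list[Beat], list[Beat]]:
    """Per-class stratified random split.

    Each class contributes round-to-nearest(fraction * class size) beats to
    the training set (halves away from zero) and the remainder to the test
    set; selection within a class is uniform under ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[Beat] = []
    test: list[Beat] = []
    for label in CLASSES:
        idx = [i for i, b in enumerate(beats) if b.label == label]
        if not idx:
            warnings.warn(f"no beats of class {label} to split", stacklevel=2)
            continue
        n_train = int(math.floor(train_fraction * len(idx) + 0.5))
        perm = rng.permutation(len(idx))
        chosen = {idx[j] for j in perm[:n_train]}
        train.extend(beats[i] for i in idx if i in chosen)
        test.extend(beats[i] for i in idx if i not in chosen)
    return train, test


def split_counts(class_size: int, train_fraction: float = 0.6) -> tuple[int, int]:
    """(train, test) sizes for one class under the stratified rounding rule."""
    n_train = int(math.floor(train_fraction * class_size + 0.5))
    return n_train, class_size - n_train


def confusion(predictions, truths, classes=CLASSES) -> ConfusionCounts:
    """One-vs-rest confusion counts per class."""
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must have equal length")
    per = {}
    for cls in classes:
        tp = sum(1 for p, t in zip(predictions, truths) if t == cls and p == cls)
        fn = sum(1 for p, t in zip(predictions, truths) if t == cls and p != cls)
        fp = sum(1 for p, t in zip(predictions, truths) if t != cls and p == cls)
        tn = sum(1 for p, t in zip(predictions, truths) if t != cls and p != cls)
        per[cls] = ClassCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return ConfusionCounts(per_class=per)


def sensitivity(c: ClassCounts) -> Optional[float]:
    """100*TP/(TP+FN), two decimals; None when the class has no true beats."""
    if c.tp + c.fn == 0:
        return None
    return round2(100.0 * c.tp / (c.tp + c.fn))


def specificity(c: ClassCounts) -> Optional[float]:
    """100*TN/(TN+FP), two decimals; None when undefined."""
    if c.tn + c.fp == 0:
        return None
    return round2(100.0 * c.tn / (c.tn + c.fp))


def pooled_metrics(counts: ConfusionCounts) -> tuple[float, float]:
    """Micro-averaged (Se, Sp) in percent: counts summed over classes
    before the ratio."""
    tp = sum(c.tp for c in counts.per_class.values())
    fn = sum(c.fn for c in counts.per_class.values())
    tn = sum(c.tn for c in counts.per_class.values())
    fp = sum(c.fp for c in counts.per_class.values())
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("pooled metrics undefined: empty count sums")
    return round2(100.0 * tp / (tp + fn)), round2(100.0 * tn / (tn + fp))


def evaluate(predictions, truths, classes=None, metadata=None) -> EvaluationReport:
    """Full report from per-beat predictions and ground truth."""
    classes = tuple(classes) if classes is not None else tuple(
        c for c in CLASSES if c in set(truths))
    counts = confusion(predictions, truths, classes)
    se = {c: sensitivity(counts.per_class[c]) for c in classes}
    sp = {c: specificity(counts.per_class[c]) for c in classes}
    pooled_se, pooled_sp = pooled_metrics(counts)
    defined = [v for v in se.values() if v is not None]
    return EvaluationReport(
        counts=counts, per_class_se=se, per_class_sp=sp,
        pooled_se=pooled_se, pooled_sp=pooled_sp,
        macro_se=float(np.mean(defined)), metadata=metadata or {})


def score_classifier(clf, test_beats: Sequence[Beat], metadata=None) -> EvaluationReport:
    truths = [b.label for b in test_beats]
    preds = clf.predict(list(test_beats))
    return evaluate(list(preds), truths, metadata=metadata)


def robustness_run(trained, test_beats: Sequence[Beat],
                   spec: PerturbationSpec) -> tuple[EvaluationReport, EvaluationReport, dict]:
    """Evaluate the same trained classifier on clean and perturbed copies of
    one test set; report the Se/Sp deltas (perturbed minus baseline)."""
    if len(test_beats) == 0:
        raise ValueError("test set must be nonempty")
    baseline = score_classifier(trained, test_beats,
                                metadata={"perturbation": None})
    perturbed_beats = [perturb(b, spec, seed_offset=i)
                       for i, b in enumerate(test_beats)]
    perturbed = score_classifier(trained, perturbed_beats,
                                 metadata={"perturbation": spec})
    deltas = {
        "pooled_se": perturbed.pooled_se - baseline.pooled_se,
        "pooled_sp": perturbed.pooled_sp - baseline.pooled_sp,
        "macro_se": perturbed.macro_se - baseline.macro_se,
    }
    return baseline, perturbed, deltas


def order_sweep(beats: Sequence[Beat], orders: Sequence[int], seed: int = 0,
                train_fraction: float = 0.6, classifier_factory=None) -> list[dict]:
    """Re-run the full pipeline at several Hermite model orders on one fixed
    split; returns one row of pooled metrics per order."""
    from .classifier import CumulantHermite1NN
    if any(o < 1 for o in orders):
        raise ValueError("model orders must be >= 1")
    train_beats, test_beats = split(beats, train_fraction, seed)
    rows = []
    for order in orders:
        if classifier_factory is not None:
            clf = classifier_factory(order)
        else:
            clf = CumulantHermite1NN(n_coefficients=order, random_state=seed)
        clf.fit(train_beats)
        report = score_classifier(clf, test_beats)
        rows.append({"order": int(order), "pooled_se": report.pooled_se,
                     "pooled_sp": report.pooled_sp})
    return rows
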