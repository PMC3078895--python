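"""Readers and writers for the package's text artifact formats.

Formats (all UTF-8, '.' decimal separator, full float precision via
``repr``):

* beats CSV — header ``label,s000,...,s200``, one beat per row, amplitudes
  in mV (baseline offsets are materialised into the samples on export);
* predictions CSV — ``beat_id,label2,label3,label4,fused,agreement`` plus
  ``true_label`` when known;
* report CSV — one row per class
  (``beat_type,total,TP,TN,FP,FN,sensitivity,specificity``) plus an
  ``Average`` row with the pooled (micro-averaged) metrics, and a JSON twin
  carrying full-precision values;
* classifier JSON — versioned serialization of the trained 1-NN banks and
  configuration.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .beats import Beat, N_SAMPLES
from .classifier import CumulantHermite1NN, Prediction
from .evaluation import EvaluationReport
from .hermite import GAConfig

BEATS_HEADER = ["label"] + [f"s{i:03d}" for i in range(N_SAMPLES)]
CLASSIFIER_SCHEMA_VERSION = 1


def write_beats(beats: Sequence[Beat], path) -> None:
    """Write beats to CSV (header always present; empty list gives a
    header-only file)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(BEATS_HEADER)
        for b in beats:
            w.writerow([b.label if b.label is not None else ""]
                       + [repr(float(v)) for v in b.samples])


def read_beats(path) -> list[Beat]:
    """Read a beats CSV, validating shape and numeric content.

    Raises ValueError naming the offending row (1-based, counting the
    header as row 1) and cell on malformed input.
    """
    beats: list[Beat] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != BEATS_HEADER:
            raise ValueError(f"{path}: missing or malformed beats header")
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != N_SAMPLES + 1:
                raise ValueError(
                    f"{path}: row {rownum} has {len(row) - 1} samples, expected {N_SAMPLES}")
            label = row[0].strip() or None
            vals = np.empty(N_SAMPLES)
            for j, cell in enumerate(row[1:]):
                try:
                    vals[j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric sample at row {rownum}, column {BEATS_HEADER[j + 1]}"
                    ) from None
            beats.append(Beat(waveform=vals, label=label))
    return beats


def write_predictions(predictions: Sequence[Prediction], path,
                      true_labels: Optional[Sequence[str]] = None) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        header = ["beat_id", "label2", "label3", "label4", "fused", "agreement"]
        if true_labels is not None:
            header.append("true_label")
        w.writerow(header)
        for i, p in enumerate(predictions):
            row = [i, *p.per_order_labels, p.fused, p.agreement]
            if true_labels is not None:
                row.append(true_labels[i])
            w.writerow(row)


def write_report_csv(report: EvaluationReport, path) -> None:
    """Benchmark-table-shaped CSV: per-class counts/metrics + Average row."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["beat_type", "total", "TP", "TN", "FP", "FN",
                    "sensitivity", "specificity"])
        for cls, c in report.counts.per_class.items():
            se = report.per_class_se[cls]
            sp = report.per_class_sp[cls]
            w.writerow([cls, c.tp + c.fn, c.tp, c.tn, c.fp, c.fn,
                        f"{se:.2f}" if se is not None else "NA",
                        f"{sp:.2f}" if sp is not None else "NA"])
        w.writerow(["Average", "", "", "", "", "",
                    f"{report.pooled_se:.2f}", f"{report.pooled_sp:.2f}"])


def report_to_dict(report: EvaluationReport) -> dict:
    return {
        "per_class": {
            cls: {"TP": c.tp, "TN": c.tn, "FP": c.fp, "FN": c.fn,
                  "sensitivity": report.per_class_se[cls],
                  "specificity": report.per_class_sp[cls]}
            for cls, c in report.counts.per_class.items()
        },
        "pooled_sensitivity": report.pooled_se,
        "pooled_specificity": report.pooled_sp,
        "macro_sensitivity": report.macro_se,
        "metadata": {k: str(v) for k, v in report.metadata.items()},
    }


def write_report_json(report: EvaluationReport, path) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2))


def save_classifier(clf: CumulantHermite1NN, path) -> None:
    """Serialise a trained classifier (banks + config) to versioned JSON."""
    from sklearn.utils.validation import check_is_fitted
    check_is_fitted(clf, "banks_")
    ga = clf.ga_config if clf.ga_config is not None else None
    payload = {
        "schema_version": CLASSIFIER_SCHEMA_VERSION,
        "params": {
            "n_coefficients": clf.n_coefficients,
            "include_sigma": clf.include_sigma,
            "standardize": clf.standardize,
            "random_state": clf.random_state,
            "ga_config": asdict(ga) if ga is not None else None,
        },
        "labels": [str(l) for l in clf.bank_labels_],
        "banks": {str(o): clf.banks_[o].tolist() for o in clf.banks_},
    }
    if clf.standardize:
        payload["scalers"] = {str(o): [m.tolist(), s.tolist()]
                              for o, (m, s) in clf.scalers_.items()}
    Path(path).write_text(json.dumps(payload))


def load_classifier(path) -> CumulantHermite1NN:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != CLASSIFIER_SCHEMA_VERSION:
        raise ValueError(f"unsupported classifier schema: {payload.get('schema_version')}")
    params = payload["params"]
    ga = params.pop("ga_config")
    if ga is not None:
        ga["sigma_bounds"] = tuple(ga["sigma_bounds"])
        params["ga_config"] = GAConfig(**ga)
    clf = CumulantHermite1NN(**params)
    clf.bank_labels_ = np.asarray(payload["labels"], dtype=object)
    clf.banks_ = {int(o): np.asarray(v, dtype=float)
                  for o, v in payload["banks"].items()}
    clf.classes_ = np.unique(clf.bank_labels_.astype(str))
    if "scalers" in payload:
        clf.scalers_ = {int(o): (np.asarray(m), np.asarray(s))
                        for o, (m, s) in payload["scalers"].items()}
    return clf
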