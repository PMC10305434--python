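"""Per-genus confusion counts and the evaluation metrics sensitivity
(TPR), specificity (TNR), informedness (BM = TPR + TNR - 1) and accuracy.

Metrics with a zero denominator are reported as None (undefined), never
silently coerced to 0 or 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd


@dataclass
class GenusConfusion:
    genus: str
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(
    predictions: Mapping[str, set[str]],
    truth: Mapping[str, set[str]],
    genus: str,
) -> GenusConfusion:
    """Count TP/TN/FP/FN for one genus over a shared phage universe."""
    if set(predictions) != set(truth):
        diff = sorted(set(predictions) ^ set(truth))
        raise ValueError(f"prediction/truth phage ids differ: {diff[:10]}")
    tp = tn = fp = fn = 0
    for pid in truth:
        predicted = genus in predictions[pid]
        actual = genus in truth[pid]
        if predicted and actual:
            tp += 1
        elif predicted:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    return GenusConfusion(genus=genus, tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: GenusConfusion) -> dict[str, float | None]:
    """Sensitivity, specificity, informedness and accuracy from counts.

    TPR = TP/(TP+FN); TNR = TN/(TN+FP); BM = TPR + TNR - 1;
    accuracy = (TP+TN)/total.  A zero denominator makes the metric (and
    any metric derived from it) undefined (None).
    """
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    tnr = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    bm = tpr + tnr - 1.0 if (tpr is not None and tnr is not None) else None
    return {
        "sensitivity": tpr,
        "specificity": tnr,
        "informedness": bm,
        "accuracy": (c.tp + c.tn) / c.total,
    }


@dataclass
class EvalReport:
    """Per-genus confusion counts + metrics and the aggregate accuracy
    sum(TP+TN) / sum(TP+TN+FP+FN)."""

    rows: list[tuple[GenusConfusion, dict[str, float | None]]]
    aggregate_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        records = []
        for c, m in self.rows:
            records.append(
                {
                    "genus": c.genus,
                    "TP": c.tp,
                    "TN": c.tn,
                    "FP": c.fp,
                    "FN": c.fn,
                    **m,
                }
            )
        return pd.DataFrame(records)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.to_csv(path, sep="\t", index=False, na_rep="undefined")

    def write_json(self, path: str | Path) -> None:
        doc = {
            "aggregate_accuracy": self.aggregate_accuracy,
            "genera": {
                c.genus: {"TP": c.tp, "TN": c.tn, "FP": c.fp, "FN": c.fn, **m}
                for c, m in self.rows
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")


def aggregate(rows: list[GenusConfusion]) -> float:
    num = sum(c.tp + c.tn for c in rows)
    den = sum(c.total for c in rows)
    if den == 0:
        raise ValueError("no confusion counts to aggregate")
    return num / den


def build_report(
    predictions: Mapping[str, set[str]],
    truth: Mapping[str, set[str]],
    genera: list[str] | set[str],
) -> EvalReport:
    rows = []
    confusions = []
    for genus in sorted(genera):
        c = confusion_counts(predictions, truth, genus)
        confusions.append(c)
        rows.append((c, metrics(c)))
    return EvalReport(rows=rows, aggregate_accuracy=aggregate(confusions))


def evaluate_suite(
    suite,
    test_matrix: pd.DataFrame,
    truth_labels,
    decision_threshold: float = 0.5,
    genera: list[str] | None = None,
) -> EvalReport:
    """Predict every test phage with the tree suite and tabulate the
    per-genus confusion counts and metrics."""
    from .hosttrees import predict_matrix

    if test_matrix.empty:
        raise ValueError("empty test set")
    predictions = predict_matrix(test_matrix, suite, decision_threshold)
    truth = {pid: truth_labels.genera_of(pid) for pid in test_matrix.index}
    if genera is None:
        genera = sorted(suite.trees)
    return build_report(predictions, truth, genera)
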