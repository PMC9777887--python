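"""Confusion matrices and sensitivity/specificity/accuracy metrics.

Metrics follow the one-vs-rest definitions: per class, sensitivity =
TP/(TP+FN), specificity = TN/(FP+TN), accuracy = (TP+TN)/total, reported
in percent.  Headline values are unweighted macro-averages over classes.
Unassigned samples (margin-rule failures) count as false negatives for
their true class and never as false positives for any class.

Partition naming mirrors chemometric practice: SEC/SPC/ACC for the
calibration set, SECV/SPCV/ACCV for cross-validation, SEP/SPP/ACP for the
prediction set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import LabelError, SpecfuseError
from .fusion import UNASSIGNED
from .io import ClassAlphabet

_PARTITION_SUFFIX = {"calibration": "C", "cv": "CV", "prediction": "P"}


@dataclass
class ConfusionMatrix:
    """Counts with true classes as rows and an extra UNASSIGNED column."""

    counts: np.ndarray  # k x (k + 1)
    alphabet: ClassAlphabet

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        cols = list(self.alphabet.names) + [UNASSIGNED]
        return pd.DataFrame(self.counts, index=list(self.alphabet.names), columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="true")


def confusion(
    true: np.ndarray, assigned: np.ndarray, alphabet: ClassAlphabet
) -> ConfusionMatrix:
    """Exact tabulation of true vs assigned labels (or UNASSIGNED)."""
    true = np.asarray(true, dtype=object)
    assigned = np.asarray(assigned, dtype=object)
    if true.size != assigned.size:
        raise SpecfuseError("true and assigned labels differ in length")
    k = len(alphabet)
    counts = np.zeros((k, k + 1), dtype=int)
    for t, a in zip(true, assigned):
        i = alphabet.index(str(t))
        if str(a) == UNASSIGNED:
            j = k
        else:
            j = alphabet.index(str(a))
        counts[i, j] += 1
    return ConfusionMatrix(counts, alphabet)


@dataclass
class MetricFragment:
    """Per-class and macro sensitivity/specificity/accuracy, in percent."""

    per_class: pd.DataFrame
    sensitivity: float
    specificity: float
    accuracy: float


def metrics(cm: ConfusionMatrix) -> MetricFragment:
    """One-vs-rest metrics from a confusion matrix.

    Classes with zero true samples have undefined sensitivity; they are
    excluded from the macro mean with a warning.
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise SpecfuseError("empty confusion matrix")
    k = len(cm.alphabet)
    rows = []
    for c in range(k):
        tp = counts[c, c]
        fn = counts[c].sum() - tp  # includes UNASSIGNED mass
        fp = counts[:, c].sum() - tp
        tn = total - tp - fn - fp
        n_true = tp + fn
        sens = 100.0 * tp / n_true if n_true else np.nan
        spec = 100.0 * tn / (fp + tn) if (fp + tn) else np.nan
        acc = 100.0 * (tp + tn) / total
        rows.append((cm.alphabet.names[c], sens, spec, acc, int(n_true)))
    df = pd.DataFrame(
        rows, columns=["class", "sensitivity", "specificity", "accuracy", "n_true"]
    )
    if df["sensitivity"].isna().any():
        empty = df.loc[df["sensitivity"].isna(), "class"].tolist()
        warnings.warn(
            f"class(es) {empty} have no true samples; excluded from macro "
            "sensitivity", stacklevel=2,
        )
    return MetricFragment(
        per_class=df,
        sensitivity=float(np.nanmean(df["sensitivity"])),
        specificity=float(np.nanmean(df["specificity"])),
        accuracy=float(df["accuracy"].mean()),
    )


@dataclass
class PerformanceReport:
    """Metrics for up to three partitions of one model.

    ``partitions`` maps partition name ("calibration", "cv", "prediction")
    to a :class:`MetricFragment`; ``summary_row`` flattens them into the
    SEC/SPC/ACC, SECV/SPCV/ACCV, SEP/SPP/ACP naming.
    """

    model_name: str
    partitions: dict[str, MetricFragment] = field(default_factory=dict)
    confusions: dict[str, ConfusionMatrix] = field(default_factory=dict)

    def add(self, partition: str, cm: ConfusionMatrix) -> MetricFragment:
        if partition not in _PARTITION_SUFFIX:
            raise SpecfuseError(f"unknown partition {partition!r}")
        frag = metrics(cm)
        self.partitions[partition] = frag
        self.confusions[partition] = cm
        return frag

    def summary_row(self) -> dict[str, float]:
        row: dict[str, float] = {"model": self.model_name}
        for part, suffix in _PARTITION_SUFFIX.items():
            frag = self.partitions.get(part)
            if frag is None:
                continue
            row[f"SE{suffix}"] = round(frag.sensitivity, 2)
            row[f"SP{suffix}"] = round(frag.specificity, 2)
            row[f"AC{suffix}"] = round(frag.accuracy, 2)
        return row

    def to_json(self, path) -> None:
        payload = {"model": self.model_name, "partitions": {}}
        for part, frag in self.partitions.items():
            payload["partitions"][part] = {
                "sensitivity": frag.sensitivity,
                "specificity": frag.specificity,
                "accuracy": frag.accuracy,
                "per_class": frag.per_class.to_dict(orient="records"),
            }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def report_table(reports: list[PerformanceReport]) -> pd.DataFrame:
    """One row per model with SEC/SPC/ACC-style columns, two decimals."""
    return pd.DataFrame([r.summary_row() for r in reports])
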