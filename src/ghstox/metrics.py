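"""Confusion-matrix-derived multiclass classification metrics.

The headline figure is the non-error rate (NER), the chemometric
convention: the arithmetic mean of per-class sensitivities — NOT overall
accuracy — so duplicating every member of one class leaves it unchanged.
ER = 1 - NER exactly.  Per class g:

* sensitivity_g = correctly assigned members of g / true members of g
* specificity_g = non-g objects not assigned to g / non-g objects
* precision_g   = correctly assigned members of g / objects assigned to g
  (undefined when nothing is assigned to g; reported as NaN and excluded
  from aggregates, never coerced to 0)
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import ROMAN


class MetricsError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """G x G counts; rows = true class, columns = assigned class."""

    counts: np.ndarray
    class_order: list[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        G = len(self.class_order)
        if self.counts.shape != (G, G):
            raise MetricsError(
                f"counts shape {self.counts.shape} does not match {G} classes"
            )
        if (self.counts < 0).any():
            raise MetricsError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    class_order: Sequence[int],
) -> ConfusionMatrix:
    """Tally counts[g, h] = #{i : true=g, predicted=h}."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise MetricsError("true/predicted length mismatch")
    if y.size == 0:
        raise MetricsError("empty label sequences")
    order = list(class_order)
    index = {c: i for i, c in enumerate(order)}
    unknown = set(y.tolist()) | set(p.tolist())
    unknown -= set(order)
    if unknown:
        raise MetricsError(f"labels {sorted(unknown)} not in class_order {order}")
    G = len(order)
    counts = np.zeros((G, G), dtype=int)
    for t, q in zip(y.tolist(), p.tolist()):
        counts[index[t], index[q]] += 1
    return ConfusionMatrix(counts=counts, class_order=order)


@dataclass
class ClassMetrics:
    ner: float
    er: float
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray  # NaN where undefined
    class_order: list[int]

    def to_dict(self) -> dict:
        return {
            "ner": self.ner,
            "er": self.er,
            "class_order": [ROMAN.get(c, str(c)) for c in self.class_order],
            "sensitivity": [float(v) for v in self.sensitivity],
            "specificity": [float(v) for v in self.specificity],
            "precision": [None if math.isnan(v) else float(v) for v in self.precision],
        }


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Derive NER/ER and the per-class rates from a confusion matrix.

    Every class must have at least one true member; otherwise its
    sensitivity is undefined and the call errors.
    """
    C = cm.counts.astype(float)
    row = C.sum(axis=1)
    col = C.sum(axis=0)
    if (row == 0).any():
        empty = cm.class_order[int(np.flatnonzero(row == 0)[0])]
        raise MetricsError(f"class {ROMAN.get(empty, empty)} has no true objects")
    diag = np.diag(C)
    sensitivity = diag / row
    G = C.shape[0]
    specificity = np.empty(G)
    for g in range(G):
        others = np.arange(G) != g
        non_g = row[others].sum()
        rejected = (row[others] - C[others, g]).sum()
        specificity[g] = rejected / non_g if non_g > 0 else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), np.nan)
    ner = float(sensitivity.mean())
    return ClassMetrics(
        ner=ner,
        er=1.0 - ner,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        class_order=list(cm.class_order),
    )


def metrics_table(
    fit: ClassMetrics, cv: ClassMetrics, external: ClassMetrics
) -> str:
    """Three-row summary (Fitting / cv / External) with 2-decimal formatting.

    Column order: NER, ER, per-class sensitivity, per-class specificity.
    """
    if not (fit.class_order == cv.class_order == external.class_order):
        raise MetricsError("class order differs between the three metric sets")
    romans = [ROMAN.get(c, str(c)) for c in fit.class_order]
    header = (
        ["", "NER", "ER"]
        + [f"Sens {r}" for r in romans]
        + [f"Spec {r}" for r in romans]
    )
    rows = []
    for name, m in (("Fitting", fit), ("cv", cv), ("External", external)):
        rows.append(
            [name, f"{m.ner:.2f}", f"{m.er:.2f}"]
            + [f"{v:.2f}" for v in m.sensitivity]
            + [f"{v:.2f}" for v in m.specificity]
        )
    widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
    lines = []
    for r in [header] + rows:
        lines.append("  ".join(cell.rjust(w) for cell, w in zip(r, widths)))
    return "\n".join(lines) + "\n"


def parse_metrics_table(text: str) -> dict[str, dict[str, list[float] | float]]:
    """Parse the text produced by :func:`metrics_table` back into numbers."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = re.split(r"\s{2,}", lines[0].strip())
    n_classes = sum(1 for h in header if h.startswith("Sens"))
    out: dict[str, dict] = {}
    for ln in lines[1:]:
        cells = re.split(r"\s{2,}", ln.strip())
        name = cells[0]
        nums = [float(c) for c in cells[1:]]
        out[name] = {
            "ner": nums[0],
            "er": nums[1],
            "sensitivity": nums[2 : 2 + n_classes],
            "specificity": nums[2 + n_classes : 2 + 2 * n_classes],
        }
    return out


def metrics_report_json(
    fit: ClassMetrics, cv: ClassMetrics, external: ClassMetrics
) -> str:
    return json.dumps(
        {"fitting": fit.to_dict(), "cv": cv.to_dict(), "external": external.to_dict()},
        indent=2,
        sort_keys=True,
    )
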