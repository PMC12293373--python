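"""Classification metrics: confusion counts, SEN/SPE/ACC and ROC-AUC.

The AUC is computed exactly as the Mann–Whitney probability — the fraction
of (positive, negative) pairs where the positive scores higher, with ties
credited 0.5 — via midranks rather than trapezoidal interpolation over
thresholds. At the sample sizes of episodic evaluation exactness matters
more than speed, and the rank form is testable against a brute-force pair
count. Sensitivity and specificity with an empty denominator are reported
as ``None`` (JSON ``null``), never silently as zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedMetricError

REPORT_SCHEMA_VERSION = 1


@dataclass
class MetricsReport:
    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float | None
    spe: float | None
    auc: float | None

    def to_dict(self) -> dict:
        return {"schema_version": REPORT_SCHEMA_VERSION, "n": self.n,
                "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "acc": self.acc, "sen": self.sen, "spe": self.spe,
                "auc": self.auc}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def confusion(results: Sequence) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) from QueryResult-like objects (true/predicted labels)."""
    tp = fp = tn = fn = 0
    for r in results:
        if r.true_label == 1:
            tp += r.predicted_label == 1
            fn += r.predicted_label == 0
        else:
            tn += r.predicted_label == 0
            fp += r.predicted_label == 1
    return tp, fp, tn, fn


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Exact ROC-AUC (Mann–Whitney U / (n_pos · n_neg), ties count 0.5).

    Raises :class:`UndefinedMetricError` when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"ROC-AUC undefined: {n_pos} positive / {n_neg} negative labels")
    ranks = rankdata(scores)  # midranks give the 0.5 tie credit exactly
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def summarize(results: Sequence) -> MetricsReport:
    """Compose confusion counts, SEN/SPE/ACC and AUC into one report.

    AUC uses each result's continuous score; it is ``None`` when the query
    set contains one class only (the other metrics are still reported).
    """
    tp, fp, tn, fn = confusion(results)
    n = tp + fp + tn + fn
    if n == 0:
        raise UndefinedMetricError("no query results to summarize")
    try:
        auc = roc_auc([r.score for r in results],
                      [r.true_label for r in results])
    except UndefinedMetricError:
        auc = None
    return MetricsReport(
        n=n, tp=tp, fp=fp, tn=tn, fn=fn,
        acc=(tp + tn) / n,
        sen=tp / (tp + fn) if tp + fn > 0 else None,
        spe=tn / (tn + fp) if tn + fp > 0 else None,
        auc=auc)
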