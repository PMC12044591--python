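"""Thermogram-level multilabel performance metrics.

Ground truth is the set of material classes present in each thermogram (not
per-spectrum), matching how mixture datasets are generated.  Per-class
precision/recall/F1 are computed from sample-level TP/FP/FN counts; the
headline numbers are the macro-averaged F1 and the Hamming accuracy — the
average fraction of classes (presence/absence) predicted correctly per
sample, i.e. 1 - Hamming loss.  BLANK is never a metric class: an empty
label set *is* the blank prediction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import ValidationError

__all__ = ["ClassMetrics", "EvalReport", "evaluate", "benchmark"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if math.isnan(p) or math.isnan(r):
            return math.nan
        return 2 * p * r / (p + r) if (p + r) else 0.0


@dataclass
class EvalReport:
    per_class: dict[str, ClassMetrics]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    hamming_accuracy: float
    subset_accuracy: float
    n_samples: int
    undefined_classes: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": cls,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
            }
            for cls, m in self.per_class.items()
        ]
        return pd.DataFrame(rows).set_index("class")

    def summary(self) -> dict[str, float]:
        return {
            "precision": self.macro_precision,
            "recall": self.macro_recall,
            "f1": self.macro_f1,
            "accuracy": self.hamming_accuracy,
        }


def evaluate(predictions, truths, classes) -> EvalReport:
    """Score run-level predicted label sets against ground-truth sets.

    Classes that are never present and never predicted have undefined
    metrics; they are excluded from the macro averages and logged.
    """
    if len(predictions) != len(truths):
        raise ValidationError("predictions and truths must have equal length")
    classes = [c for c in classes if c != "BLANK"]
    n_classes = len(classes)
    if n_classes == 0:
        raise ValidationError("no metric classes given")
    predictions = [set(p) & set(classes) for p in predictions]
    truths = [set(t) & set(classes) for t in truths]

    per_class: dict[str, ClassMetrics] = {}
    for cls in classes:
        tp = sum(1 for p, t in zip(predictions, truths) if cls in p and cls in t)
        fp = sum(1 for p, t in zip(predictions, truths) if cls in p and cls not in t)
        fn = sum(1 for p, t in zip(predictions, truths) if cls not in p and cls in t)
        per_class[cls] = ClassMetrics(tp=tp, fp=fp, fn=fn)

    undefined = tuple(
        cls for cls, m in per_class.items() if m.tp + m.fp + m.fn == 0
    )
    if undefined:
        logger.info("classes never present nor predicted (excluded from macro): %s",
                    ", ".join(undefined))

    def macro(values: list[float]) -> float:
        defined = [v for v in values if not math.isnan(v)]
        return float(np.mean(defined)) if defined else math.nan

    scored = {c: m for c, m in per_class.items() if c not in undefined}
    # precision/recall may be NaN for a class that is present but never
    # predicted (or vice versa); treat those counts as 0 in the macro average
    # so a never-predicted class drags recall down rather than vanishing.
    precisions = [0.0 if math.isnan(m.precision) else m.precision for m in scored.values()]
    recalls = [0.0 if math.isnan(m.recall) else m.recall for m in scored.values()]
    f1s = [0.0 if math.isnan(m.f1) else m.f1 for m in scored.values()]

    n = len(predictions)
    if n:
        hamming = float(
            np.mean([1.0 - len(p ^ t) / n_classes for p, t in zip(predictions, truths)])
        )
        subset = float(np.mean([p == t for p, t in zip(predictions, truths)]))
    else:
        hamming = subset = math.nan

    return EvalReport(
        per_class=per_class,
        macro_precision=macro(precisions),
        macro_recall=macro(recalls),
        macro_f1=macro(f1s),
        hamming_accuracy=hamming,
        subset_accuracy=subset,
        n_samples=n,
        undefined_classes=undefined,
    )


def benchmark(identifiers: dict, runs, manifest: list[dict], classes) -> pd.DataFrame:
    """Run every identifier over every thermogram and tabulate the metrics.

    ``identifiers`` maps a display name to a callable ``run -> set of class
    labels``.  A failure on a thermogram is recorded and that thermogram is
    skipped for that identifier only.  Returns one row per identifier with
    columns precision / recall / f1 / accuracy (+ skip count).
    """
    truths_all = [set(record["components"]) for record in manifest]
    if len(truths_all) != len(runs):
        raise ValidationError("manifest length does not match number of runs")
    rows = []
    for name, identify in identifiers.items():
        preds, truths, skipped = [], [], 0
        for run, truth in zip(runs, truths_all):
            try:
                preds.append(set(identify(run)))
                truths.append(truth)
            except Exception:  # noqa: BLE001 — identifier bug must not kill the benchmark
                logger.exception("identifier %r failed on a thermogram; skipping", name)
                skipped += 1
        report = evaluate(preds, truths, classes)
        rows.append({"identifier": name, **report.summary(), "skipped": skipped})
    return pd.DataFrame(rows).set_index("identifier")
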