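"""Open-set recognition: flagging samples from species outside the trained set.

A closed-set softmax classifier must place every sample somewhere, but its
maximum softmax probability drops on inputs unlike anything it trained on.
The rule is strict confidence thresholding: a sample whose top probability is
below the threshold is flagged an "untested species"; at or above, a "tested
species".  The sweep evaluates this rule over a threshold grid on a mixture
of seen test samples and held-out unseen-species samples, with "untested" as
the positive class for precision/recall/F1 (both orientations are exported).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .classify.protocol import PredictionResult

__all__ = ["ThresholdSweepRow", "flag_unknown", "sweep", "summarize_unseen",
           "sweep_table", "default_thresholds"]


@dataclasses.dataclass(frozen=True)
class ThresholdSweepRow:
    """Unseen-detection metrics at one threshold (positive class: untested)."""

    threshold: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if self.precision + self.recall > 0:
            expect = 2 * self.precision * self.recall / (self.precision + self.recall)
            if abs(self.f1 - expect) > 1e-9:
                raise ValueError("f1 is not the harmonic mean of precision and recall")


def flag_unknown(prediction: PredictionResult, threshold: float = 0.9) -> str:
    """"untested" iff confidence is strictly below the threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    conf = prediction.confidence
    if not 0.0 <= conf <= 1.0:
        raise ValueError(f"confidence {conf} outside [0, 1]")
    return "untested" if conf < threshold else "tested"


def _confidences(predictions: Sequence[PredictionResult | float]) -> np.ndarray:
    vals = [p if isinstance(p, (int, float)) else p.confidence for p in predictions]
    arr = np.asarray(vals, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("confidences must lie in [0, 1]")
    return arr


def sweep(predictions_seen: Sequence[PredictionResult | float],
          predictions_unseen: Sequence[PredictionResult | float],
          thresholds: Sequence[float]) -> list[ThresholdSweepRow]:
    """Evaluate unseen-species detection over a threshold grid.

    At each threshold: unseen samples flagged untested are true positives,
    seen samples flagged untested are false positives, unseen flagged tested
    are false negatives, seen flagged tested are true negatives.  Undefined
    ratios (0/0) are reported as 0.
    """
    if not len(predictions_seen) or not len(predictions_unseen):
        raise ValueError("both prediction lists must be non-empty")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    seen = _confidences(predictions_seen)
    unseen = _confidences(predictions_unseen)
    rows = []
    for t in thresholds:
        tp = int((unseen < t).sum())
        fn = int(len(unseen) - tp)
        fp = int((seen < t).sum())
        tn = int(len(seen) - fp)
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if (precision + recall) else 0.0)
        rows.append(ThresholdSweepRow(float(t), precision, recall, f1,
                                      tp, fp, fn, tn))
    return rows


def sweep_table(rows: Sequence[ThresholdSweepRow]) -> pd.DataFrame:
    """Sweep rows as a DataFrame, including the tested-positive orientation."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    # tested-as-positive orientation: swap the confusion-cell roles
    prec_t = df["tn"] / (df["tn"] + df["fn"]).replace(0, np.nan)
    rec_t = df["tn"] / (df["tn"] + df["fp"]).replace(0, np.nan)
    df["precision_tested"] = prec_t.fillna(0.0)
    df["recall_tested"] = rec_t.fillna(0.0)
    denom = (df["precision_tested"] + df["recall_tested"]).replace(0, np.nan)
    df["f1_tested"] = (2 * df["precision_tested"] * df["recall_tested"] / denom).fillna(0.0)
    return df


def summarize_unseen(predictions_unseen: Sequence[PredictionResult | float]) -> float:
    """Mean confidence over unseen-species predictions."""
    conf = _confidences(predictions_unseen)
    if conf.size == 0:
        raise ValueError("need at least one prediction")
    return float(conf.mean())


def default_thresholds(start: float = 0.5, stop: float = 1.0,
                       step: float = 0.05) -> list[float]:
    n = int(round((stop - start) / step)) + 1
    return [round(start + i * step, 10) for i in range(n)]
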