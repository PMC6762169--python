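"""Evaluation of a binary LVSI prediction as a diagnostic test.

The 2x2 cross-tabulation of prediction against pathological truth gives
TP/FP/FN/TN, from which the five standard test metrics follow:

    sensitivity = TP/(TP+FN)      specificity = TN/(TN+FP)
    PPV = TP/(TP+FP)              NPV = TN/(TN+FN)
    accuracy = (TP+TN)/(TP+FP+FN+TN)

A metric whose denominator is zero is *undefined* and reported as such,
never silently zero.  Reports format proportions as percentages to one
decimal place; internal values stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .select import _as_bool_labels

__all__ = ["ConfusionMetrics", "confusion", "from_counts", "incidence",
           "format_percent", "write_report"]


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


@dataclass(frozen=True)
class ConfusionMetrics:
    """TP/FP/FN/TN counts and derived diagnostic proportions.

    Metric attributes are ``None`` when their denominator is zero.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float | None:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return _ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float | None:
        return _ratio(self.tp + self.tn, self.n)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
        }


def from_counts(tp: int, fp: int, fn: int, tn: int) -> ConfusionMetrics:
    """Build metrics directly from a printed cross-tabulation."""
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if tp + fp + fn + tn == 0:
        raise ValueError("empty confusion table")
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def confusion(predicted, truth) -> ConfusionMetrics:
    """Cross-tabulate a prediction against truth over the same samples."""
    pred = _as_bool_labels(predicted)
    tru = _as_bool_labels(truth)
    if isinstance(pred, pd.Series) and isinstance(tru, pd.Series):
        if set(pred.index) != set(tru.index):
            raise ValueError("predicted and truth cover different samples")
        tru = tru.reindex(pred.index)
    elif len(pred) != len(tru):
        raise ValueError("predicted and truth have different lengths")
    p = pred.to_numpy()
    t = tru.to_numpy()
    return from_counts(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()), tn=int((~p & ~t).sum()),
    )


def incidence(labels, subset=None) -> float:
    """Proportion of positives among ``subset`` (default: all samples)."""
    lab = _as_bool_labels(labels)
    if subset is not None:
        lab = lab.loc[list(subset)] if isinstance(lab, pd.Series) else lab[subset]
    if len(lab) == 0:
        raise ValueError("empty subset")
    return float(lab.sum() / len(lab))


def format_percent(value: float | None) -> str:
    """One-decimal percent string; undefined metrics print as 'undefined'."""
    return "undefined" if value is None else f"{100 * value:.1f}%"


def write_report(metrics: ConfusionMetrics, path,
                 header_comment: str | None = None) -> None:
    """Tab-delimited 2x2 table plus metrics block."""
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    lines += [
        "clustering\tLVSI-positive\tLVSI-negative\tmetric",
        f"group_A\t{metrics.tp}\t{metrics.fp}\t{format_percent(metrics.ppv)} (PPV)",
        f"group_B\t{metrics.fn}\t{metrics.tn}\t{format_percent(metrics.npv)} (NPV)",
        (f"\t{format_percent(metrics.sensitivity)} (sensitivity)"
         f"\t{format_percent(metrics.specificity)} (specificity)"
         f"\t{format_percent(metrics.accuracy)} (accuracy)"),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
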