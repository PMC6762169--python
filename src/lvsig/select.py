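"""Three-stage differential-expression gene selection.

The signature is the set of genes that survive, in order:

1. **Detection filter** — a gene is excluded when its below-detection
   fraction exceeds a strict threshold in either class.  With the default
   threshold of 0.25 and class sizes 26/62 this excludes exactly the genes
   missing in >=7 of 26 positives or >=16 of 62 negatives.
2. **Mean-difference filter** — mean log2 ratio over detected values in
   the LVSI-positive class minus that in the negative class must be at
   least ``min_mean_diff`` (signed: only genes up-shifted in positives
   qualify; set ``signed=False`` to use the absolute difference).
3. **Student's t-test** — pooled-variance two-sample t on detected
   values, two-sided p from the t distribution with n1+n2-2 df;
   selected when p < ``alpha`` (strict).

All statistics are complete-case per gene: below-detection cells never
enter a mean, variance or test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "SelectionParams",
    "SelectionResult",
    "detection_filter",
    "mean_diff_filter",
    "two_sample_t",
    "select_signature",
    "write_selection",
    "write_signature",
]


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds of the three selection stages.

    ``max_missing_frac_pos``/``neg`` are strict upper bounds on the
    below-detection fraction per class (default 0.25).  ``min_mean_diff``
    is in log2 units (default 1).  ``alpha`` is the strict t-test p-value
    threshold (default 0.005).  ``equal_var=False`` switches to the
    Welch test.
    """

    max_missing_frac_pos: float = 0.25
    max_missing_frac_neg: float = 0.25
    min_mean_diff: float = 1.0
    alpha: float = 0.005
    signed: bool = True
    equal_var: bool = True

    def __post_init__(self) -> None:
        for name in ("max_missing_frac_pos", "max_missing_frac_neg"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.min_mean_diff < 0:
            raise ValueError(f"min_mean_diff must be >= 0, got {self.min_mean_diff}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class SelectionResult:
    """Per-gene filter outcomes and the ordered selected gene list.

    ``table`` is indexed by gene id with columns ``n_detected_pos``,
    ``n_detected_neg``, ``mean_pos``, ``mean_neg``, ``mean_diff``,
    ``t_stat``, ``p_value``, ``passed_detection``, ``passed_diff``,
    ``passed_test``, ``selected``.  ``signature`` is the selected gene
    list sorted by ascending p-value, ties broken by gene id.
    """

    table: pd.DataFrame
    signature: list[str]
    params: SelectionParams


def _split_labels(matrix: ExpressionMatrix, labels: pd.Series):
    labels = labels.reindex(matrix.sample_ids)
    if labels.isna().any():
        sid = labels.index[labels.isna()][0]
        raise ValueError(f"no LVSI label for sample {sid!r}")
    pos = labels.astype(bool).to_numpy()
    if pos.all() or not pos.any():
        raise ValueError("labels must contain both classes")
    return pos


def _as_bool_labels(labels) -> pd.Series:
    """Accept a boolean Series or a SampleTable-style 'positive'/'negative' one."""
    s = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    if s.dtype == object:
        return s.map({"positive": True, "negative": False})
    return s.astype(bool)


def _class_stats(matrix: ExpressionMatrix, pos: np.ndarray):
    """Masked per-gene per-class detected counts, means and sum of squares."""
    vals = matrix.values.to_numpy()
    det = ~matrix.below_detection.to_numpy()
    x = np.where(det, vals, 0.0)
    out = {}
    for cls, sel in (("pos", pos), ("neg", ~pos)):
        d = det[:, sel]
        n = d.sum(axis=1)
        s = x[:, sel].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
            centered = np.where(d, vals[:, sel] - mean[:, None], 0.0)
            ss = np.einsum("ij,ij->i", centered, centered)
        out[cls] = (n, mean, ss)
    return out


def detection_filter(matrix: ExpressionMatrix, labels, params: SelectionParams
                     ) -> pd.Series:
    """Per-gene detection-filter flag.

    A gene fails iff its below-detection fraction among positives exceeds
    ``max_missing_frac_pos`` or among negatives exceeds
    ``max_missing_frac_neg`` (both strict).
    """
    pos = _split_labels(matrix, _as_bool_labels(labels))
    mask = matrix.below_detection.to_numpy()
    frac_pos = mask[:, pos].mean(axis=1)
    frac_neg = mask[:, ~pos].mean(axis=1)
    passed = ~((frac_pos > params.max_missing_frac_pos)
               | (frac_neg > params.max_missing_frac_neg))
    return pd.Series(passed, index=matrix.values.index, name="passed_detection")


def mean_diff_filter(matrix: ExpressionMatrix, labels, params: SelectionParams
                     ) -> pd.DataFrame:
    """Per-gene class means over detected values and the mean-difference flag."""
    pos = _split_labels(matrix, _as_bool_labels(labels))
    st = _class_stats(matrix, pos)
    (n1, m1, _), (n2, m2, _) = st["pos"], st["neg"]
    diff = m1 - m2
    crit = diff if params.signed else np.abs(diff)
    with np.errstate(invalid="ignore"):
        passed = (crit >= params.min_mean_diff) & (n1 > 0) & (n2 > 0)
    return pd.DataFrame(
        {
            "n_detected_pos": n1,
            "n_detected_neg": n2,
            "mean_pos": m1,
            "mean_neg": m2,
            "mean_diff": diff,
            "passed_diff": passed,
        },
        index=matrix.values.index,
    )


def two_sample_t(matrix: ExpressionMatrix, labels, params: SelectionParams
                 ) -> pd.DataFrame:
    """Per-gene two-sample t statistic and two-sided p over detected values.

    Pooled-variance by default (``equal_var=True``), Welch otherwise.
    Degenerate genes: with zero within-class variance the statistic is
    +/-inf (p -> 0) for unequal means and 0 (p = 1) for equal means.  A
    gene with fewer than two detected values in either class is
    untestable: t and p are NaN and ``passed_test`` is False.
    """
    pos = _split_labels(matrix, _as_bool_labels(labels))
    st = _class_stats(matrix, pos)
    (n1, m1, ss1), (n2, m2, ss2) = st["pos"], st["neg"]
    testable = (n1 >= 2) & (n2 >= 2)
    diff = m1 - m2
    with np.errstate(invalid="ignore", divide="ignore"):
        if params.equal_var:
            df = n1 + n2 - 2.0
            sp2 = (ss1 + ss2) / np.maximum(df, 1)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        else:
            v1 = ss1 / np.maximum(n1 - 1, 1) / n1
            v2 = ss2 / np.maximum(n2 - 1, 1) / n2
            se = np.sqrt(v1 + v2)
            with np.errstate(invalid="ignore", divide="ignore"):
                df = (v1 + v2) ** 2 / (
                    v1**2 / np.maximum(n1 - 1, 1) + v2**2 / np.maximum(n2 - 1, 1)
                )
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
        # zero-variance conventions: |t|=inf => p=0; t=0 with equal means => p=1
        p = np.where(np.isinf(t), 0.0, p)
        p = np.where((se == 0) & (diff == 0), 1.0, p)
    t = np.where(testable, t, np.nan)
    p = np.where(testable, p, np.nan)
    passed = testable & (p < params.alpha)
    return pd.DataFrame(
        {"t_stat": t, "p_value": p, "passed_test": passed},
        index=matrix.values.index,
    )


def select_signature(matrix: ExpressionMatrix, labels,
                     params: SelectionParams | None = None) -> SelectionResult:
    """Apply the three filters in order and assemble the signature.

    ``labels`` may be a boolean Series indexed by sample id or a string
    Series with levels ``positive``/``negative``.
    """
    params = params or SelectionParams()
    det = detection_filter(matrix, labels, params)
    md = mean_diff_filter(matrix, labels, params)
    tt = two_sample_t(matrix, labels, params)
    table = pd.concat([md[["n_detected_pos", "n_detected_neg", "mean_pos",
                           "mean_neg", "mean_diff"]],
                       tt[["t_stat", "p_value"]],
                       det, md[["passed_diff"]], tt[["passed_test"]]], axis=1)
    table["selected"] = (table["passed_detection"] & table["passed_diff"]
                         & table["passed_test"])
    sel = table[table["selected"]]
    order = sel.assign(_gid=sel.index).sort_values(["p_value", "_gid"])
    return SelectionResult(table=table, signature=list(order.index), params=params)


def write_selection(result: SelectionResult, path,
                    header_comment: str | None = None) -> None:
    """Tab-delimited per-gene selection table."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        result.table.to_csv(fh, sep="\t", index_label="gene_id")


def write_signature(result: SelectionResult, path,
                    header_comment: str | None = None) -> None:
    """Selected gene ids, one per line, p-value order."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for gid in result.signature:
            fh.write(f"{gid}\n")
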