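"""Clinicopathological association and survival statistics.

Covariate-by-LVSI 2x2 tables are tested with the two-sided Fisher exact
test (p = sum of hypergeometric probabilities of all margin-preserving
tables no more probable than the observed one).  Continuous covariates
(age, BMI) are compared with the Mann-Whitney U test.  Overall survival
is summarized per LVSI group with the Kaplan-Meier product-limit
estimator and compared with the two-sided log-rank test.  Significance
is conventionally declared at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from .select import _as_bool_labels

__all__ = [
    "ContingencyTable2x2",
    "SurvivalCurve",
    "fisher_exact",
    "mann_whitney",
    "kaplan_meier",
    "crosstab_2x2",
    "table1_report",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = covariate levels, columns = LVSI positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate for one group.

    ``times`` are the distinct event times (months) plus time 0;
    ``survival`` is non-increasing and starts at 1.  ``censor_times``
    lists censored follow-up times for plotting tick marks.
    """

    group: str
    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray


def fisher_exact(table: ContingencyTable2x2 | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sided by the "probability at most that of the observed table"
    rule over all tables with the same margins.
    """
    if not isinstance(table, ContingencyTable2x2):
        t = np.asarray(table)
        table = ContingencyTable2x2(*[int(v) for v in t.ravel()])
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p.

    Exact null distribution for small samples (both n <= 20, no ties);
    normal approximation with continuity and tie correction otherwise —
    the regime of the study's group sizes (26 vs 62).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def kaplan_meier(times, events, groups) -> tuple[dict[str, SurvivalCurve],
                                                 float | None]:
    """Per-group product-limit curves and the two-sided log-rank p.

    ``events`` is 1/True for death, 0/False for censored.  Returns the
    log-rank p, or ``None`` (flagged as undefined) when no event occurred
    in either group.  A group with no subjects is an error.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    groups = np.asarray(groups)
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(labels)}")
    curves: dict[str, SurvivalCurve] = {}
    for g in labels:
        sel = groups == g
        if not sel.any():
            raise ValueError(f"group {g!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], event_observed=events[sel])
        tl = kmf.survival_function_.index.to_numpy(dtype=float)
        curves[str(g)] = SurvivalCurve(
            group=str(g),
            times=tl,
            at_risk=kmf.event_table["at_risk"].to_numpy(),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
            censor_times=np.sort(times[sel & ~events]),
        )
    if not events.any():
        return curves, None
    sel = groups == labels[0]
    res = _lifelines_logrank(times[sel], times[~sel],
                             event_observed_A=events[sel],
                             event_observed_B=events[~sel])
    return curves, float(res.p_value)


def crosstab_2x2(table: pd.DataFrame, covariate: str,
                 level_groups: tuple[tuple[str, ...], tuple[str, ...]]
                 ) -> ContingencyTable2x2:
    """Collapse a covariate to two level groups and cross-tabulate vs LVSI."""
    lvsi = _as_bool_labels(table["lvsi"])
    vals = table[covariate].astype(str)
    row0 = vals.isin(level_groups[0])
    row1 = vals.isin(level_groups[1])
    return ContingencyTable2x2(
        a=int((row0 & lvsi).sum()), b=int((row0 & ~lvsi).sum()),
        c=int((row1 & lvsi).sum()), d=int((row1 & ~lvsi).sum()),
    )


#: covariate -> (row label pair, level groups) for the standard report
REPORT_DICHOTOMIES: dict[str, tuple[tuple[str, str],
                                    tuple[tuple[str, ...], tuple[str, ...]]]] = {
    "stage": (("I/II", "III/IV"), (("I", "II"), ("III", "IV"))),
    "histology": (("endometrioid", "nonendometrioid"),
                  (("endometrioid",), ("nonendometrioid",))),
    "grade": (("1", "2/3"), (("1",), ("2", "3"))),
    "myoinvasion": (("<50%", ">=50%"), (("<50%",), (">=50%",))),
    "ln_metastasis": (("yes", "no"), (("yes",), ("no",))),
    "recurrence": (("yes", "no"), (("yes",), ("no",))),
}


def table1_report(samples: pd.DataFrame) -> pd.DataFrame:
    """Covariate-by-LVSI association table.

    One row per covariate level pair with per-class counts and the
    Fisher exact p; age and BMI rows carry per-class means/SDs and the
    Mann-Whitney p.  Subjects outside the two compared levels (e.g.
    lymph-node status ``not_evaluated``) are excluded from that test.
    """
    lvsi = _as_bool_labels(samples["lvsi"])
    rows = []
    for col in ("age", "bmi"):
        x = samples.loc[lvsi, col].dropna().to_numpy(dtype=float)
        y = samples.loc[~lvsi, col].dropna().to_numpy(dtype=float)
        _, p = mann_whitney(x, y)
        rows.append({
            "covariate": col, "level": "mean+/-SD",
            "lvsi_positive": f"{x.mean():.1f}+/-{x.std(ddof=1):.1f}",
            "lvsi_negative": f"{y.mean():.1f}+/-{y.std(ddof=1):.1f}",
            "test": "mann_whitney", "p_value": p,
        })
    for col, (labels_, groups_) in REPORT_DICHOTOMIES.items():
        ct = crosstab_2x2(samples, col, groups_)
        p = fisher_exact(ct)
        for i, (lev, npos, nneg) in enumerate(
                [(labels_[0], ct.a, ct.b), (labels_[1], ct.c, ct.d)]):
            rows.append({
                "covariate": col, "level": lev,
                "lvsi_positive": npos, "lvsi_negative": nneg,
                "test": "fisher_exact" if i == 0 else "",
                "p_value": p if i == 0 else np.nan,
            })
    return pd.DataFrame(rows)
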