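"""Synthetic two-channel microarray datasets with planted LVSI structure.

The study's raw 88-sample microarray data are not publicly deposited, so
this module generates datasets with the statistical structure the
analysis assumes: log2 ratios that are Gaussian around 0 for background
genes, a planted set of signature genes whose LVSI-positive-class mean
is shifted upward by ``effect_size`` log2 units, an independent
below-detection mask, and clinical covariates whose per-covariate 2x2
margins reproduce the study cohort's cross-tabulations exactly in
deterministic mode.

Default study conditions: 26 LVSI-positive vs 62 LVSI-negative samples,
55 planted genes of 1000, effect size 1.5 log2 units, per-gene noise SD
0.5, dropout rate 0.05.  Survival is exponential with a configurable
hazard ratio between LVSI groups and administrative censoring at a
configurable horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SAMPLE_COLUMNS, ExpressionMatrix, validate_samples

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "TABLE1_MARGINS",
    "generate_expression",
    "generate_clinical",
    "generate_dataset",
]


#: per-covariate level counts conditional on LVSI status, matching the
#: study cohort's cross-tabulations (26 positive / 62 negative).  Stage
#: and grade are grouped in the source table; the within-group splits
#: (I vs II, 2 vs 3) are assumptions that collapse back to the printed
#: counts under the standard dichotomies.  Recurrence margins are an
#: assumption (the source table prints none).
TABLE1_MARGINS: dict[str, list[tuple[str, int, int]]] = {
    "stage": [("I", 7, 45), ("II", 2, 5), ("III", 15, 10), ("IV", 2, 2)],
    "histology": [("endometrioid", 22, 56), ("nonendometrioid", 4, 6)],
    "grade": [("1", 6, 48), ("2", 14, 10), ("3", 6, 4)],
    "myoinvasion": [("<50%", 20, 10), (">=50%", 6, 52)],
    "ln_metastasis": [("yes", 10, 1), ("no", 9, 60), ("not_evaluated", 7, 1)],
    "recurrence": [("yes", 8, 4), ("no", 18, 58)],
}

#: per-class (mean, SD) of age in years and BMI in kg/m^2
AGE_PARAMS = {"positive": (63.0, 12.1), "negative": (57.0, 13.1)}
BMI_PARAMS = {"positive": (22.7, 4.7), "negative": (27.0, 9.3)}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dataset.

    ``n_signature`` may be 0 for a pure-null dataset.  ``effect_size`` is
    the mean log2-ratio shift of planted genes in the positive class (>=1
    makes them selectable by the default mean-difference rule).
    """

    n_pos: int = 26
    n_neg: int = 62
    n_genes: int = 1000
    n_signature: int = 55
    effect_size: float = 1.5
    noise_sd: float = 0.5
    dropout_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pos", "n_neg", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_signature < 0:
            raise ValueError(f"n_signature must be >= 0, got {self.n_signature}")
        if self.n_signature > self.n_genes:
            raise ValueError(
                f"n_signature ({self.n_signature}) must be <= n_genes "
                f"({self.n_genes})")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(
                f"dropout_rate must be in [0, 1), got {self.dropout_rate}")

    @property
    def n_samples(self) -> int:
        return self.n_pos + self.n_neg


@dataclass
class SyntheticDataset:
    """Expression matrix, sample annotations and planted-gene truth."""

    expression: ExpressionMatrix
    samples: pd.DataFrame
    truth: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not set(self.truth) <= set(self.expression.gene_ids):
            raise ValueError("truth genes must appear in the expression matrix")
        if list(self.samples["sample_id"]) != self.expression.sample_ids:
            raise ValueError("sample table does not match expression columns")

    @property
    def labels(self) -> pd.Series:
        return (self.samples.set_index("sample_id")["lvsi"] == "positive")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    width = max(3, len(str(config.n_samples)))
    sids = [f"S{i:0{width}d}" for i in range(1, config.n_samples + 1)]
    table = pd.DataFrame({c: pd.Series([np.nan] * config.n_samples)
                          for c in SAMPLE_COLUMNS})
    table["sample_id"] = sids
    table["lvsi"] = (["positive"] * config.n_pos + ["negative"] * config.n_neg)
    return table


def generate_expression(config: SimulationConfig) -> SyntheticDataset:
    """Draw a log2-ratio matrix with planted differential expression.

    Background genes have class-independent mean 0; the first
    ``n_signature`` genes have positive-class mean ``effect_size`` and
    negative-class mean 0.  The below-detection mask is drawn
    independently of the values at ``dropout_rate`` (missing at random).
    Identical config implies bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    gids = _gene_ids(config.n_genes)
    table = _sample_frame(config)
    vals = rng.normal(0.0, config.noise_sd,
                      size=(config.n_genes, config.n_samples))
    vals[: config.n_signature, : config.n_pos] += config.effect_size
    mask = rng.random(size=vals.shape) < config.dropout_rate
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=gids, columns=table["sample_id"].tolist()),
        pd.DataFrame(mask, index=gids, columns=table["sample_id"].tolist()),
    )
    return SyntheticDataset(expression=expr, samples=table,
                            truth=gids[: config.n_signature])


def _allocate(level_counts: list[tuple[str, int]], n: int, name: str,
              deterministic: bool, rng: np.random.Generator) -> np.ndarray:
    total = sum(c for _, c in level_counts)
    if total != n:
        raise ValueError(
            f"margins for {name!r} sum to {total}, expected {n}")
    out = np.concatenate([np.repeat(lev, c) for lev, c in level_counts])
    if not deterministic:
        out = rng.permutation(out)
    return out


def _scale_margins(margins: list[tuple[str, int, int]], n_pos: int, n_neg: int
                   ) -> list[tuple[str, int, int]]:
    """Largest-remainder rescale of per-class counts to new class sizes."""
    def scale(counts: list[int], n: int) -> list[int]:
        tot = sum(counts)
        raw = [c * n / tot for c in counts]
        base = [int(np.floor(r)) for r in raw]
        rem = n - sum(base)
        order = np.argsort([b - r for r, b in zip(raw, base)])
        for i in order[:rem]:
            base[i] += 1
        return base

    pos = scale([p for _, p, _ in margins], n_pos)
    neg = scale([q for _, _, q in margins], n_neg)
    return [(lev, p, q) for (lev, _, _), p, q in zip(margins, pos, neg)]


def generate_clinical(config: SimulationConfig,
                      margins: dict[str, list[tuple[str, int, int]]] | None = None,
                      deterministic: bool = True,
                      hazard_ratio: float = 3.0,
                      baseline_hazard: float = 0.004,
                      censor_horizon: float = 120.0,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample a clinical annotation table conditional on LVSI status.

    ``margins`` maps covariates to per-level (level, n_positive,
    n_negative) counts; explicit margins must sum exactly to the class
    sizes.  When omitted, the study-cohort margins are rescaled to the
    configured class sizes by largest remainder.  In deterministic mode
    levels are allocated in sample order within each class, reproducing
    the requested cross-tabulations exactly; otherwise the allocation is
    permuted.  Survival is exponential (``baseline_hazard`` per month for
    LVSI-negatives, multiplied by ``hazard_ratio`` for positives) with
    administrative censoring at ``censor_horizon`` months.
    """
    if hazard_ratio <= 0 or baseline_hazard <= 0:
        raise ValueError("hazard_ratio and baseline_hazard must be > 0")
    if censor_horizon < 0:
        raise ValueError("censor_horizon must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    if margins is None:
        margins = {k: _scale_margins(v, config.n_pos, config.n_neg)
                   for k, v in TABLE1_MARGINS.items()}
    table = _sample_frame(config)
    pos = (table["lvsi"] == "positive").to_numpy()
    for cov, levels in margins.items():
        vals = np.empty(config.n_samples, dtype=object)
        vals[pos] = _allocate([(lev, p) for lev, p, _ in levels], config.n_pos,
                              f"{cov}/positive", deterministic, rng)
        vals[~pos] = _allocate([(lev, q) for lev, _, q in levels], config.n_neg,
                               f"{cov}/negative", deterministic, rng)
        table[cov] = vals
    for col, params in (("age", AGE_PARAMS), ("bmi", BMI_PARAMS)):
        out = np.empty(config.n_samples)
        for cls, sel in (("positive", pos), ("negative", ~pos)):
            mu, sd = params[cls]
            out[sel] = rng.normal(mu, sd, size=int(sel.sum()))
        table[col] = np.round(np.clip(out, 15.0, None), 1)
    hazard = np.where(pos, baseline_hazard * hazard_ratio, baseline_hazard)
    t_event = rng.exponential(1.0 / hazard)
    observed = t_event < censor_horizon
    table["surv_time"] = np.round(np.where(observed, t_event, censor_horizon), 2)
    table["surv_event"] = np.where(observed, "death", "censored")
    return validate_samples(table)


def generate_dataset(config: SimulationConfig,
                     margins=None, deterministic: bool = True,
                     hazard_ratio: float = 3.0,
                     baseline_hazard: float = 0.004,
                     censor_horizon: float = 120.0) -> SyntheticDataset:
    """Expression and clinical annotations in one reproducible draw."""
    ds = generate_expression(config)
    ds.samples = generate_clinical(
        config, margins=margins, deterministic=deterministic,
        hazard_ratio=hazard_ratio, baseline_hazard=baseline_hazard,
        censor_horizon=censor_horizon)
    return ds
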