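"""Expression-matrix and sample-annotation containers and tab-delimited I/O.

Expression values are log2 ratios of a two-channel hybridization
(Cy5 sample over Cy3 common reference).  A probe whose fluorescence falls
below the scanner's detection limit carries no trustworthy ratio; such
cells are tracked in a parallel boolean mask and excluded from every
downstream mean, median and test.

File formats
------------
Matrix: tab-delimited, first column ``gene_id``, header row of sample ids,
below-detection cells written as a sentinel token (default ``"NA"``).
Annotations: tab-delimited with the :data:`SAMPLE_COLUMNS` header.
Values are written at full ``repr`` precision so that write->read is the
identity on valid matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ParseError",
    "SAMPLE_COLUMNS",
    "read_matrix",
    "write_matrix",
    "read_samples",
    "write_samples",
    "validate_samples",
    "ratios_to_log2",
    "median_center",
]


class ParseError(ValueError):
    """Malformed matrix or annotation file; message carries the line number."""


#: required columns of a sample annotation table
SAMPLE_COLUMNS = [
    "sample_id",
    "lvsi",
    "age",
    "bmi",
    "stage",
    "histology",
    "grade",
    "myoinvasion",
    "ln_metastasis",
    "recurrence",
    "surv_time",
    "surv_event",
]

_CATEGORICAL_LEVELS = {
    "lvsi": {"positive", "negative"},
    "stage": {"I", "II", "III", "IV"},
    "histology": {"endometrioid", "nonendometrioid"},
    "grade": {"1", "2", "3"},
    "myoinvasion": {"<50%", ">=50%"},
    "ln_metastasis": {"yes", "no", "not_evaluated"},
    "recurrence": {"yes", "no"},
    "surv_event": {"death", "censored"},
}


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-ratio matrix with a below-detection mask.

    Attributes
    ----------
    values : pandas.DataFrame
        Float log2 ratios, index = gene ids, columns = sample ids.
        Cells flagged in ``below_detection`` are undefined-but-ignored.
    below_detection : pandas.DataFrame
        Boolean, same shape/labels as ``values``; True = below the
        detection limit (treated as missing everywhere downstream).
    """

    values: pd.DataFrame
    below_detection: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.below_detection is None:
            self.below_detection = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if self.values.shape != self.below_detection.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape "
                f"{self.below_detection.shape}"
            )
        if not (
            self.values.index.equals(self.below_detection.index)
            and self.values.columns.equals(self.below_detection.columns)
        ):
            raise ValueError("values and below_detection must share labels")
        for name, idx in (("gene", self.values.index), ("sample", self.values.columns)):
            if idx.has_duplicates:
                dup = idx[idx.duplicated()][0]
                raise ValueError(f"duplicate {name} id: {dup!r}")
        self.values = self.values.astype(float)
        self.below_detection = self.below_detection.astype(bool)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def detected(self) -> pd.DataFrame:
        """Values with below-detection cells replaced by NaN."""
        return self.values.mask(self.below_detection)

    def restrict_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)].copy(),
            self.below_detection.loc[list(gene_ids)].copy(),
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        det = self.below_detection
        if not (
            det.equals(other.below_detection)
            and self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
        ):
            return False
        a = self.values.to_numpy()
        b = other.values.to_numpy()
        keep = ~det.to_numpy()
        return bool(np.array_equal(a[keep], b[keep]))


def read_matrix(path, sentinel: str = "NA") -> ExpressionMatrix:
    """Parse a tab-delimited log2-ratio matrix.

    ``sentinel`` (``"NA"`` or ``""``) marks below-detection cells.
    Raises :class:`ParseError` naming the offending line for ragged rows,
    duplicate ids or non-numeric non-sentinel cells.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise ParseError(f"{path}:1: duplicate sample id {dup!r}")
    n_cols = len(header)
    gene_ids: list[str] = []
    seen: set[str] = set()
    vals = np.empty((len(lines) - 1, len(sample_ids)))
    mask = np.zeros_like(vals, dtype=bool)
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ParseError(
                f"{path}:{i}: expected {n_cols} fields, found {len(fields)}"
            )
        gid = fields[0]
        if gid in seen:
            raise ParseError(f"{path}:{i}: duplicate gene id {gid!r}")
        seen.add(gid)
        gene_ids.append(gid)
        for j, cell in enumerate(fields[1:]):
            if cell == sentinel:
                mask[i - 2, j] = True
                vals[i - 2, j] = np.nan
            else:
                try:
                    vals[i - 2, j] = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}:{i}: non-numeric cell {cell!r} for gene {gid!r}"
                    ) from None
    return ExpressionMatrix(
        pd.DataFrame(vals, index=gene_ids, columns=sample_ids),
        pd.DataFrame(mask, index=gene_ids, columns=sample_ids),
    )


def write_matrix(matrix: ExpressionMatrix, path, sentinel: str = "NA",
                 header_comment: str | None = None) -> None:
    """Write a matrix in the tab-delimited format read by :func:`read_matrix`."""
    path = Path(path)
    vals = matrix.values.to_numpy()
    mask = matrix.below_detection.to_numpy()
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, gid in enumerate(matrix.gene_ids):
            cells = [
                sentinel if mask[i, j] else repr(float(vals[i, j]))
                for j in range(vals.shape[1])
            ]
            fh.write(gid + "\t" + "\t".join(cells) + "\n")


def validate_samples(table: pd.DataFrame) -> pd.DataFrame:
    """Check a sample annotation table against the expected schema."""
    missing = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    if table["lvsi"].isna().any():
        raise ValueError("lvsi status may not be missing")
    for col, levels in _CATEGORICAL_LEVELS.items():
        vals = table[col].dropna().astype(str)
        bad = set(vals) - levels
        if bad:
            raise ValueError(f"invalid {col} level(s): {sorted(bad)}")
    return table


def read_samples(path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "grade": str},
                        comment="#")
    return validate_samples(table)


def write_samples(table: pd.DataFrame, path,
                  header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, sep="\t", index=False)


def ratios_to_log2(primary: ExpressionMatrix) -> ExpressionMatrix:
    """Convert primary Cy5/Cy3 ratios to log2 ratios, preserving the mask.

    Detected ratios must be strictly positive.
    """
    vals = primary.values.to_numpy(copy=True)
    mask = primary.below_detection.to_numpy()
    bad = (~mask) & ~(vals > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive detected ratio {vals[i, j]!r} at gene "
            f"{primary.gene_ids[i]!r}, sample {primary.sample_ids[j]!r}"
        )
    out = np.full_like(vals, np.nan)
    out[~mask] = np.log2(vals[~mask])
    return ExpressionMatrix(
        pd.DataFrame(out, index=primary.values.index, columns=primary.values.columns),
        primary.below_detection.copy(),
    )


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample median centering over detected values.

    After centering, each sample's median of detected log ratios is 0.
    Idempotent; the mask is unchanged.  A sample with no detected value
    has no defined median and is an error.
    """
    det = matrix.detected()
    n_det = det.notna().sum(axis=0)
    if (n_det == 0).any():
        sid = n_det.index[n_det == 0][0]
        raise ValueError(f"sample {sid!r} has no detected values")
    medians = det.median(axis=0, skipna=True)
    return ExpressionMatrix(matrix.values.sub(medians, axis=1),
                            matrix.below_detection.copy())
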