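"""Readers, writers, cross-tabulation, and run configuration.

Expression matrices travel as delimited text with gene ids in the first
column and a header row of sample ids; clinical tables as delimited text
with mandatory ``sample_id``, ``time_years``, ``event`` columns and the
missing-value token ``NA``; gene sets as YAML mapping name -> gene list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signatures import ExpressionMatrix, GeneSet
from .survival import contingency_test

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"


class IOError_(ValueError):
    pass


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples delimited matrix.

    Duplicate gene rows are collapsed by mean (warning); any non-numeric or
    missing cell is an error naming its gene row and sample column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                     keep_default_na=False)
    values = np.empty(df.shape)
    for j, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise IOError_(
                f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        values[:, j] = parsed.to_numpy()
    return ExpressionMatrix(list(df.index.astype(str)),
                            list(df.columns.astype(str)), values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    expr.to_dataframe().to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_clinical(path: str | Path, time_unit: str = "years") -> pd.DataFrame:
    """Read a clinical table; ``NA`` marks missing values.

    ``time_unit="months"`` converts follow-up to years on read.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), na_values=[NA_TOKEN],
                     keep_default_na=False, dtype={"sample_id": str})
    for col in ("sample_id", "time_years", "event"):
        if col not in df.columns:
            raise IOError_(f"{path}: missing mandatory column {col!r}")
    if time_unit == "months":
        df["time_years"] = df["time_years"] / 12.0
    elif time_unit != "years":
        raise IOError_(f"unknown time unit {time_unit!r}")
    # force categorical clinical columns to string levels
    for col in ("stage", "nodal", "grade", "her2", "group", "cohort"):
        if col in df.columns:
            df[col] = df[col].map(lambda v: v if pd.isna(v) else str(v))
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False, na_rep=NA_TOKEN)


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """YAML mapping of signature name to gene-id list."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise IOError_(f"{path}: expected a mapping of name -> gene list")
    out = {}
    for name, genes in raw.items():
        if not isinstance(genes, list):
            raise IOError_(f"{path}: gene set {name!r} must be a list")
        out[str(name)] = GeneSet(str(name), tuple(map(str, genes)))
    return out


@dataclass
class CrossTab:
    """Counts and column percentages for two categorical variables.

    Unknown/missing values form their own row and column but are excluded
    from the association test; the test p is omitted (NaN) when the known
    table is degenerate.
    """

    row_var: str
    col_var: str
    counts: pd.DataFrame
    percentages: pd.DataFrame
    p_value: float
    n: int
    n_unknown: int


def crosstab(clinical: pd.DataFrame, row_var: str, col_var: str) -> CrossTab:
    for v in (row_var, col_var):
        if v not in clinical.columns:
            raise IOError_(f"variable {v!r} not in clinical table")
    rows = clinical[row_var].astype(object).where(~clinical[row_var].isna(),
                                                  "Unknown")
    cols = clinical[col_var].astype(object).where(~clinical[col_var].isna(),
                                                  "Unknown")
    counts = pd.crosstab(rows, cols, dropna=False)
    pct = 100.0 * counts / counts.sum(axis=0)
    known = counts.loc[[r for r in counts.index if r != "Unknown"],
                       [c for c in counts.columns if c != "Unknown"]]
    n_unknown = int(counts.to_numpy().sum() - known.to_numpy().sum())
    p = np.nan
    if known.shape[0] >= 2 and known.shape[1] >= 2:
        if known.shape == (2, 2):
            p = contingency_test(known.to_numpy(), method="chi2_cc")
        else:
            from scipy import stats
            table = known.to_numpy()
            if np.all(table.sum(axis=0) > 0) and np.all(table.sum(axis=1) > 0):
                p = float(stats.chi2_contingency(table, correction=False)[1])
    else:
        logger.info("crosstab %s x %s: degenerate table, no test", row_var, col_var)
    return CrossTab(row_var, col_var, counts, pct, p,
                    n=int(counts.to_numpy().sum()), n_unknown=n_unknown)


def share_of_level(clinical: pd.DataFrame, variable: str, level: str,
                   within: str | None = None,
                   within_level: str | None = None) -> float:
    """Percent of records having ``variable == level``, optionally within a
    subgroup.  The denominator is the whole (sub)cohort including records
    with unknown ``variable``, matching the summary-table convention of
    printing percentages on the full cohort size."""
    sub = clinical
    if within is not None:
        sub = clinical[clinical[within] == within_level]
    if len(sub) == 0:
        raise IOError_("no records for share computation")
    return 100.0 * float((sub[variable] == level).sum()) / len(sub)
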