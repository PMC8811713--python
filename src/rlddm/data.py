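"""Loading and validation of trial-level datasets.

The input dialect is one row per trial, in ascending trial order within
each subject x condition block, with the required columns

    rt        response time in seconds (omitted for RT-free softmax models)
    response  1 = upper-boundary option, 0 = lower-boundary option
    split_by  condition identifier
    subj_idx  non-negative integer subject identifier
    feedback  numeric reward for the chosen option
    q_init    initial expected value of both options in the block

plus any number of numeric covariate columns for regression models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("response", "split_by", "subj_idx", "feedback", "q_init")


class SchemaError(ValueError):
    """A required or requested column is missing or malformed."""


class ValidationError(ValueError):
    """A cell value violates the trial-table contract."""


@dataclass
class TrialTable:
    """A validated trial-level dataset.

    Thin wrapper around a :class:`pandas.DataFrame` that guarantees the
    column contract and exposes subject x condition block iteration in file
    order.  Row order is preserved exactly; learning is order-dependent.
    """

    df: pd.DataFrame
    has_rt: bool = True

    def __post_init__(self) -> None:
        _validate(self.df, require_rt=self.has_rt)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subjects(self) -> list[int]:
        return sorted(self.df["subj_idx"].unique().tolist())

    def conditions(self, subj: int) -> list:
        sub = self.df[self.df["subj_idx"] == subj]
        return list(dict.fromkeys(sub["split_by"].tolist()))  # file order

    def block(self, subj: int, cond) -> pd.DataFrame:
        """All trials of one subject x condition, in file order."""
        mask = (self.df["subj_idx"] == subj) & (self.df["split_by"] == cond)
        return self.df[mask]

    def iter_blocks(self):
        for subj in self.subjects:
            for cond in self.conditions(subj):
                yield subj, cond, self.block(subj, cond)

    def save(self, path, sep: str = ",") -> None:
        self.df.to_csv(path, sep=sep, index=False)


def _validate(df: pd.DataFrame, require_rt: bool = True) -> None:
    required = (("rt",) if require_rt else ()) + REQUIRED_COLUMNS
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if require_rt:
        bad = df.index[~(df["rt"] > 0)]
        if len(bad):
            raise ValidationError(f"rt must be positive; first bad row index {bad[0]}")
    bad = df.index[~df["response"].isin([0, 1])]
    if len(bad):
        raise ValidationError(
            f"response must be 0 or 1; first bad row index {bad[0]}")
    if not np.issubdtype(df["subj_idx"].dtype, np.number) \
            or (df["subj_idx"] < 0).any():
        raise ValidationError("subj_idx must be non-negative integers")
    # q_init must be constant within each subject x condition block
    q_counts = df.groupby(["subj_idx", "split_by"])["q_init"].nunique()
    if (q_counts > 1).any():
        key = q_counts[q_counts > 1].index[0]
        raise ValidationError(
            f"q_init varies within subject x condition block {key}")
    # heterogeneity across conditions of one subject is legal but unusual
    per_subj = df.groupby("subj_idx")["q_init"].nunique()
    if (per_subj > 1).any():
        warnings.warn(
            "q_init differs across conditions for subject(s) "
            f"{per_subj[per_subj > 1].index.tolist()}; each block keeps its own value",
            stacklevel=3)


def load_trials(path, require_rt: bool = True) -> TrialTable:
    """Read a CSV/TSV trial file and validate it.

    The delimiter is auto-detected between comma and tab from the header
    line; other dialects are rejected.  Row order is preserved exactly.
    """
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        sep = "\t"
    elif "," in header:
        sep = ","
    else:
        raise SchemaError(
            f"{path}: could not detect a comma or tab delimiter in the header")
    df = pd.read_csv(path, sep=sep)
    has_rt = "rt" in df.columns
    if require_rt and not has_rt:
        raise SchemaError("missing required column 'rt' "
                          "(pass require_rt=False for RT-free softmax models)")
    return TrialTable(df, has_rt=has_rt)


def validate_regressor_columns(table: TrialTable, terms: list[str]) -> TrialTable:
    """Check that every named covariate exists and is fully numeric.

    Returns the table unchanged on success.
    """
    if not terms:
        raise ValueError("terms must be non-empty")
    for term in terms:
        if term not in table.df.columns:
            raise SchemaError(f"covariate column {term!r} not found")
        col = pd.to_numeric(table.df[term], errors="coerce")
        bad = table.df.index[col.isna()]
        if len(bad):
            raise ValidationError(
                f"covariate {term!r} has a non-numeric or missing entry at "
                f"row index {bad[0]}")
    return table
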