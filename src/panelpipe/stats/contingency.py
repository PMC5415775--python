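"""Contingency tables from cohort data."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..errors import ConfigError
from .ihc import COMBINED_LEVELS

# deterministic level orders for known variables
_LEVEL_ORDER: Dict[str, Tuple[str, ...]] = {
    "fgfr1": ("low", "high"),
    "fgfr3": ("low", "high"),
    "grade": ("I", "II", "III"),
    "location": ("spinal", "cerebellar", "cerebral"),
    "age16": ("pediatric", "adult"),
    "fgfr_combined": COMBINED_LEVELS,
    "sex": ("M", "F"),
}


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: List[str]
    col_labels: List[str]
    n_dropped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ConfigError("contingency table must be 2-dimensional")
        if (self.counts < 0).any():
            raise ConfigError("contingency table entries must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def drop_empty(self) -> "ContingencyTable":
        rows = self.counts.sum(axis=1) > 0
        cols = self.counts.sum(axis=0) > 0
        return ContingencyTable(self.counts[np.ix_(rows, cols)],
                                [l for l, k in zip(self.row_labels, rows) if k],
                                [l for l, k in zip(self.col_labels, cols) if k],
                                self.n_dropped)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T, list(self.col_labels),
                                list(self.row_labels), self.n_dropped)

    def row_proportion(self, row: str, col: str) -> float:
        """Cell count divided by its row total."""
        i = self.row_labels.index(row)
        j = self.col_labels.index(col)
        total = self.counts[i].sum()
        if total == 0:
            raise ConfigError(f"row {row!r} is empty")
        return float(self.counts[i, j] / total)


def _resolve(cohort: pd.DataFrame, var: str) -> pd.Series:
    """Column lookup with on-the-fly derived variables."""
    from .ihc import binarize_score, combined_fgfr_group
    if var in cohort.columns:
        return cohort[var]
    if var in ("fgfr1", "fgfr3") and f"{var}_score" in cohort.columns:
        return binarize_score(cohort[f"{var}_score"])
    if var == "age16" and "age_years" in cohort.columns:
        return pd.Series(np.where(cohort["age_years"] < 16, "pediatric", "adult"),
                         index=cohort.index)
    if var == "fgfr_combined" and {"fgfr1_score", "fgfr3_score"} <= set(cohort.columns):
        return pd.Series([combined_fgfr_group(a, b) for a, b in
                          zip(cohort["fgfr1_score"], cohort["fgfr3_score"])],
                         index=cohort.index)
    raise ConfigError(f"unknown variable {var!r}")


def crosstab(cohort: pd.DataFrame, row_var: str, col_var: str,
             filters: Optional[Mapping[str, object]] = None) -> ContingencyTable:
    """Cross-tabulate two cohort variables.

    Rows with a missing value in either variable are dropped (and
    counted in ``n_dropped``).  Derived variables (``fgfr1``, ``fgfr3``,
    ``fgfr_combined``, ``age16``) are computed on the fly.  ``filters``
    restricts the cohort to rows where each named column equals the
    given value.
    """
    df = cohort
    if filters:
        for col, val in filters.items():
            df = df[_resolve(df, col) == val]
    rows = _resolve(df, row_var)
    cols = _resolve(df, col_var)
    keep = rows.notna() & cols.notna()
    n_dropped = int((~keep).sum())
    rows, cols = rows[keep], cols[keep]
    if rows.empty:
        raise ConfigError("empty table after filtering")

    def levels(var: str, values: pd.Series) -> List[str]:
        if var in _LEVEL_ORDER:
            return [l for l in _LEVEL_ORDER[var] if l in set(values)]
        return sorted(set(values))

    rl = levels(row_var, rows)
    cl = levels(col_var, cols)
    counts = np.zeros((len(rl), len(cl)), dtype=int)
    for i, r in enumerate(rl):
        for j, c in enumerate(cl):
            counts[i, j] = int(((rows == r) & (cols == c)).sum())
    table = ContingencyTable(counts, rl, cl, n_dropped)
    if len(rl) < 2 or len(cl) < 2:
        raise ConfigError("contingency table needs >= 2 rows and columns")
    return table
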