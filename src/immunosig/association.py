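"""Association of the immune phenotype with clinical variables.

Cross-tabulates immune-rich/poor labels against receptor subtype or nodal
status and applies Pearson's chi-square test of independence (no continuity
correction; the cohort tables this targets are large-count).  Samples whose
category is ``missing`` are excluded listwise from the test table and
reported separately: including them as a category would test missingness,
not biology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataValidationError

logger = logging.getLogger(__name__)

VARIABLES = ("subtype", "nodal")


@dataclass
class ContingencyResult:
    """Chi-square test outcome on a label-by-category count table."""

    table: pd.DataFrame
    chi2: float
    df: int
    p_value: float
    excluded_missing: int = 0


def crosstab(
    calls: pd.DataFrame, meta: pd.DataFrame, variable: str
) -> tuple[pd.DataFrame, int]:
    """Count table of immune label x clinical category.

    ``calls`` is a classifier output frame (sample_id, label); ``meta`` a
    metadata frame indexed by sample_id with subtype/nodal columns.  Returns
    the table (rows = labels, columns = non-missing categories, sorted) and
    the number of overlapping samples excluded for a missing category.
    """
    if variable not in VARIABLES:
        raise DataValidationError(f"variable must be one of {VARIABLES}")
    labels = calls.set_index("sample_id")["label"]
    shared = labels.index.intersection(meta.index)
    if len(shared) == 0:
        raise DataValidationError("calls and metadata share no sample ids")
    joined = pd.DataFrame(
        {"label": labels.loc[shared], "category": meta.loc[shared, variable]}
    )
    missing_mask = joined["category"] == "missing"
    excluded = int(missing_mask.sum())
    joined = joined[~missing_mask]
    if joined.empty:
        raise DataValidationError(f"all samples have missing {variable}")
    table = pd.crosstab(joined["label"], joined["category"])
    table = table.sort_index(axis=0).sort_index(axis=1)
    table.index.name = "label"
    table.columns.name = variable
    return table, excluded


def chi_square_test(
    table: pd.DataFrame, excluded_missing: int = 0
) -> ContingencyResult:
    """Pearson chi-square without continuity correction on an r x c table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DataValidationError(
            f"chi-square needs an r x c table with r, c >= 2; got shape {arr.shape}"
        )
    if (arr < 0).any() or (arr != np.floor(arr)).any():
        raise DataValidationError("contingency table must hold non-negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DataValidationError("zero marginal in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return ContingencyResult(
        table=pd.DataFrame(table),
        chi2=float(chi2),
        df=int(dof),
        p_value=float(p),
        excluded_missing=excluded_missing,
    )


def association_test(
    calls: pd.DataFrame, meta: pd.DataFrame, variable: str
) -> ContingencyResult:
    """Convenience: crosstab then chi-square in one step."""
    table, excluded = crosstab(calls, meta, variable)
    result = chi_square_test(table, excluded)
    logger.info(
        "association label x %s: chi2=%.3f, df=%d, p=%.3g (%d missing excluded)",
        variable, result.chi2, result.df, result.p_value, excluded,
    )
    return result
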