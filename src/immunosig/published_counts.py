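"""Published contingency tables: immune phenotype vs clinical variables.

Counts reported for three large breast-cancer cohorts (METABRIC, a curated
GEO/ArrayExpress array aggregate, and TCGA BRCA) cross-tabulating the
permutation-test immune-rich/immune-poor phenotype against receptor subtype
and nodal metastasis status.  Rows are the phenotype labels, columns the
clinical categories; subtype tables exclude samples with missing subtype.
These tables let the chi-square association stage be exercised against
real-data margins without redistributing any expression data.
"""

from __future__ import annotations

import pandas as pd

_SUBTYPE_COLS = ["HER2", "Luminal", "TNBC"]
_NODAL_COLS = ["negative", "positive"]
_LABELS = ["poor", "rich"]


def _table(rows, cols) -> pd.DataFrame:
    df = pd.DataFrame(rows, index=pd.Index(_LABELS, name="label"), columns=cols)
    return df


SUBTYPE_TABLES: dict[str, pd.DataFrame] = {
    "METABRIC": _table([[83, 445, 109], [19, 60, 54]], _SUBTYPE_COLS),
    "GEO": _table([[47, 272, 54], [74, 189, 115]], _SUBTYPE_COLS),
    "TCGA": _table([[10, 278, 22], [20, 210, 58]], _SUBTYPE_COLS),
}

#: samples excluded from the subtype tables for missing subtype (poor, rich)
SUBTYPE_MISSING: dict[str, tuple[int, int]] = {
    "METABRIC": (2, 0),
    "GEO": (0, 0),
    "TCGA": (17, 35),
}

NODAL_TABLES: dict[str, pd.DataFrame] = {
    "METABRIC": _table([[328, 311], [61, 72]], _NODAL_COLS),
    "GEO": _table([[323, 147], [297, 160]], _NODAL_COLS),
    "TCGA": _table([[136, 191], [157, 166]], _NODAL_COLS),
}

COHORTS = ("METABRIC", "GEO", "TCGA")
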