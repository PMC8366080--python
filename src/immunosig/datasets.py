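"""Data containers and text-format I/O.

All expression data move through :class:`ExpressionDataset`, a gene-by-sample
matrix tagged with a cohort id and a value kind (``continuous`` for
log-intensity/array-like data, ``counts`` for RNA-seq-like non-negative
integers).  Immune reference profiles live in :class:`SignatureMatrix`
(genes x cell types, LM22 layout), gene sets in :class:`GeneSetCollection`
(GMT dialect).  Per-sample clinical annotation is carried as a plain
:class:`pandas.DataFrame` indexed by sample id with ``subtype`` and ``nodal``
columns restricted to closed vocabularies.

On-disk formats are tab-separated text throughout:

* expression: header row of sample ids, first column gene symbols;
* metadata: columns ``sample_id``, ``subtype``, ``nodal``;
* signature: first column gene symbol, remaining columns cell types;
* gene sets: standard GMT (name, description, member genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataValidationError, ParseError

logger = logging.getLogger(__name__)

VALUE_KINDS = ("continuous", "counts")
SUBTYPE_LEVELS = ("Luminal", "HER2", "TNBC", "missing")
NODAL_LEVELS = ("negative", "positive", "missing")


def _first_offending_cell(values: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(mask)[0]
    return str(values.index[i]), str(values.columns[j])


@dataclass
class ExpressionDataset:
    """Gene-by-sample expression matrix for one cohort.

    Parameters
    ----------
    cohort_id:
        Short identifier of the cohort (used in output file names and in
        cross-cohort tables).
    values:
        Numeric DataFrame, genes on the index, samples on the columns.
        Gene and sample ids must be unique; missing values are rejected.
    value_kind:
        ``"continuous"`` or ``"counts"``.  Count matrices must contain
        non-negative integers only.
    """

    cohort_id: str
    values: pd.DataFrame
    value_kind: str = "continuous"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise DataValidationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise DataValidationError("values must be a pandas DataFrame")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample ids: {dups[:5]}")
        try:
            arr = v.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise DataValidationError(f"non-numeric expression values: {exc}") from exc
        if np.isnan(arr).any():
            g, s = _first_offending_cell(v, np.isnan(arr))
            raise DataValidationError(
                f"missing value at gene {g!r}, sample {s!r}; matrices must be complete"
            )
        if self.value_kind == "counts":
            if (arr < 0).any():
                g, s = _first_offending_cell(v, arr < 0)
                raise DataValidationError(f"negative count at gene {g!r}, sample {s!r}")
            frac = arr != np.floor(arr)
            if frac.any():
                g, s = _first_offending_cell(v, frac)
                raise DataValidationError(
                    f"non-integer count at gene {g!r}, sample {s!r}"
                )
        self.values = v.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)

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


@dataclass
class SignatureMatrix:
    """Reference expression profiles: signature genes x immune cell types.

    Mirrors the layout of the LM22 leukocyte signature (547 genes, 22 cell
    types); any non-negative genes-by-cell-types matrix with >= 2 cell types
    is accepted.
    """

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.profiles
        if not isinstance(p, pd.DataFrame):
            raise DataValidationError("profiles must be a pandas DataFrame")
        if p.index.has_duplicates:
            raise DataValidationError("duplicate gene ids in signature")
        if p.shape[1] < 2:
            raise DataValidationError("signature needs at least 2 cell types")
        arr = p.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise DataValidationError("signature profiles contain missing values")
        if (arr < 0).any():
            raise DataValidationError("signature profiles must be non-negative")
        self.profiles = p.astype(float)
        self.profiles.index = self.profiles.index.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def cell_type_ids(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def n_genes(self) -> int:
        return self.profiles.shape[0]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT carrier for KEGG-style pathway collections)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise DataValidationError(f"duplicate gene set names: {dups[:5]}")
        for s in self.sets:
            if len(s.genes) == 0:
                raise DataValidationError(f"gene set {s.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return {s.name: s.genes for s in self.sets}


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    path: str | Path, value_kind: str, cohort_id: str | None = None
) -> ExpressionDataset:
    """Read a genes-x-samples expression TSV.

    Duplicate gene symbols are collapsed by keeping the row with the highest
    mean expression (common microarray probe-collapse convention); the rule
    and the affected symbols are logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ParseError(
                    f"{path}: non-numeric value {df.loc[bad[0], col]!r} at "
                    f"gene {bad[0]!r}, sample {col!r}"
                )
            df[col] = coerced
    if df.isna().to_numpy().any():
        raise ParseError(f"{path}: matrix contains empty cells")
    if df.index.has_duplicates:
        means = df.to_numpy(dtype=float).mean(axis=1)
        best: dict[str, int] = {}
        for i, g in enumerate(df.index):
            if g not in best or means[i] > means[best[g]]:
                best[g] = i
        keep = sorted(best.values())
        dups = df.index[df.index.duplicated()].unique().tolist()
        logger.warning(
            "%s: collapsed %d duplicated gene symbol(s) by keeping the "
            "highest-mean row: %s",
            path,
            len(dups),
            ", ".join(map(str, dups[:10])),
        )
        df = df.iloc[keep]
    return ExpressionDataset(cohort_id or path.stem, df, value_kind)


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    df = ds.values
    if ds.value_kind == "counts":
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="gene")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata TSV (sample_id, subtype, nodal)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subtype", "nodal"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: metadata must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        raise DataValidationError(f"{path}: duplicate sample_id in metadata")
    df = df.fillna("missing").set_index("sample_id")
    for col, levels in (("subtype", SUBTYPE_LEVELS), ("nodal", NODAL_LEVELS)):
        bad = set(df[col]) - set(levels)
        if bad:
            raise DataValidationError(
                f"{path}: invalid {col} value(s) {sorted(bad)}; allowed {levels}"
            )
    return df[["subtype", "nodal"]]


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta[["subtype", "nodal"]].to_csv(path, sep="\t", index_label="sample_id")


def read_signature(path: str | Path) -> SignatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureMatrix(df)


def write_signature(sig: SignatureMatrix, path: str | Path) -> None:
    sig.profiles.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from GMT: name TAB description TAB gene [TAB gene ...]."""
    path = Path(path)
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            genes = tuple(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in names:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            names.add(name)
            sets.append(GeneSet(name, desc, genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write an analysis result table as TSV with a stable column order."""
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


# ---------------------------------------------------------------------------
# dataset-level operations


def intersect_signature(
    ds: ExpressionDataset, sig: SignatureMatrix
) -> tuple[list[str], dict[str, int]]:
    """Signature genes measured by a cohort, in signature order.

    Returns the retained gene list and a ``{"present": .., "absent": ..}``
    report.  Raises when the cohort measures none of the signature genes
    (classification is then impossible).
    """
    have = set(ds.gene_ids)
    retained = [g for g in sig.gene_ids if g in have]
    report = {"present": len(retained), "absent": sig.n_genes - len(retained)}
    if not retained:
        raise DataValidationError(
            f"cohort {ds.cohort_id!r} shares no genes with the signature; "
            "immune classification impossible"
        )
    logger.info(
        "cohort %s: %d/%d signature genes present",
        ds.cohort_id,
        report["present"],
        sig.n_genes,
    )
    return retained, report


def standardize(ds: ExpressionDataset) -> ExpressionDataset:
    """Per-gene z-score across samples within one dataset.

    Uses the sample (n-1) standard deviation.  Zero-variance genes map to
    all-zero rows with a warning.  Count matrices must be converted to
    log-CPM first (see :mod:`immunosig.de`).
    """
    if ds.value_kind != "continuous":
        raise DataValidationError(
            "standardize requires continuous values; run counts through "
            "log_cpm first"
        )
    if ds.n_samples < 2:
        raise DataValidationError("cannot standardize a single-sample dataset")
    arr = ds.values.to_numpy()
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0).ravel()
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (arr - mu) / sd_safe
    if const.any():
        z[const, :] = 0.0
        logger.warning(
            "cohort %s: %d zero-variance gene(s) set to all-zero after "
            "standardization",
            ds.cohort_id,
            int(const.sum()),
        )
    out = pd.DataFrame(z, index=ds.values.index, columns=ds.values.columns)
    return ExpressionDataset(ds.cohort_id, out, "continuous")
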