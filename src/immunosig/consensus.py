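"""Cross-cohort consensus filtering of differential-expression results.

A gene is a consensus hit when it was tested in every cohort (intersection
universe: a cohort cannot validate what it never measured), is significant
at the FDR threshold in every cohort, and has the same log-fold-change sign
everywhere.  The method intersects result lists; it does not pool effect
sizes meta-analytically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import SignatureMatrix
from .exceptions import DataValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusCriteria:
    """Filtering rules for cross-cohort validation."""

    fdr_threshold: float = 0.05
    require_all_cohorts: bool = True
    require_sign_consistency: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise DataValidationError("fdr_threshold must be in (0, 1)")


def consensus_filter(
    tables: Mapping[str, pd.DataFrame], criteria: ConsensusCriteria | None = None
) -> pd.DataFrame:
    """Intersect per-cohort DE tables into a consensus gene list.

    ``tables`` maps cohort id to a DE table indexed by gene with ``logFC``
    and ``fdr`` columns.  The output has one row per consensus gene with its
    direction (up/down, from the shared sign), per-cohort logFC and FDR, and
    is sorted by the smallest absolute logFC across cohorts (descending),
    ties broken by gene name.  The result is invariant to cohort ordering.
    """
    criteria = criteria or ConsensusCriteria()
    if not tables:
        raise DataValidationError("no DE tables given")
    if len(tables) < 2:
        raise DataValidationError("consensus needs >= 2 cohorts")
    cohorts = sorted(tables)
    shared = None
    for cid in cohorts:
        t = tables[cid]
        if not {"logFC", "fdr"}.issubset(t.columns):
            raise DataValidationError(f"table {cid!r} lacks logFC/fdr columns")
        genes = set(t.index)
        shared = genes if shared is None else shared & genes
    shared = sorted(shared)
    if not shared:
        logger.warning("no genes shared across all cohorts")

    frame = pd.DataFrame(index=pd.Index(shared, name="gene"))
    for cid in cohorts:
        t = tables[cid].loc[shared]
        frame[f"logFC_{cid}"] = t["logFC"]
        frame[f"fdr_{cid}"] = t["fdr"]

    fdr_cols = [f"fdr_{c}" for c in cohorts]
    lfc_cols = [f"logFC_{c}" for c in cohorts]
    sig = frame[fdr_cols].to_numpy() < criteria.fdr_threshold
    signs = np.sign(frame[lfc_cols].to_numpy())

    if criteria.require_all_cohorts:
        passing = sig.all(axis=1)
        sign_ref = signs
    else:
        passing = sig.sum(axis=1) >= 2
        # sign checked over significant cohorts only in the relaxed mode
        sign_ref = np.where(sig, signs, np.nan)
    if criteria.require_sign_consistency:
        with np.errstate(invalid="ignore"):
            smin = np.nanmin(sign_ref, axis=1)
            smax = np.nanmax(sign_ref, axis=1)
        consistent = (smin == smax) & (smin != 0) & ~np.isnan(smin)
        passing = passing & consistent

    out = frame[passing].copy()
    mean_sign = np.sign(out[lfc_cols].mean(axis=1))
    out.insert(0, "direction", np.where(mean_sign > 0, "up", "down"))
    out["min_abs_logFC"] = out[lfc_cols].abs().min(axis=1)
    out = out.sort_values(
        ["min_abs_logFC", "gene"], ascending=[False, True], kind="mergesort"
    )
    logger.info(
        "consensus: %d/%d shared genes pass (fdr<%g in %s cohorts, sign %s)",
        len(out), len(shared), criteria.fdr_threshold,
        "all" if criteria.require_all_cohorts else ">=2",
        "required" if criteria.require_sign_consistency else "free",
    )
    return out


def partition_by_signature(
    table: pd.DataFrame, sig: SignatureMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a DE table into (signature genes, non-signature genes)."""
    mask = table.index.isin(sig.gene_ids)
    return table[mask], table[~mask]
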