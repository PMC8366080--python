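"""Gene-wise differential expression with empirical-Bayes variance moderation.

One inference engine serves all cohorts: a per-gene linear model (two-group
contrast, optionally with additive categorical covariates) followed by
empirical-Bayes shrinkage of the residual variances toward a common prior.
The prior degrees of freedom d0 and prior variance s0^2 are estimated by
moment-matching the log residual variances (the digamma/trigamma equations
of the standard moderated-t derivation); posterior variances are

    s_post^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t-statistic logFC / (s_post * u_g) is referred to a t
distribution on d0 + d_g degrees of freedom.  P-values are adjusted by
Benjamini-Hochberg.

Count cohorts are brought onto this continuous path via trimmed-mean-of-
M-values (TMM) scaling factors and a log2-CPM transform, so array-like and
RNA-seq-like cohorts share one tested engine.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset, SignatureMatrix
from .exceptions import DataValidationError

logger = logging.getLogger(__name__)

#: d0 above this is treated as infinite (pure common-variance limit)
MAX_PRIOR_DF = 1e6


@dataclass(frozen=True)
class Contrast:
    """Two-group comparison: ``group_a`` minus ``group_b`` on the log2 scale."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    scope: str = "all"
    gene_scope: str = "all"

    def __post_init__(self) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if a & b:
            raise DataValidationError("contrast groups must be disjoint")
        if len(a) < 2 or len(b) < 2:
            raise DataValidationError("each contrast group needs >= 2 samples")


@dataclass
class EBayesFit:
    """Fitted shrinkage state: prior (d0, s0^2) and per-gene variances."""

    d0: float
    s0_sq: float
    df_resid: float
    s_g_sq: pd.Series
    s_post_sq: pd.Series


# ---------------------------------------------------------------------------
# count normalization


def tmm_factors(counts: ExpressionDataset) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    The reference column is the one whose upper-quartile (of counts scaled
    by library size) is closest to the mean upper-quartile.  Per column,
    gene-wise log-ratios M and average log-abundances A are computed against
    the reference; the 30% most extreme M on each side and the 5% most
    extreme A on each side are trimmed, and the factor is the
    precision-weighted mean of the remaining M.  Factors are rescaled to a
    geometric mean of 1 (so they multiply to 1).
    """
    if counts.value_kind != "counts":
        raise DataValidationError("tmm_factors requires a counts dataset")
    arr = counts.values.to_numpy(dtype=float)
    arr = arr[arr.sum(axis=1) > 0]  # all-zero genes carry no information
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        bad = [s for s, l in zip(counts.sample_ids, lib) if l == 0]
        raise DataValidationError(f"all-zero library for sample(s) {bad[:5]}")
    uq = np.array([np.quantile(arr[:, j], 0.75) for j in range(arr.shape[1])]) / lib
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    ref = arr[:, ref_j]
    n_ref = lib[ref_j]

    factors = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        factors[j] = _tmm_pair(arr[:, j], ref, lib[j], n_ref)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    logratio_trim: float = 0.3, sum_trim: float = 0.05, a_cutoff: float = -1e10,
) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > a_cutoff)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = stats.rankdata(log_r)
    rank_e = stats.rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def log_cpm(
    counts: ExpressionDataset,
    factors: pd.Series | None = None,
    prior: float = 0.5,
) -> ExpressionDataset:
    """log2 counts-per-million with a small prior count:

        log2((count + prior) / (library_size * factor + 2 * prior) * 1e6).
    """
    if counts.value_kind != "counts":
        raise DataValidationError("log_cpm requires a counts dataset")
    if factors is None:
        factors = pd.Series(1.0, index=counts.sample_ids)
    f = factors.reindex(counts.sample_ids)
    if f.isna().any() or (f <= 0).any():
        raise DataValidationError("normalization factors must be positive, one per sample")
    arr = counts.values.to_numpy(dtype=float)
    lib = arr.sum(axis=0) * f.to_numpy()
    out = np.log2((arr + prior) / (lib[None, :] + 2 * prior) * 1e6)
    return ExpressionDataset(
        counts.cohort_id,
        pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns),
        "continuous",
    )


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.isnan(arr).any():
        raise DataValidationError("p-values contain NaN")
    if (arr <= 0).any() or (arr > 1).any():
        raise DataValidationError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# empirical-Bayes engine


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def estimate_prior(s_g_sq: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Matches the mean and variance of log s_g^2 to the scaled-F model for
    gene variances.  When the observed spread of log-variances is no larger
    than sampling noise alone, d0 is infinite and s0^2 is the common
    variance on the log scale.
    """
    s = np.asarray(s_g_sq, dtype=float)
    if (s <= 0).any():
        raise DataValidationError("residual variances must be positive")
    dg = float(df_resid)
    e = np.log(s) - float(polygamma(0, dg / 2)) + math.log(dg / 2)
    e_bar = float(e.mean())
    # in the infinite-d0 limit the common variance is the plain mean of s_g^2
    if e.size < 2:
        logger.warning("single gene: prior df set to +inf (no spread to estimate)")
        return math.inf, float(s.mean())
    e_var = float(e.var(ddof=1))
    target = e_var - float(polygamma(1, dg / 2))
    if target <= 0:
        return math.inf, float(s.mean())
    d0 = 2.0 * _trigamma_inverse(target)
    if d0 > MAX_PRIOR_DF:
        return math.inf, float(s.mean())
    s0_sq = math.exp(e_bar + float(polygamma(0, d0 / 2)) - math.log(d0 / 2))
    return d0, s0_sq


def posterior_variances(
    s_g_sq: np.ndarray, df_resid: float, d0: float, s0_sq: float
) -> np.ndarray:
    """Shrink per-gene variances toward the prior."""
    s = np.asarray(s_g_sq, dtype=float)
    if math.isinf(d0):
        return np.full_like(s, s0_sq)
    return (d0 * s0_sq + df_resid * s) / (d0 + df_resid)


def moderated_t(
    logfc: np.ndarray,
    s_g_sq: np.ndarray,
    df_resid: float,
    stdev_unscaled: float,
    d0: float,
    s0_sq: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Moderated t, two-sided p and total df for given prior parameters.

    Exposed separately so the two limits (d0 -> 0: ordinary t; d0 -> inf:
    common-variance t) can be exercised directly.
    """
    s_post = posterior_variances(s_g_sq, df_resid, d0, s0_sq)
    t = np.asarray(logfc, dtype=float) / (np.sqrt(s_post) * stdev_unscaled)
    df_total = d0 + df_resid
    p = 2 * stats.t.sf(np.abs(t), df_total)
    return t, np.clip(p, np.nextafter(0, 1), 1.0), df_total


def _build_design(
    samples: list[str],
    group_a: set[str],
    covariates: pd.DataFrame | None,
) -> tuple[np.ndarray, list[str]]:
    g = np.array([1.0 if s in group_a else 0.0 for s in samples])
    cols = [np.ones(len(samples)), g]
    names = ["intercept", "group"]
    if covariates is not None:
        cov = covariates.loc[samples]
        for c in cov.columns:
            dummies = pd.get_dummies(cov[c], prefix=c, drop_first=True, dtype=float)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy())
                names.append(name)
    return np.column_stack(cols), names


def fit_ebayes(
    expr: ExpressionDataset | pd.DataFrame,
    group_a,
    group_b,
    covariates: pd.DataFrame | None = None,
) -> tuple[EBayesFit, pd.DataFrame]:
    """Fit the moderated-t model for a two-group contrast.

    Parameters
    ----------
    expr:
        Continuous expression (dataset or genes-x-samples frame).
    group_a, group_b:
        Disjoint sample-id collections, each of size >= 2 after dropping
        samples with missing covariate categories (listwise).
    covariates:
        Optional frame indexed by sample id with categorical columns (e.g.
        subtype, nodal) entered as additive indicator covariates; the level
        ``missing`` triggers listwise removal.

    Returns the :class:`EBayesFit` and a result table with per-gene logFC
    (group_a minus group_b, log2 units), average expression, moderated t,
    total df, p-value and BH FDR, indexed by gene in input order.
    """
    if isinstance(expr, ExpressionDataset):
        if expr.value_kind != "continuous":
            raise DataValidationError(
                "fit_ebayes needs continuous values; run counts through log_cpm"
            )
        values = expr.values
    else:
        values = expr
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise DataValidationError("contrast groups must be disjoint")
    missing = (set(group_a) | set(group_b)) - set(values.columns)
    if missing:
        raise DataValidationError(
            f"samples not in expression matrix: {sorted(missing)[:5]}"
        )
    if covariates is not None:
        keep = covariates.index[(covariates != "missing").all(axis=1)]
        dropped = (set(group_a) | set(group_b)) - set(keep)
        if dropped:
            logger.warning(
                "dropping %d sample(s) with missing covariate categories", len(dropped)
            )
        group_a = [s for s in group_a if s in set(keep)]
        group_b = [s for s in group_b if s in set(keep)]
    if len(group_a) < 2 or len(group_b) < 2:
        raise DataValidationError("each group needs >= 2 usable samples")

    samples = group_a + group_b
    Y = values[samples].to_numpy(dtype=float)
    genes = values.index

    # genes with zero variance in both groups carry no evidence either way
    na, nb = len(group_a), len(group_b)
    var_a = Y[:, :na].var(axis=1)
    var_b = Y[:, na:].var(axis=1)
    dead = (var_a == 0) & (var_b == 0)
    if dead.any():
        logger.warning(
            "dropping %d gene(s) with zero variance in both groups", int(dead.sum())
        )
        Y = Y[~dead]
        genes = genes[~dead]
    if Y.shape[0] == 0:
        raise DataValidationError("no genes with non-zero variance")

    X, _ = _build_design(samples, set(group_a), covariates)
    rank = np.linalg.matrix_rank(X)
    n = X.shape[0]
    df_resid = n - rank
    if df_resid < 1:
        raise DataValidationError("design has no residual degrees of freedom")
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = Y @ X @ xtx_inv.T  # (G, p)
    resid = Y - beta @ X.T
    rss = (resid**2).sum(axis=1)
    s_g_sq = rss / df_resid
    tiny = s_g_sq <= 1e-12
    if tiny.any():
        logger.warning(
            "dropping %d gene(s) with numerically zero residual variance",
            int(tiny.sum()),
        )
        keep = ~tiny
        Y, beta, s_g_sq, genes = Y[keep], beta[keep], s_g_sq[keep], genes[keep]
    logfc = beta[:, 1]
    stdev_unscaled = float(np.sqrt(xtx_inv[1, 1]))

    d0, s0_sq = estimate_prior(s_g_sq, df_resid)
    t, _, df_total = moderated_t(logfc, s_g_sq, df_resid, stdev_unscaled, d0, s0_sq)
    # information cannot exceed the pooled residual df of all genes
    df_total = min(df_total, df_resid * len(s_g_sq))
    p = np.clip(2 * stats.t.sf(np.abs(t), df_total), np.nextafter(0, 1), 1.0)
    fdr = bh_adjust(p)

    fit = EBayesFit(
        d0=d0,
        s0_sq=s0_sq,
        df_resid=df_resid,
        s_g_sq=pd.Series(s_g_sq, index=genes),
        s_post_sq=pd.Series(
            posterior_variances(s_g_sq, df_resid, d0, s0_sq), index=genes
        ),
    )
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "avg_expr": Y.mean(axis=1),
            "t_mod": t,
            "df_total": df_total,
            "p_value": p,
            "fdr": fdr,
        },
        index=pd.Index(genes, name="gene"),
    )
    logger.info(
        "moderated t: %d genes, d0=%.3g, s0^2=%.3g, %d at FDR<0.05",
        len(table), d0, s0_sq, int((table["fdr"] < 0.05).sum()),
    )
    return fit, table


class EmpiricalBayesDE(BaseEstimator):
    """Sklearn-style wrapper: fit a two-group moderated-t model.

    Attributes (after :meth:`fit`): ``prior_df_`` (d0), ``prior_var_``
    (s0^2), ``fit_`` (:class:`EBayesFit`) and ``results_`` (the DE table).
    """

    def __init__(self, covariate_columns: tuple[str, ...] = ()):
        self.covariate_columns = covariate_columns

    def fit(self, expr, groups, covariates: pd.DataFrame | None = None):
        """``groups`` maps sample id -> "a"/"b" (dict or Series)."""
        groups = pd.Series(groups)
        group_a = groups.index[groups == "a"].tolist()
        group_b = groups.index[groups == "b"].tolist()
        cov = None
        if covariates is not None and len(self.covariate_columns):
            cov = covariates[list(self.covariate_columns)]
        self.fit_, self.results_ = fit_ebayes(expr, group_a, group_b, cov)
        self.prior_df_ = self.fit_.d0
        self.prior_var_ = self.fit_.s0_sq
        return self

    def transform(self, X=None) -> pd.DataFrame:
        if not hasattr(self, "results_"):
            raise NotFittedError("EmpiricalBayesDE is not fitted")
        return self.results_


# ---------------------------------------------------------------------------
# contrast construction


def build_contrast(
    calls: pd.DataFrame,
    meta: pd.DataFrame | None,
    kind: str,
    subtype: str | None = None,
) -> Contrast:
    """Assemble the standard two-group contrasts used in the pipeline.

    ``rich_vs_poor``: immune-rich vs immune-poor (optionally within one
    subtype); ``subtype_vs_rest``: one subtype vs all others grouped (not
    pairwise); ``rich_only_subtype``: the same restricted to immune-rich
    samples.
    """
    labels = calls.set_index("sample_id")["label"]
    if kind == "rich_vs_poor":
        pool = labels.index
        if subtype is not None:
            if meta is None:
                raise DataValidationError("subtype restriction requires metadata")
            pool = pool.intersection(meta.index[meta["subtype"] == subtype])
        a = [s for s in pool if labels[s] == "rich"]
        b = [s for s in pool if labels[s] == "poor"]
        name = f"rich_vs_poor{'_' + subtype if subtype else ''}"
        return Contrast(name, tuple(a), tuple(b), scope="all")
    if kind in ("subtype_vs_rest", "rich_only_subtype"):
        if meta is None or subtype is None:
            raise DataValidationError(f"{kind} requires metadata and a subtype")
        pool = labels.index.intersection(meta.index)
        if kind == "rich_only_subtype":
            pool = pool[labels.loc[pool] == "rich"]
        sub = meta.loc[pool, "subtype"]
        a = list(pool[sub == subtype])
        b = list(pool[(sub != subtype) & (sub != "missing")])
        scope = "within_rich" if kind == "rich_only_subtype" else "all"
        return Contrast(f"{kind}_{subtype}", tuple(a), tuple(b), scope=scope)
    raise DataValidationError(f"unknown contrast kind {kind!r}")


def restrict_gene_scope(
    table: pd.DataFrame, sig: SignatureMatrix, gene_scope: str
) -> pd.DataFrame:
    """Restrict a DE table to signature (lm22_only) or non-signature genes."""
    if gene_scope == "all":
        return table
    in_sig = table.index.isin(sig.gene_ids)
    if gene_scope in ("lm22", "lm22_only"):
        return table[in_sig]
    if gene_scope == "non_lm22":
        return table[~in_sig]
    raise DataValidationError(f"unknown gene_scope {gene_scope!r}")
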