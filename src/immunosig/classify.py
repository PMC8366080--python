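"""Monte-Carlo permutation test for immune-rich / immune-poor phenotyping.

For each tumor sample the observed statistic is the Pearson correlation
between the sample's expression over the measured signature genes and a
reference vector derived from the signature matrix (by default the per-gene
mean of the cell-type profiles).  The null distribution is built by drawing
B random gene subsets of the same size from the sample's full transcriptome
(without replacement within a draw, signature genes not excluded) and
correlating each against the same reference vector.  The permutation
p-value uses the add-one estimator

    p = (1 + #{r_b >= r_obs}) / (B + 1),

which is strictly positive, lies on the grid {k/(B+1)} and is exactly
uniform on that grid under the null.  Samples with p below ``alpha``
(default 0.05, B default 1000) are labeled immune-rich, all others
immune-poor.

Expression is expected to be standardized per dataset (see
:func:`immunosig.datasets.standardize`) before classification.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .datasets import ExpressionDataset, SignatureMatrix, intersect_signature
from .exceptions import DataValidationError

logger = logging.getLogger(__name__)

REFERENCE_MODES = ("row_mean",)


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable parameters of the permutation classifier."""

    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0
    reference_mode: str = "row_mean"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise DataValidationError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise DataValidationError("alpha must be in (0, 1)")
        if self.reference_mode not in REFERENCE_MODES:
            raise DataValidationError(
                f"reference_mode must be one of {REFERENCE_MODES}"
            )


@dataclass(frozen=True)
class ImmuneCall:
    """Per-sample classification outcome."""

    sample_id: str
    r_obs: float
    p_value: float
    label: str
    n_signature_genes_used: int


def reference_vector(
    sig: SignatureMatrix, retained_genes: list[str] | None = None
) -> np.ndarray:
    """Per-gene mean of the signature profiles across cell types, restricted
    to ``retained_genes`` in signature order."""
    profiles = sig.profiles
    if retained_genes is not None:
        if len(retained_genes) == 0:
            raise DataValidationError("retained gene set is empty")
        missing = set(retained_genes) - set(profiles.index)
        if missing:
            raise DataValidationError(
                f"retained genes not in signature: {sorted(missing)[:5]}"
            )
        profiles = profiles.loc[retained_genes]
    return profiles.to_numpy().mean(axis=1)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises on vectors shorter than 3 or with zero variance (the classifier
    maps the latter case to p = 1 / immune-poor at a higher level).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataValidationError("pearson_r needs two equal-length 1-d vectors")
    if x.size < 3:
        raise DataValidationError("pearson_r needs length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc**2).sum() * (yc**2).sum())
    if den == 0:
        raise DataValidationError("correlation undefined for constant input")
    return float(np.clip((xc * yc).sum() / den, -1.0, 1.0))


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # per-sample stream keyed on (seed, crc32(sample_id)): cohort results are
    # independent of sample order
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(str(sample_id).encode("utf8"))])
    )


def _null_correlations(
    values: np.ndarray, ref_centered: np.ndarray, ref_norm: float,
    m: int, n_perm: int, rng: np.random.Generator,
) -> np.ndarray:
    keys = rng.random((n_perm, values.size))
    idx = np.argpartition(keys, m, axis=1)[:, :m]
    sub = values[idx]
    sub = sub - sub.mean(axis=1, keepdims=True)
    num = sub @ ref_centered
    den = np.sqrt((sub**2).sum(axis=1)) * ref_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return r


def classify_sample(
    sample_values,
    gene_ids,
    sig: SignatureMatrix,
    cfg: ClassifierConfig,
    sample_id: str = "sample",
    rng: np.random.Generator | None = None,
    _positions: np.ndarray | None = None,
    _reference: np.ndarray | None = None,
) -> ImmuneCall:
    """Classify one sample's full-transcriptome vector as rich/poor."""
    values = np.asarray(sample_values, dtype=float)
    gene_index = pd.Index(gene_ids)
    if values.size != gene_index.size:
        raise DataValidationError("expression vector and gene id list differ in length")
    if _positions is None:
        retained = [g for g in sig.gene_ids if g in set(gene_index)]
        if not retained:
            raise DataValidationError("no signature genes present in transcriptome")
        _positions = gene_index.get_indexer(retained)
        _reference = reference_vector(sig, retained)
    m = _positions.size
    if values.size <= m:
        raise DataValidationError(
            "transcriptome must be larger than the retained signature"
        )
    if rng is None:
        rng = _sample_rng(cfg.seed, sample_id)

    ref = _reference
    ref_c = ref - ref.mean()
    ref_norm = float(np.sqrt((ref_c**2).sum()))
    x = values[_positions]
    xc = x - x.mean()
    x_norm = float(np.sqrt((xc**2).sum()))
    if x_norm == 0 or ref_norm == 0 or np.ptp(values) == 0:
        logger.warning(
            "sample %s: constant expression vector, correlation undefined; "
            "p set to 1 (immune-poor)",
            sample_id,
        )
        return ImmuneCall(str(sample_id), float("nan"), 1.0, "poor", m)
    r_obs = float(np.clip((xc * ref_c).sum() / (x_norm * ref_norm), -1.0, 1.0))

    r_null = _null_correlations(values, ref_c, ref_norm, m, cfg.n_permutations, rng)
    n_ge = int(np.sum(r_null >= r_obs))  # ties count toward the numerator
    p = (1 + n_ge) / (cfg.n_permutations + 1)
    label = "rich" if p < cfg.alpha else "poor"
    return ImmuneCall(str(sample_id), r_obs, p, label, m)


class SignatureCorrelationClassifier(BaseEstimator):
    """Sklearn-style estimator wrapping the permutation test.

    Parameters
    ----------
    n_permutations:
        Number of random gene subsets per sample (B).
    alpha:
        Significance threshold below which a sample is labeled immune-rich.
    random_state:
        Base seed; each sample gets its own stream derived from
        (random_state, sample_id) so results are order-independent.
    reference_mode:
        How the reference vector is built from the signature; currently
        ``"row_mean"`` (per-gene mean across cell types).

    Attributes
    ----------
    signature_ : SignatureMatrix
        The signature supplied to :meth:`fit`.
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        alpha: float = 0.05,
        random_state: int = 0,
        reference_mode: str = "row_mean",
    ):
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.random_state = random_state
        self.reference_mode = reference_mode

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            seed=self.random_state,
            reference_mode=self.reference_mode,
        )

    def fit(self, signature: SignatureMatrix, y=None) -> "SignatureCorrelationClassifier":
        self._config()  # validate parameters
        if not isinstance(signature, SignatureMatrix):
            raise DataValidationError("fit expects a SignatureMatrix")
        self.signature_ = signature
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "signature_"):
            raise NotFittedError(
                "SignatureCorrelationClassifier must be fit with a signature first"
            )

    def classify(self, ds: ExpressionDataset) -> pd.DataFrame:
        """Classify every sample of a (standardized) dataset.

        Returns a DataFrame with columns sample_id, r_obs, p_value, label,
        n_signature_genes_used.
        """
        self._check_fitted()
        cfg = self._config()
        retained, report = intersect_signature(ds, self.signature_)
        if ds.n_genes <= len(retained):
            raise DataValidationError(
                "transcriptome must be larger than the retained signature"
            )
        positions = ds.values.index.get_indexer(retained)
        ref = reference_vector(self.signature_, retained)
        arr = ds.values.to_numpy()
        calls = []
        for j, sid in enumerate(ds.sample_ids):
            call = classify_sample(
                arr[:, j],
                ds.values.index,
                self.signature_,
                cfg,
                sample_id=sid,
                _positions=positions,
                _reference=ref,
            )
            calls.append(call)
        out = pd.DataFrame([c.__dict__ for c in calls])
        logger.info(
            "cohort %s: %d/%d samples immune-rich (B=%d, alpha=%g, %d/%d "
            "signature genes used)",
            ds.cohort_id, int((out["label"] == "rich").sum()), len(out),
            cfg.n_permutations, cfg.alpha, report["present"],
            self.signature_.n_genes,
        )
        return out

    def predict(self, ds: ExpressionDataset) -> np.ndarray:
        """Labels only (``"rich"``/``"poor"``), aligned with ds.sample_ids."""
        return self.classify(ds)["label"].to_numpy()


def classify_cohort(
    ds: ExpressionDataset, sig: SignatureMatrix, cfg: ClassifierConfig | None = None
) -> pd.DataFrame:
    """Functional wrapper over :class:`SignatureCorrelationClassifier`."""
    cfg = cfg or ClassifierConfig()
    clf = SignatureCorrelationClassifier(
        n_permutations=cfg.n_permutations,
        alpha=cfg.alpha,
        random_state=cfg.seed,
        reference_mode=cfg.reference_mode,
    )
    return clf.fit(sig).classify(ds)
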