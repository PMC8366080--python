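"""Synthetic multi-cohort breast-tumor expression studies with known truth.

The generator emulates the structure of a three-cohort bulk-expression study:
two array-like cohorts on a continuous log2 scale and one RNA-seq-like count
cohort, each measuring a different gene universe that covers only part of the
immune signature (so cross-platform signature intersection is exercised).
Every sample carries a latent immune-rich flag whose prevalence depends on
receptor subtype; immune-rich samples have their measured signature genes
shifted upward in proportion to the signature reference profile, and carry
planted differential-expression effects shared across all cohorts (consensus
positives), restricted to one cohort, or sign-flipped in one cohort
(consensus-negative controls).  Nodal status is independent of richness by
default, with an optional log-odds dependence knob for power studies.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence`, so identical configurations produce
bit-identical studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    SignatureMatrix,
    write_expression,
    write_gmt,
    write_metadata,
    write_signature,
    write_table,
)
from .exceptions import ConfigError

logger = logging.getLogger(__name__)

SUBTYPES = ("Luminal", "HER2", "TNBC")


@dataclass(frozen=True)
class CohortSpec:
    """Shape of one simulated cohort."""

    cohort_id: str
    n_samples: int = 300
    value_kind: str = "continuous"
    gene_universe_size: int = 5000
    signature_coverage_fraction: float = 0.98


DEFAULT_COHORTS: tuple[CohortSpec, ...] = (
    CohortSpec("arrayA", 300, "continuous", 5000, 0.98),
    CohortSpec("arrayB", 300, "continuous", 5000, 0.97),
    CohortSpec("rnaseqC", 300, "counts", 5000, 0.99),
)


def _default_subtype_probs() -> dict[str, float]:
    # non-missing subtype margins pooled over the three published cohorts
    return {"Luminal": 0.68, "HER2": 0.12, "TNBC": 0.20}


def _default_rich_probs() -> dict[str, float]:
    # Luminal tumors predominantly immune-poor; TNBC/HER2 more often rich
    return {"Luminal": 0.30, "HER2": 0.45, "TNBC": 0.55}


def _default_subtype_effects() -> dict[str, tuple]:
    # a few subtype-restricted genes in each direction, log2 units
    return {"TNBC": (1.0, 1.0, -1.0, -1.0), "Luminal": (-1.0, -1.0)}


@dataclass
class SimulationConfig:
    """Study-level parameters of the generator.

    Effects are on the log2 expression scale; ``signature_effect`` is the
    mean shift of measured signature genes in immune-rich samples, in
    within-gene standard-deviation units, distributed across genes in
    proportion to the signature reference profile.
    """

    seed: int = 0
    cohorts: tuple[CohortSpec, ...] = DEFAULT_COHORTS
    n_signature_genes: int = 547
    n_cell_types: int = 22
    subtype_probs: dict[str, float] = field(default_factory=_default_subtype_probs)
    subtype_missing_prob: float = 0.03
    rich_prob_by_subtype: dict[str, float] = field(default_factory=_default_rich_probs)
    nodal_positive_prob: float = 0.45
    nodal_missing_prob: float = 0.02
    nodal_rich_log_odds: float = 0.0
    signature_effect: float = 1.5
    de_gene_count: int = 100
    de_effect: float = 1.0
    cohort_specific_de_count: int = 20
    sign_flip_de_count: int = 10
    subtype_specific_genes: dict[str, tuple] = field(
        default_factory=_default_subtype_effects
    )
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (5e5, 1.5e6)

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ConfigError("at least one cohort required")
        ids = [c.cohort_id for c in self.cohorts]
        if len(set(ids)) != len(ids):
            raise ConfigError("cohort ids must be unique")
        for c in self.cohorts:
            if c.n_samples < 4:
                raise ConfigError(f"cohort {c.cohort_id}: n_samples must be >= 4")
            if not 0 < c.signature_coverage_fraction <= 1:
                raise ConfigError("signature_coverage_fraction must be in (0, 1]")
            if c.value_kind not in ("continuous", "counts"):
                raise ConfigError(f"unknown value_kind {c.value_kind!r}")
        if abs(sum(self.subtype_probs.get(s, 0.0) for s in SUBTYPES) - 1.0) > 1e-9:
            raise ConfigError("subtype_probs must sum to 1 over Luminal/HER2/TNBC")
        probs = [
            *self.subtype_probs.values(),
            *self.rich_prob_by_subtype.values(),
            self.subtype_missing_prob,
            self.nodal_positive_prob,
            self.nodal_missing_prob,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        effects = [
            self.signature_effect,
            self.de_effect,
            self.nodal_rich_log_odds,
            *(
                e[1] if isinstance(e, (tuple, list)) else e
                for effs in self.subtype_specific_genes.values()
                for e in effs
            ),
        ]
        if any(not math.isfinite(float(e)) for e in effects):
            raise ConfigError("effect sizes must be finite")
        if self.signature_effect < 0:
            raise ConfigError("signature_effect must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must be a positive pair lo <= hi")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "cohorts" in d:
            d["cohorts"] = tuple(
                c if isinstance(c, CohortSpec) else CohortSpec(**c)
                for c in d["cohorts"]
            )
        if "subtype_specific_genes" in d:
            d["subtype_specific_genes"] = {
                k: tuple(tuple(e) if isinstance(e, (list, tuple)) else e for e in v)
                for k, v in d["subtype_specific_genes"].items()
            }
        if "library_size_range" in d:
            d["library_size_range"] = tuple(d["library_size_range"])
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"invalid simulation config: {exc}") from exc


@dataclass
class GroundTruth:
    """Latent state of a simulated study.

    ``samples`` has one row per sample (cohort_id, sample_id, subtype_true,
    subtype, nodal, true_rich); ``gene_effects`` one row per planted effect
    (gene, kind, cohort, subtype, effect) where kind is one of ``signature``,
    ``consensus_de``, ``cohort_specific``, ``sign_flip``, ``subtype``.
    """

    samples: pd.DataFrame
    gene_effects: pd.DataFrame
    signature_genes: list[str]

    def true_rich(self, cohort_id: str) -> pd.Series:
        sub = self.samples[self.samples["cohort_id"] == cohort_id]
        return sub.set_index("sample_id")["true_rich"].astype(bool)

    def genes_of_kind(self, kind: str) -> list[str]:
        return self.gene_effects.loc[
            self.gene_effects["kind"] == kind, "gene"
        ].unique().tolist()


def sample_negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float, size=None
) -> np.ndarray:
    """NB draws parameterized by mean ``m`` and dispersion ``phi``
    (variance ``m + phi * m**2``)."""
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size if size is not None else mean.shape)


def _marker_profiles(
    rng: np.random.Generator, n_genes: int, n_cell_types: int
) -> np.ndarray:
    """Marker-structured reference profiles: a low Gamma baseline everywhere
    plus a large Gamma boost at each gene's marker cell type.

    Immune signature genes are cell-type markers (high in one or two cell
    types, near-zero elsewhere); this gives the per-gene mean profile the
    large cross-gene spread a correlation-based classifier relies on.
    """
    profiles = rng.gamma(2.0, 0.25, size=(n_genes, n_cell_types))
    marker = rng.integers(0, n_cell_types, size=n_genes)
    profiles[np.arange(n_genes), marker] += rng.gamma(2.0, 10.0, size=n_genes)
    return profiles


def signature_from_genes(
    gene_ids: Sequence[str], n_cell_types: int = 22, seed: int = 0
) -> SignatureMatrix:
    """Synthetic marker-structured signature over the given genes
    (non-negative by construction)."""
    rng = np.random.default_rng(seed)
    profiles = _marker_profiles(rng, len(gene_ids), n_cell_types)
    cols = [f"CT{j + 1:02d}" for j in range(n_cell_types)]
    return SignatureMatrix(pd.DataFrame(profiles, index=list(gene_ids), columns=cols))


def null_cohort(
    n_samples: int, n_genes: int, seed: int = 0, cohort_id: str = "null"
) -> ExpressionDataset:
    """Structureless cohort: every gene i.i.d. standard normal across samples.

    Used for classifier calibration; carries no immune signal by
    construction.
    """
    if n_samples < 2 or n_genes < 2:
        raise ConfigError("null_cohort needs n_samples >= 2 and n_genes >= 2")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_samples))
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    samples = [f"{cohort_id}_S{i + 1:04d}" for i in range(n_samples)]
    return ExpressionDataset(
        cohort_id, pd.DataFrame(values, index=genes, columns=samples), "continuous"
    )


def _resolve_subtype_genes(
    cfg: SimulationConfig, pool: list[str]
) -> list[tuple[str, str, float]]:
    """Expand subtype_specific_genes into (subtype, gene, effect) rows.

    Entries may be bare effects (a gene is assigned from the shared pool) or
    explicit (gene, effect) pairs.
    """
    out: list[tuple[str, str, float]] = []
    cursor = 0
    for subtype, effs in cfg.subtype_specific_genes.items():
        if subtype not in SUBTYPES:
            raise ConfigError(f"unknown subtype {subtype!r} in subtype_specific_genes")
        for e in effs:
            if isinstance(e, (tuple, list)):
                gene, effect = e
                gene = str(gene) if gene is not None else None
            else:
                gene, effect = None, float(e)
            if gene is None:
                gene = pool[cursor]
                cursor += 1
            out.append((subtype, gene, float(effect)))
    return out


def simulate_study(
    cfg: SimulationConfig,
) -> tuple[list[ExpressionDataset], dict[str, pd.DataFrame], SignatureMatrix, GroundTruth]:
    """Generate a full multi-cohort study.

    Returns the expression datasets (one per cohort), per-cohort metadata
    frames (sample_id index; subtype, nodal), the synthetic signature matrix
    and the :class:`GroundTruth`.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(2 + len(cfg.cohorts))
    r_struct = np.random.default_rng(children[0])
    cohort_rngs = [np.random.default_rng(c) for c in children[2:]]

    S = cfg.n_signature_genes
    sig_genes = [f"IMM{i + 1:04d}" for i in range(S)]
    profiles = _marker_profiles(r_struct, S, cfg.n_cell_types)
    signature = SignatureMatrix(
        pd.DataFrame(
            profiles,
            index=sig_genes,
            columns=[f"CT{j + 1:02d}" for j in range(cfg.n_cell_types)],
        )
    )
    # infiltration weights: immune content added per signature gene tracks the
    # mean reference profile (unit mean, so signature_effect is the mean shift)
    w = profiles.mean(axis=1)
    w = w / w.mean()
    w_by_gene = dict(zip(sig_genes, w))

    n_covered = [round(c.signature_coverage_fraction * S) for c in cfg.cohorts]
    core_size = min(c.gene_universe_size - nc for c, nc in zip(cfg.cohorts, n_covered))
    n_planted = (
        cfg.de_gene_count
        + cfg.cohort_specific_de_count
        + cfg.sign_flip_de_count
        + sum(len(v) for v in cfg.subtype_specific_genes.values())
    )
    if core_size < n_planted + 10:
        raise ConfigError(
            "gene universes too small for the requested number of planted genes"
        )
    core = [f"G{i + 1:05d}" for i in range(core_size)]
    planted_pool = list(r_struct.choice(core, size=n_planted, replace=False))
    de_genes = planted_pool[: cfg.de_gene_count]
    k = cfg.de_gene_count
    cohort_specific = planted_pool[k : k + cfg.cohort_specific_de_count]
    k += cfg.cohort_specific_de_count
    sign_flip = planted_pool[k : k + cfg.sign_flip_de_count]
    k += cfg.sign_flip_de_count
    subtype_rows = _resolve_subtype_genes(cfg, planted_pool[k:])

    cohort_ids = [c.cohort_id for c in cfg.cohorts]
    specific_owner = {
        g: cohort_ids[i % len(cohort_ids)] for i, g in enumerate(cohort_specific)
    }
    flip_owner = {
        g: cohort_ids[i % len(cohort_ids)] for i, g in enumerate(sign_flip)
    }

    # shared per-gene baselines (log2 scale) so planted effects are
    # comparable across cohorts
    all_shared = sig_genes + core
    mu = dict(zip(all_shared, r_struct.normal(7.0, 1.5, size=len(all_shared))))
    sigma = dict(zip(all_shared, r_struct.uniform(0.8, 1.2, size=len(all_shared))))

    effect_rows = [
        {"gene": g, "kind": "signature", "cohort": "all", "subtype": "",
         "effect": cfg.signature_effect * w_by_gene[g]}
        for g in sig_genes
    ]
    effect_rows += [
        {"gene": g, "kind": "consensus_de", "cohort": "all", "subtype": "",
         "effect": cfg.de_effect}
        for g in de_genes
    ]
    effect_rows += [
        {"gene": g, "kind": "cohort_specific", "cohort": specific_owner[g],
         "subtype": "", "effect": cfg.de_effect}
        for g in cohort_specific
    ]
    effect_rows += [
        {"gene": g, "kind": "sign_flip", "cohort": flip_owner[g], "subtype": "",
         "effect": cfg.de_effect}
        for g in sign_flip
    ]
    effect_rows += [
        {"gene": g, "kind": "subtype", "cohort": "all", "subtype": st, "effect": e}
        for st, g, e in subtype_rows
    ]

    datasets: list[ExpressionDataset] = []
    metadata: dict[str, pd.DataFrame] = {}
    sample_rows: list[dict] = []
    p_subtype = np.array([cfg.subtype_probs[s] for s in SUBTYPES])
    base_logit = math.log(cfg.nodal_positive_prob / (1 - cfg.nodal_positive_prob)) \
        if 0 < cfg.nodal_positive_prob < 1 else None

    for spec, nc, rng in zip(cfg.cohorts, n_covered, cohort_rngs):
        covered_idx = np.sort(rng.choice(S, size=nc, replace=False))
        covered = [sig_genes[i] for i in covered_idx]
        n_priv = spec.gene_universe_size - nc - core_size
        private = [f"{spec.cohort_id}_P{i + 1:04d}" for i in range(n_priv)]
        genes = covered + core + private
        order = rng.permutation(len(genes))
        genes = [genes[i] for i in order]
        gene_index = {g: i for i, g in enumerate(genes)}

        n = spec.n_samples
        subtype_true = rng.choice(len(SUBTYPES), size=n, p=p_subtype)
        subtype_true = np.array([SUBTYPES[i] for i in subtype_true])
        rich = rng.random(n) < np.array(
            [cfg.rich_prob_by_subtype[s] for s in subtype_true]
        )
        if base_logit is None:
            p_nodal = np.full(n, cfg.nodal_positive_prob)
        else:
            logit = base_logit + cfg.nodal_rich_log_odds * rich
            p_nodal = 1.0 / (1.0 + np.exp(-logit))
        nodal = np.where(rng.random(n) < p_nodal, "positive", "negative")
        subtype_rec = np.where(
            rng.random(n) < cfg.subtype_missing_prob, "missing", subtype_true
        )
        nodal_rec = np.where(rng.random(n) < cfg.nodal_missing_prob, "missing", nodal)
        sample_ids = [f"{spec.cohort_id}_S{i + 1:04d}" for i in range(n)]

        # private genes get their own baselines
        priv_mask = np.array([g not in mu for g in genes])
        mu_arr = np.empty(len(genes))
        sd_arr = np.empty(len(genes))
        for i, g in enumerate(genes):
            if g in mu:
                mu_arr[i] = mu[g]
                sd_arr[i] = sigma[g]
        if priv_mask.any():
            mu_arr[priv_mask] = rng.normal(7.0, 1.5, size=priv_mask.sum())
            sd_arr[priv_mask] = rng.uniform(0.8, 1.2, size=priv_mask.sum())

        shift = np.zeros((len(genes), n))
        rich_cols = np.flatnonzero(rich)
        for g in covered:
            i = gene_index[g]
            shift[i, rich_cols] += cfg.signature_effect * w_by_gene[g] * sd_arr[i]
        for g in de_genes:
            shift[gene_index[g], rich_cols] += cfg.de_effect
        for g in cohort_specific:
            if specific_owner[g] == spec.cohort_id:
                shift[gene_index[g], rich_cols] += cfg.de_effect
        for g in sign_flip:
            sgn = -1.0 if flip_owner[g] == spec.cohort_id else 1.0
            shift[gene_index[g], rich_cols] += sgn * cfg.de_effect
        for st, g, e in subtype_rows:
            cols = np.flatnonzero(subtype_true == st)
            shift[gene_index[g], cols] += e

        if spec.value_kind == "continuous":
            values = (
                mu_arr[:, None]
                + shift
                + sd_arr[:, None] * rng.standard_normal((len(genes), n))
            )
        else:
            lam = np.exp2(mu_arr[:, None] + shift)
            lib = rng.uniform(*cfg.library_size_range, size=n)
            m = lam / lam.sum(axis=0, keepdims=True) * lib[None, :]
            values = sample_negative_binomial(rng, m, cfg.nb_dispersion).astype(float)

        df = pd.DataFrame(values, index=genes, columns=sample_ids)
        datasets.append(ExpressionDataset(spec.cohort_id, df, spec.value_kind))
        metadata[spec.cohort_id] = pd.DataFrame(
            {"subtype": subtype_rec, "nodal": nodal_rec},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        for i, sid in enumerate(sample_ids):
            sample_rows.append(
                {
                    "cohort_id": spec.cohort_id,
                    "sample_id": sid,
                    "subtype_true": subtype_true[i],
                    "subtype": subtype_rec[i],
                    "nodal": nodal_rec[i],
                    "true_rich": bool(rich[i]),
                }
            )
        logger.info(
            "simulated cohort %s: %d samples x %d genes (%s), %d rich, "
            "%d/%d signature genes covered",
            spec.cohort_id, n, len(genes), spec.value_kind, int(rich.sum()), nc, S,
        )

    truth = GroundTruth(
        samples=pd.DataFrame(sample_rows),
        gene_effects=pd.DataFrame(
            effect_rows, columns=["gene", "kind", "cohort", "subtype", "effect"]
        ),
        signature_genes=sig_genes,
    )
    return datasets, metadata, signature, truth


def synthetic_gene_sets(
    universe: Sequence[str],
    enriched_genes: Sequence[str] = (),
    n_random_sets: int = 40,
    set_size_range: tuple[int, int] = (20, 150),
    seed: int = 0,
) -> GeneSetCollection:
    """Gene sets for end-to-end demos: random sets drawn from the universe,
    plus (when ``enriched_genes`` given) one set concentrating those genes."""
    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets: list[GeneSet] = []
    if enriched_genes:
        pad = rng.choice(universe, size=min(50, len(universe)), replace=False)
        members = tuple(dict.fromkeys([*enriched_genes, *pad]))
        sets.append(GeneSet("SET_PLANTED_RESPONSE", "planted effect genes", members))
    for i in range(n_random_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        members = tuple(rng.choice(universe, size=min(size, len(universe)), replace=False))
        sets.append(GeneSet(f"SET_RANDOM_{i + 1:03d}", "random set", members))
    return GeneSetCollection(sets)


def write_study(
    outdir: str | Path,
    datasets: list[ExpressionDataset],
    metadata: dict[str, pd.DataFrame],
    signature: SignatureMatrix,
    truth: GroundTruth,
    gene_sets: GeneSetCollection | None = None,
) -> dict[str, Path]:
    """Write a simulated study to disk in the package's TSV/GMT formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for ds in datasets:
        p = outdir / f"expression_{ds.cohort_id}.tsv"
        write_expression(ds, p)
        paths[f"expression_{ds.cohort_id}"] = p
        m = outdir / f"metadata_{ds.cohort_id}.tsv"
        write_metadata(metadata[ds.cohort_id], m)
        paths[f"metadata_{ds.cohort_id}"] = m
    write_signature(signature, outdir / "signature.tsv")
    paths["signature"] = outdir / "signature.tsv"
    write_table(truth.samples, outdir / "truth_samples.tsv")
    paths["truth_samples"] = outdir / "truth_samples.tsv"
    write_table(truth.gene_effects, outdir / "truth_genes.tsv")
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    if gene_sets is not None:
        write_gmt(gene_sets, outdir / "gene_sets.gmt")
        paths["gene_sets"] = outdir / "gene_sets.gmt"
    return paths
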