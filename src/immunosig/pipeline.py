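"""End-to-end orchestration: simulate/load -> classify -> associate -> DE ->
consensus -> pathway over-representation, with a reproducible run manifest.

A :class:`PipelineConfig` (built in code or loaded from YAML/JSON) names the
input files per cohort, the classifier and consensus thresholds, and an
output directory.  ``run_pipeline`` executes every stage, writes all outputs
as TSV, and returns a manifest recording the package version, seed, SHA-256
hashes of inputs and outputs, and per-stage summaries.  Identical config and
seed give identical classifier output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .association import association_test
from .classify import ClassifierConfig, classify_cohort
from .consensus import ConsensusCriteria, consensus_filter, partition_by_signature
from .datasets import (
    ExpressionDataset,
    read_expression,
    read_gmt,
    read_metadata,
    read_signature,
    standardize,
    write_table,
)
from .de import build_contrast, fit_ebayes, log_cpm, tmm_factors
from .enrich import hypergeom_enrich, intersect_pathways
from .exceptions import ConfigError, DataValidationError, ImmunosigError
from .simulate import SimulationConfig, simulate_study, synthetic_gene_sets, write_study

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortInput:
    cohort_id: str
    expression: str
    value_kind: str = "continuous"
    metadata: str | None = None


@dataclass
class PipelineConfig:
    """Everything one run needs; paths are checked before any compute."""

    outdir: str = "immunosig_run"
    seed: int = 0
    cohorts: tuple[CohortInput, ...] = ()
    signature: str | None = None
    gene_sets: str | None = None
    n_permutations: int = 1000
    alpha: float = 0.05
    fdr_threshold: float = 0.05
    require_sign_consistency: bool = True
    simulate: SimulationConfig | None = None

    def validate(self) -> None:
        if self.simulate is None:
            if not self.cohorts:
                raise ConfigError("config needs cohorts (or a simulate section)")
            if self.signature is None:
                raise ConfigError("config needs a signature path")
            for path in [
                self.signature,
                self.gene_sets,
                *[c.expression for c in self.cohorts],
                *[c.metadata for c in self.cohorts if c.metadata],
            ]:
                if path is not None and not Path(path).exists():
                    raise ConfigError(f"input path does not exist: {path}")
        ClassifierConfig(self.n_permutations, self.alpha, self.seed)
        ConsensusCriteria(self.fdr_threshold, True, self.require_sign_consistency)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ConfigError(f"{path}: config must be a mapping")
        d = dict(raw)
        if "cohorts" in d:
            d["cohorts"] = tuple(
                CohortInput(**c) if not isinstance(c, CohortInput) else c
                for c in d["cohorts"]
            )
        if d.get("simulate") is not None:
            sim = dict(d["simulate"])
            sim.setdefault("seed", d.get("seed", 0))
            d["simulate"] = SimulationConfig.from_dict(sim)
        try:
            cfg = cls(**d)
        except TypeError as exc:
            raise ConfigError(f"{path}: invalid pipeline config: {exc}") from exc
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "inputs": {},
        "outputs": {},
        "stages": [],
    }

    def emit(name: str, df: pd.DataFrame, index_label: str | None = None) -> Path:
        path = outdir / f"{name}.tsv"
        write_table(df, path, index_label=index_label)
        manifest["outputs"][path.name] = _sha256(path)
        return path

    # ---- stage: inputs -------------------------------------------------
    stage = "load_inputs"
    try:
        if cfg.simulate is not None:
            datasets, metadata, signature, truth = simulate_study(cfg.simulate)
            planted = truth.genes_of_kind("consensus_de")
            shared = set(datasets[0].gene_ids)
            for ds in datasets[1:]:
                shared &= set(ds.gene_ids)
            gene_sets = synthetic_gene_sets(
                sorted(shared - set(truth.signature_genes)),
                enriched_genes=[g for g in planted if g in shared],
                seed=cfg.simulate.seed,
            )
            inputs_dir = outdir / "inputs"
            paths = write_study(
                inputs_dir, datasets, metadata, signature, truth, gene_sets
            )
            manifest["inputs"] = {k: _sha256(p) for k, p in paths.items()}
        else:
            datasets = [
                read_expression(c.expression, c.value_kind, c.cohort_id)
                for c in cfg.cohorts
            ]
            metadata = {
                c.cohort_id: read_metadata(c.metadata)
                for c in cfg.cohorts
                if c.metadata
            }
            signature = read_signature(cfg.signature)
            gene_sets = read_gmt(cfg.gene_sets) if cfg.gene_sets else None
            for c in cfg.cohorts:
                manifest["inputs"][c.cohort_id] = _sha256(Path(c.expression))
        manifest["stages"].append({"stage": stage, "cohorts": len(datasets)})
    except ImmunosigError as exc:
        raise ImmunosigError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: normalize + classify ----------------------------------
    calls_by_cohort: dict[str, pd.DataFrame] = {}
    continuous: dict[str, ExpressionDataset] = {}
    for ds in datasets:
        stage = f"classify[{ds.cohort_id}]"
        try:
            if ds.value_kind == "counts":
                factors = tmm_factors(ds)
                expr = log_cpm(ds, factors)
            else:
                expr = ds
            expr = standardize(expr)
            continuous[ds.cohort_id] = expr
            calls = classify_cohort(
                expr,
                signature,
                ClassifierConfig(cfg.n_permutations, cfg.alpha, cfg.seed),
            )
            calls_by_cohort[ds.cohort_id] = calls
            emit(f"calls_{ds.cohort_id}", calls)
            manifest["stages"].append(
                {
                    "stage": stage,
                    "n_samples": int(len(calls)),
                    "n_rich": int((calls["label"] == "rich").sum()),
                }
            )
        except ImmunosigError as exc:
            raise ImmunosigError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: association -------------------------------------------
    assoc_rows = []
    for cid, calls in calls_by_cohort.items():
        if cid not in metadata:
            continue
        for variable in ("subtype", "nodal"):
            stage = f"associate[{cid}:{variable}]"
            try:
                res = association_test(calls, metadata[cid], variable)
                assoc_rows.append(
                    {
                        "cohort": cid,
                        "variable": variable,
                        "chi2": res.chi2,
                        "df": res.df,
                        "p_value": res.p_value,
                        "excluded_missing": res.excluded_missing,
                    }
                )
            except DataValidationError as exc:
                # degenerate tables (e.g. a single label present) are a data
                # property, reported rather than fatal
                logger.warning("%s: not testable (%s)", stage, exc)
                assoc_rows.append(
                    {"cohort": cid, "variable": variable, "chi2": float("nan"),
                     "df": 0, "p_value": float("nan"), "excluded_missing": 0}
                )
    if assoc_rows:
        emit("association", pd.DataFrame(assoc_rows))
        manifest["stages"].append({"stage": "associate", "tests": len(assoc_rows)})

    # ---- stage: differential expression -------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    for cid, expr in continuous.items():
        stage = f"de[{cid}]"
        try:
            contrast = build_contrast(
                calls_by_cohort[cid], metadata.get(cid), "rich_vs_poor"
            )
            _, table = fit_ebayes(expr, contrast.group_a, contrast.group_b)
            de_tables[cid] = table
            emit(f"de_{cid}", table, index_label="gene")
            manifest["stages"].append(
                {
                    "stage": stage,
                    "n_genes": int(len(table)),
                    "n_fdr05": int((table["fdr"] < 0.05).sum()),
                }
            )
        except ImmunosigError as exc:
            raise ImmunosigError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: consensus ----------------------------------------------
    stage = "consensus"
    try:
        criteria = ConsensusCriteria(
            cfg.fdr_threshold, True, cfg.require_sign_consistency
        )
        lm22 = {c: partition_by_signature(t, signature)[0] for c, t in de_tables.items()}
        non_lm22 = {
            c: partition_by_signature(t, signature)[1] for c, t in de_tables.items()
        }
        cons_lm22 = consensus_filter(lm22, criteria)
        cons_non = consensus_filter(non_lm22, criteria)
        emit("consensus_lm22", cons_lm22, index_label="gene")
        emit("consensus_non_lm22", cons_non, index_label="gene")
        manifest["stages"].append(
            {
                "stage": stage,
                "lm22_consensus": int(len(cons_lm22)),
                "non_lm22_consensus": int(len(cons_non)),
            }
        )
    except ImmunosigError as exc:
        raise ImmunosigError(f"stage {stage!r} failed: {exc}") from exc

    # ---- stage: over-representation ------------------------------------
    if gene_sets is not None:
        for direction in ("up", "down"):
            stage = f"ova[{direction}]"
            try:
                per_cohort: dict[str, pd.DataFrame] = {}
                for cid, table in non_lm22.items():
                    sign = 1 if direction == "up" else -1
                    hits = table.index[
                        (table["fdr"] < cfg.fdr_threshold)
                        & (sign * table["logFC"] > 0)
                    ]
                    per_cohort[cid] = hypergeom_enrich(
                        hits, gene_sets, list(table.index)
                    )
                    emit(f"ova_{direction}_{cid}", per_cohort[cid], index_label="set_name")
                consensus_paths, overlaps = intersect_pathways(
                    per_cohort, cfg.fdr_threshold
                )
                overlap_df = pd.DataFrame(
                    [
                        {"cohorts": "+".join(k), "n_pathways": v}
                        for k, v in sorted(overlaps.items())
                    ]
                )
                emit(
                    f"ova_{direction}_consensus",
                    pd.DataFrame({"set_name": consensus_paths}),
                )
                if len(overlap_df):
                    emit(f"ova_{direction}_overlap", overlap_df)
                manifest["stages"].append(
                    {"stage": stage, "consensus_pathways": len(consensus_paths)}
                )
            except DataValidationError as exc:
                logger.warning("%s: skipped (%s)", stage, exc)
                manifest["stages"].append({"stage": stage, "skipped": str(exc)})

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d outputs in %s", len(manifest["outputs"]), outdir)
    return manifest
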