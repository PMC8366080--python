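"""Shared fixtures: small synthetic studies reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import immunosig as im

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """Three small cohorts (two continuous, one counts) with planted effects."""
    cfg = im.SimulationConfig(
        seed=5,
        cohorts=(
            im.CohortSpec("a", 120, "continuous", 3000, 0.96),
            im.CohortSpec("b", 120, "continuous", 3000, 0.94),
            im.CohortSpec("c", 120, "counts", 3000, 0.98),
        ),
        n_signature_genes=300,
        de_gene_count=60,
        cohort_specific_de_count=9,
        sign_flip_de_count=9,
    )
    return cfg, im.simulate_study(cfg)


@pytest.fixture(scope="session")
def recovery_study():
    """One continuous cohort at the recovery study size (n=200, full signature)."""
    cfg = im.SimulationConfig(
        seed=11, cohorts=(im.CohortSpec("a", 200, "continuous", 4000, 0.95),)
    )
    return cfg, im.simulate_study(cfg)


@pytest.fixture
def tiny_expression():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 6.0, 8.0], [5.0, 5.0, 5.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3"],
    )
    return im.ExpressionDataset("tiny", values, "continuous")


@pytest.fixture
def tiny_signature():
    rng = np.random.default_rng(0)
    profiles = pd.DataFrame(
        rng.gamma(2.0, 1.0, size=(4, 3)),
        index=["g1", "g2", "g4", "g5"],
        columns=["T", "B", "NK"],
    )
    return im.SignatureMatrix(profiles)


def confusion(calls: pd.DataFrame, truth: pd.Series) -> tuple[float, float]:
    """(sensitivity, specificity) of rich calls against a boolean truth."""
    pred = calls.set_index("sample_id")["label"] == "rich"
    pred, truth = pred.align(truth, join="inner")
    tp = (pred & truth).sum()
    fn = (~pred & truth).sum()
    tn = (~pred & ~truth).sum()
    fp = (pred & ~truth).sum()
    return tp / (tp + fn), tn / (tn + fp)
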