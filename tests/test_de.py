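"""TMM factors, log-CPM, BH adjustment, and the moderated-t engine."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import immunosig as im
from immunosig.de import posterior_variances
from immunosig.exceptions import DataValidationError


def _counts(arr, samples=None):
    arr = np.asarray(arr)
    genes = [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return im.ExpressionDataset(
        "c", pd.DataFrame(arr, index=genes, columns=samples), "counts"
    )


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 500, size=300)
        ds = _counts(np.column_stack([col, col]))
        np.testing.assert_allclose(im.tmm_factors(ds).to_numpy(), [1.0, 1.0])

    def test_pure_depth_difference_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 500, size=300)
        ds = _counts(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(im.tmm_factors(ds).to_numpy(), [1.0, 1.0])

    def test_factors_multiply_to_one(self):
        rng = np.random.default_rng(2)
        ds = _counts(rng.integers(0, 800, size=(400, 6)))
        f = im.tmm_factors(ds).to_numpy()
        assert np.prod(f) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_library_errors(self):
        ds = _counts([[0, 5], [0, 3]])
        with pytest.raises(DataValidationError, match="all-zero library"):
            im.tmm_factors(ds)


class TestLogCpm:
    def test_plug_in_value(self):
        # libraries of exactly 1e6 with a zero-count gene
        ds = _counts([[0, 0], [1_000_000, 1_000_000]], samples=["s1", "s2"])
        out = im.log_cpm(ds, pd.Series([1.0, 1.0], index=["s1", "s2"]), prior=0.5)
        expected = math.log2(0.5 / (1_000_000 + 1) * 1e6)
        assert out.values.loc["g0", "s1"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-1.0000014, abs=1e-6)

    def test_monotone_in_count_and_approx_scale_invariant(self):
        lib = 1_000_000
        base = np.array([[10], [100], [1000], [lib - 1110]])
        ds1 = _counts(base, samples=["s1"])
        ds2 = _counts(2 * base, samples=["s1"])
        l1 = im.log_cpm(ds1).values.to_numpy().ravel()
        l2 = im.log_cpm(ds2).values.to_numpy().ravel()
        assert (np.diff(l1) > 0).all()
        # fixed prior: deviation shrinks as counts grow
        assert abs(l1[0] - l2[0]) < 0.05
        assert abs(l1[3] - l2[3]) < 1e-5

    def test_counts_path_composes_with_standardize(self, small_study):
        _, (datasets, _, _, _) = small_study
        counts = next(d for d in datasets if d.value_kind == "counts")
        expr = im.standardize(im.log_cpm(counts, im.tmm_factors(counts)))
        assert expr.value_kind == "continuous"
        assert expr.values.shape == counts.values.shape


class TestBh:
    def test_worked_vectors(self):
        np.testing.assert_allclose(
            im.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(im.bh_adjust([0.001, 0.9]), [0.002, 0.9])
        np.testing.assert_allclose(im.bh_adjust([0.42]), [0.42])

    def test_nan_rejected(self):
        with pytest.raises(DataValidationError, match="NaN"):
            im.bh_adjust([0.1, float("nan")])

    @given(
        st.lists(
            st.floats(1e-12, 1.0, allow_nan=False, exclude_min=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_adjusted_dominates_raw_and_keeps_order(self, ps):
        adj = im.bh_adjust(ps)
        assert ((adj >= np.asarray(ps) - 1e-15) & (adj <= 1.0)).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestEbayes:
    def _two_group(self, rng, n_genes=500, na=20, nb=20, effect=None, sd=1.0):
        Y = rng.normal(0.0, sd, size=(n_genes, na + nb))
        if effect is not None:
            Y[: len(effect), :na] += np.asarray(effect)[:, None]
        genes = [f"g{i}" for i in range(n_genes)]
        samples = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
        expr = pd.DataFrame(Y, index=genes, columns=samples)
        return expr, samples[:na], samples[na:]

    def test_logfc_is_group_mean_difference_and_antisymmetric(self):
        rng = np.random.default_rng(3)
        expr, a, b = self._two_group(rng, n_genes=50)
        _, tab = im.fit_ebayes(expr, a, b)
        manual = expr[a].mean(axis=1) - expr[b].mean(axis=1)
        np.testing.assert_allclose(tab["logFC"], manual.loc[tab.index], atol=1e-12)
        _, tab_swapped = im.fit_ebayes(expr, b, a)
        np.testing.assert_allclose(
            tab["logFC"], -tab_swapped["logFC"].loc[tab.index], atol=1e-12
        )

    def test_equal_variances_collapse_to_common_variance_t(self):
        """Genes sharing one variance: d0 -> inf, t equals pooled-variance t."""
        rng = np.random.default_rng(4)
        base = rng.normal(size=12)
        expr = pd.DataFrame(
            np.stack([base + i for i in range(30)]),  # identical within-group var
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(12)],
        )
        a, b = list(expr.columns[:6]), list(expr.columns[6:])
        fit, tab = im.fit_ebayes(expr, a, b)
        assert math.isinf(fit.d0)
        s2 = fit.s_g_sq.iloc[0]
        expected_t = tab["logFC"] / np.sqrt(s2 * (1 / 6 + 1 / 6))
        np.testing.assert_allclose(tab["t_mod"], expected_t, rtol=1e-9)

    def test_prior_df_limits_recover_ordinary_and_common_t(self):
        rng = np.random.default_rng(5)
        expr, a, b = self._two_group(rng, n_genes=200)
        fit, tab = im.fit_ebayes(expr, a, b)
        logfc = tab["logFC"].to_numpy()
        s2 = fit.s_g_sq.to_numpy()
        u = math.sqrt(1 / 20 + 1 / 20)
        t0, _, df0 = im.moderated_t(logfc, s2, fit.df_resid, u, 1e-12, fit.s0_sq)
        np.testing.assert_allclose(t0, logfc / (np.sqrt(s2) * u), rtol=1e-5)
        tinf, _, dfinf = im.moderated_t(
            logfc, s2, fit.df_resid, u, math.inf, fit.s0_sq
        )
        np.testing.assert_allclose(
            tinf, logfc / (math.sqrt(fit.s0_sq) * u), rtol=1e-9
        )
        assert math.isinf(dfinf)

    def test_posterior_variance_between_prior_and_observed(self):
        s2 = np.array([0.1, 1.0, 10.0])
        post = posterior_variances(s2, df_resid=10, d0=4.0, s0_sq=1.0)
        lo = np.minimum(s2, 1.0)
        hi = np.maximum(s2, 1.0)
        assert ((post >= lo) & (post <= hi)).all()

    def test_single_gene_falls_back_to_infinite_prior(self, caplog):
        rng = np.random.default_rng(6)
        expr, a, b = self._two_group(rng, n_genes=1)
        with caplog.at_level("WARNING"):
            fit, _ = im.fit_ebayes(expr, a, b)
        assert math.isinf(fit.d0)

    def test_power_on_planted_effects(self):
        """2000 genes, 100 planted at logFC 1, n=50/50: >= 90% detected,
        empirical FDR <= 0.10."""
        rng = np.random.default_rng(7)
        expr, a, b = self._two_group(
            rng, n_genes=2000, na=50, nb=50, effect=np.ones(100)
        )
        _, tab = im.fit_ebayes(expr, a, b)
        hits = set(tab.index[tab["fdr"] < 0.05])
        planted = {f"g{i}" for i in range(100)}
        assert len(hits & planted) / 100 >= 0.90
        false = len(hits - planted)
        assert false / max(len(hits), 1) <= 0.10

    def test_covariate_adjustment_drops_missing_listwise(self, caplog):
        rng = np.random.default_rng(8)
        expr, a, b = self._two_group(rng, n_genes=40, na=6, nb=6)
        cov = pd.DataFrame(
            {"subtype": ["Luminal"] * 5 + ["missing"] + ["TNBC"] * 6},
            index=a + b,
        )
        with caplog.at_level("WARNING"):
            fit, tab = im.fit_ebayes(expr, a, b, covariates=cov)
        assert "missing covariate" in caplog.text
        assert len(tab) == 40

    def test_groups_too_small_error(self):
        rng = np.random.default_rng(9)
        expr, a, b = self._two_group(rng, n_genes=10, na=2, nb=2)
        with pytest.raises(DataValidationError, match=">= 2"):
            im.fit_ebayes(expr, a[:1], b)

    def test_estimator_wrapper(self):
        rng = np.random.default_rng(10)
        expr, a, b = self._two_group(rng, n_genes=30)
        groups = pd.Series({**{s: "a" for s in a}, **{s: "b" for s in b}})
        est = im.EmpiricalBayesDE().fit(expr, groups)
        assert est.prior_df_ > 0
        assert {"logFC", "fdr"}.issubset(est.transform().columns)


class TestContrasts:
    def test_build_rich_vs_poor_and_subtype_contrasts(self, small_study):
        _, (datasets, metadata, _, truth) = small_study
        cid = datasets[0].cohort_id
        sub = truth.samples[truth.samples["cohort_id"] == cid]
        calls = pd.DataFrame(
            {"sample_id": sub["sample_id"],
             "label": np.where(sub["true_rich"], "rich", "poor")}
        )
        meta = metadata[cid]
        ct = im.build_contrast(calls, meta, "rich_vs_poor")
        assert set(ct.group_a).isdisjoint(ct.group_b)
        ct2 = im.build_contrast(calls, meta, "subtype_vs_rest", "TNBC")
        assert all(meta.loc[s, "subtype"] == "TNBC" for s in ct2.group_a)
        assert all(meta.loc[s, "subtype"] not in ("TNBC", "missing")
                   for s in ct2.group_b)
        ct3 = im.build_contrast(calls, meta, "rich_only_subtype", "TNBC")
        rich = set(calls.loc[calls["label"] == "rich", "sample_id"])
        assert set(ct3.group_a) | set(ct3.group_b) <= rich
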