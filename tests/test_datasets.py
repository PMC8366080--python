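"""Container invariants, TSV/GMT round-trips, standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import immunosig as im
from immunosig.exceptions import DataValidationError, ParseError


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadExpression:
    def test_round_trip_identity(self, tmp_path, tiny_expression):
        p = tmp_path / "expr.tsv"
        im.write_expression(tiny_expression, p)
        back = im.read_expression(p, "continuous", "tiny")
        pd.testing.assert_frame_equal(
            back.values, tiny_expression.values, check_names=False
        )

    def test_duplicate_symbol_keeps_highest_mean_row(self, tmp_path, caplog):
        p = _write(
            tmp_path,
            "dup.tsv",
            "gene\ts1\ts2\nACTB\t1\t1\nGAPDH\t5\t5\nACTB\t9\t9\n",
        )
        with caplog.at_level("WARNING"):
            ds = im.read_expression(p, "continuous")
        assert ds.gene_ids == ["GAPDH", "ACTB"]
        assert ds.values.loc["ACTB", "s1"] == 9
        assert "ACTB" in caplog.text

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = _write(tmp_path, "bad.tsv", "gene\ts1\ts2\ng1\t1\tx\n")
        with pytest.raises(ParseError, match="g1.*s2"):
            im.read_expression(p, "continuous")

    def test_fractional_counts_rejected(self, tmp_path):
        p = _write(tmp_path, "cnt.tsv", "gene\ts1\ts2\ng1\t1\t2.5\n")
        with pytest.raises(DataValidationError, match="non-integer"):
            im.read_expression(p, "counts")

    def test_negative_counts_rejected(self):
        df = pd.DataFrame([[1, -2]], index=["g1"], columns=["s1", "s2"])
        with pytest.raises(DataValidationError, match="negative"):
            im.ExpressionDataset("x", df, "counts")

    def test_duplicate_sample_ids_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["s1", "s1"])
        with pytest.raises(DataValidationError, match="sample"):
            im.ExpressionDataset("x", df, "continuous")


class TestStandardize:
    def test_row_z_scores_with_sample_sd(self, tiny_expression):
        z = im.standardize(tiny_expression)
        np.testing.assert_allclose(z.values.loc["g1"], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(z.values.loc["g2"], [-1.0, 0.0, 1.0])

    def test_constant_row_maps_to_zeros_with_warning(self, tiny_expression, caplog):
        with caplog.at_level("WARNING"):
            z = im.standardize(tiny_expression)
        np.testing.assert_array_equal(z.values.loc["g3"], [0.0, 0.0, 0.0])
        assert "zero-variance" in caplog.text

    def test_single_sample_errors(self):
        ds = im.ExpressionDataset(
            "x", pd.DataFrame([[1.0]], index=["g"], columns=["s"]), "continuous"
        )
        with pytest.raises(DataValidationError, match="single-sample"):
            im.standardize(ds)

    def test_counts_must_go_through_log_cpm_first(self):
        ds = im.ExpressionDataset(
            "x",
            pd.DataFrame([[1, 2], [3, 4]], index=["g1", "g2"], columns=["s1", "s2"]),
            "counts",
        )
        with pytest.raises(DataValidationError, match="log_cpm"):
            im.standardize(ds)

    @given(
        arr=hnp.arrays(
            float,
            shape=st.tuples(st.integers(2, 8), st.integers(3, 9)),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        )
    )
    def test_idempotent_and_unit_moments(self, arr):
        df = pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        )
        z1 = im.standardize(im.ExpressionDataset("x", df, "continuous"))
        z2 = im.standardize(z1)
        np.testing.assert_allclose(
            z1.values.to_numpy(), z2.values.to_numpy(), atol=1e-10
        )
        nonconst = z1.values.std(axis=1, ddof=1) > 0
        np.testing.assert_allclose(
            z1.values[nonconst].mean(axis=1), 0.0, atol=1e-10
        )
        np.testing.assert_allclose(
            z1.values[nonconst].std(axis=1, ddof=1), 1.0, atol=1e-10
        )


class TestIntersectSignature:
    def test_counts_and_signature_order(self, tiny_expression, tiny_signature):
        retained, report = im.intersect_signature(tiny_expression, tiny_signature)
        assert retained == ["g1", "g2"]  # signature order preserved
        assert report == {"present": 2, "absent": 2}

    def test_full_overlap(self, tiny_signature):
        df = pd.DataFrame(
            np.ones((4, 3)), index=["g1", "g2", "g4", "g5"],
            columns=["s1", "s2", "s3"],
        )
        retained, report = im.intersect_signature(
            im.ExpressionDataset("x", df, "continuous"), tiny_signature
        )
        assert report["present"] == tiny_signature.n_genes
        assert retained == tiny_signature.gene_ids

    def test_disjoint_universe_errors(self, tiny_signature):
        df = pd.DataFrame(np.ones((2, 3)), index=["zz1", "zz2"],
                          columns=["s1", "s2", "s3"])
        with pytest.raises(DataValidationError, match="no genes"):
            im.intersect_signature(
                im.ExpressionDataset("x", df, "continuous"), tiny_signature
            )

    def test_synthetic_cross_platform_intersection_counts(self):
        """A 547-gene signature against a cohort carrying 515 of them."""
        sig_genes = [f"IMM{i:04d}" for i in range(547)]
        sig = im.signature_from_genes(sig_genes, 4, seed=0)
        cohort_genes = sig_genes[:515] + [f"G{i}" for i in range(100)]
        df = pd.DataFrame(
            np.zeros((len(cohort_genes), 3)),
            index=cohort_genes, columns=["s1", "s2", "s3"],
        )
        _, report = im.intersect_signature(
            im.ExpressionDataset("x", df, "continuous"), sig
        )
        assert report == {"present": 515, "absent": 32}


class TestGmt:
    def test_round_trip(self, tmp_path):
        coll = im.GeneSetCollection(
            [
                im.GeneSet("PATH_A", "desc a", ("g1", "g2", "g3")),
                im.GeneSet("PATH_B", "desc b", ("g4",)),
            ]
        )
        p = tmp_path / "sets.gmt"
        im.write_gmt(coll, p)
        back = im.read_gmt(p)
        assert back.as_dict() == coll.as_dict()

    def test_short_line_errors_with_line_number(self, tmp_path):
        p = _write(tmp_path, "bad.gmt", "PATH_A\tdesc\tg1\nPATH_B\tdesc\n")
        with pytest.raises(ParseError, match=":2"):
            im.read_gmt(p)

    def test_duplicate_name_errors(self, tmp_path):
        p = _write(tmp_path, "dup.gmt", "P\td\tg1\nP\td\tg2\n")
        with pytest.raises(ParseError, match="duplicate"):
            im.read_gmt(p)

    def test_empty_gene_list_errors(self, tmp_path):
        p = _write(tmp_path, "empty.gmt", "P\td\t\n")
        with pytest.raises(ParseError):
            im.read_gmt(p)


class TestMetadataAndSignatureIO:
    def test_metadata_round_trip_and_levels(self, tmp_path):
        meta = pd.DataFrame(
            {"subtype": ["Luminal", "TNBC", "missing"],
             "nodal": ["positive", "negative", "missing"]},
            index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        )
        p = tmp_path / "meta.tsv"
        im.write_metadata(meta, p)
        back = im.read_metadata(p)
        pd.testing.assert_frame_equal(back, meta)

    def test_invalid_subtype_rejected(self, tmp_path):
        p = _write(tmp_path, "meta.tsv",
                   "sample_id\tsubtype\tnodal\ns1\tBasal\tpositive\n")
        with pytest.raises(DataValidationError, match="subtype"):
            im.read_metadata(p)

    def test_signature_round_trip_and_negativity_check(self, tmp_path, tiny_signature):
        p = tmp_path / "sig.tsv"
        im.write_signature(tiny_signature, p)
        back = im.read_signature(p)
        pd.testing.assert_frame_equal(
            back.profiles, tiny_signature.profiles, check_names=False
        )
        with pytest.raises(DataValidationError, match="non-negative"):
            im.SignatureMatrix(tiny_signature.profiles - 100)
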