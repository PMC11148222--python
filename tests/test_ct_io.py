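"""Ct-table parsing, replicate collapsing and ΔCt quantification."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glupanel as g
from glupanel.ct import CtFormatError, CtIntegrityError, CtTable


def _write_csv(tmp_path, text, name="ct.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadCtTable:
    def test_preserves_all_replicate_rows(self, tmp_path):
        path = _write_csv(
            tmp_path,
            "sample_id,gene,replicate,ct\n"
            "s1,GRIA2,1,25.0\ns1,GRIA2,2,25.4\ns1,TBP,1,22.0\ns1,TBP,2,22.2\n",
        )
        table = g.read_ct_table(path)
        assert len(table.measurements) == 4
        assert table.housekeeping_gene == "TBP"

    def test_undetermined_becomes_missing_with_warning(self, tmp_path, caplog):
        path = _write_csv(
            tmp_path,
            "sample_id,gene,replicate,ct\ns1,GRIA2,1,Undetermined\ns1,TBP,1,22.0\n",
        )
        with caplog.at_level(logging.WARNING):
            table = g.read_ct_table(path)
        assert np.isnan(table.measurements["ct"].iloc[0])
        assert any("missing" in rec.message for rec in caplog.records)

    def test_ct_beyond_detection_limit_is_missing(self, tmp_path):
        path = _write_csv(
            tmp_path,
            "sample_id,gene,replicate,ct\ns1,GRIA2,1,41.2\ns1,TBP,1,22.0\n",
        )
        table = g.read_ct_table(path)
        assert np.isnan(table.measurements["ct"].iloc[0])

    def test_missing_column_is_format_error(self, tmp_path):
        path = _write_csv(tmp_path, "sample_id,gene,ct\ns1,GRIA2,25.0\n")
        with pytest.raises(CtFormatError):
            g.read_ct_table(path)

    def test_duplicate_measurement_is_integrity_error(self, tmp_path):
        path = _write_csv(
            tmp_path,
            "sample_id,gene,replicate,ct\ns1,GRIA2,1,25.0\ns1,GRIA2,1,25.4\n",
        )
        with pytest.raises(CtIntegrityError):
            g.read_ct_table(path)

    def test_round_trip_preserves_values(self, tmp_path, tiny_ct_frame):
        table = CtTable(tiny_ct_frame)
        out = tmp_path / "rt.csv"
        g.write_ct_table(table, out)
        back = g.read_ct_table(out)
        pd.testing.assert_frame_equal(
            back.measurements.reset_index(drop=True),
            table.measurements.reset_index(drop=True),
            check_dtype=False,
        )


class TestCollapseReplicates:
    @pytest.mark.parametrize(
        "reps, expected",
        [
            ([20.0, 21.0], 20.5),
            ([20.0, np.nan], 20.0),
            ([np.nan, np.nan], np.nan),
        ],
    )
    def test_mean_of_present_replicates(self, reps, expected):
        df = pd.DataFrame(
            {
                "sample_id": ["s1", "s1", "s1"],
                "gene": ["GRIA2", "GRIA2", "TBP"],
                "replicate": [1, 2, 1],
                "ct": reps + [22.0],
            }
        )
        out = g.collapse_replicates(CtTable(df)).measurements
        value = out.loc[out["gene"] == "GRIA2", "ct"].iloc[0]
        if np.isnan(expected):
            assert np.isnan(value)
        else:
            assert value == pytest.approx(expected)


class TestComputeDeltaCt:
    @pytest.mark.parametrize(
        "ct_target, ct_hk, expected",
        [(25.0, 22.0, 3.0), (22.0, 22.0, 0.0), (np.nan, 22.0, np.nan)],
    )
    def test_subtraction_and_missing_propagation(self, ct_target, ct_hk, expected):
        df = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "gene": ["GRIA2", "TBP"],
                "replicate": [1, 1],
                "ct": [ct_target, ct_hk],
            }
        )
        matrix = g.compute_delta_ct(CtTable(df))
        value = matrix.delta_ct.at["GRIA2", "s1"]
        if np.isnan(expected):
            assert np.isnan(value)
        else:
            assert value == pytest.approx(expected)

    def test_sample_without_housekeeping_is_all_missing(self, caplog):
        df = pd.DataFrame(
            {
                "sample_id": ["s1", "s1", "s2"],
                "gene": ["GRIA2", "TBP", "GRIA2"],
                "replicate": [1, 1, 1],
                "ct": [25.0, 22.0, 26.0],
            }
        )
        with caplog.at_level(logging.WARNING):
            matrix = g.compute_delta_ct(CtTable(df))
        assert np.isnan(matrix.delta_ct.at["GRIA2", "s2"])
        assert matrix.delta_ct.at["GRIA2", "s1"] == pytest.approx(3.0)

    def test_housekeeping_gene_excluded_from_targets(self, tiny_ct_frame):
        matrix = g.compute_delta_ct(CtTable(tiny_ct_frame))
        assert "TBP" not in matrix.genes

    def test_collapse_then_delta_matches_precollapsed(self, tiny_ct_frame):
        """Collapsing is idempotent: ΔCt from raw equals ΔCt from collapsed."""
        table = CtTable(tiny_ct_frame)
        direct = g.compute_delta_ct(table)
        pre = g.compute_delta_ct(g.collapse_replicates(table))
        pd.testing.assert_frame_equal(direct.delta_ct, pre.delta_ct)

    @given(shift=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_constant_ct_shift(self, shift):
        """Adding a constant to every Ct of a sample leaves ΔCt unchanged."""
        df = pd.DataFrame(
            {
                "sample_id": ["s1"] * 3,
                "gene": ["GRIA2", "GRIK1", "TBP"],
                "replicate": [1, 1, 1],
                "ct": [25.0, 27.5, 22.0],
            }
        )
        base = g.compute_delta_ct(CtTable(df))
        shifted_df = df.assign(ct=df["ct"] + shift)
        shifted = g.compute_delta_ct(CtTable(shifted_df))
        np.testing.assert_allclose(
            shifted.delta_ct.to_numpy(), base.delta_ct.to_numpy(), atol=1e-9
        )


class TestRelativeExpression:
    @pytest.mark.parametrize(
        "delta, expected",
        [(0.0, 1000.0), (1.0, 500.0), (2.81, 142.595464)],
    )
    def test_reference_values(self, delta, expected):
        assert g.relative_expression(delta) == pytest.approx(expected, abs=1e-4)

    @given(delta=st.floats(-20, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_halves_per_extra_cycle(self, delta):
        assert g.relative_expression(delta + 1.0) * 2.0 == pytest.approx(
            g.relative_expression(delta), rel=1e-12
        )
        assert g.relative_expression(delta) > 0

    def test_missing_propagates(self):
        assert np.isnan(g.relative_expression(np.nan))


def test_expression_matrix_tsv_round_trip(tmp_path, default_matrix):
    matrix, _ = default_matrix
    delta_path = tmp_path / "expression.tsv"
    rel_path = tmp_path / "relative.tsv"
    g.write_expression_matrix(matrix, delta_path, rel_path)
    back = pd.read_csv(delta_path, sep="\t", index_col=0)
    np.testing.assert_allclose(
        back.to_numpy(), matrix.delta_ct.to_numpy(), atol=1e-9, equal_nan=True
    )
    rel = pd.read_csv(rel_path, sep="\t", index_col=0)
    assert (rel.stack() > 0).all()
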