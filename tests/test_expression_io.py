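import logging

import numpy as np
import pytest

from tsnet.expression_io import (
    ExpressionMatrix,
    GeneList,
    SampleTable,
    collapse_probes,
    read_expression_matrix,
    read_gene_list,
    read_sample_table,
    subset_stage,
    write_expression_matrix,
    write_gene_list,
    write_sample_table,
    zscore_rows,
)
from helpers import random_expression


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


class TestReadExpressionMatrix:
    def test_identity_round_trip_fixture(self, tmp_path):
        write_lines(
            tmp_path / "m.tsv",
            [
                "probe_id\ts1\ts2\ts3\ts4",
                "P1\t1\t2\t3\t4",
                "P2\t4\t3\t2\t1",
                "P3\t5\t5\t6\t6",
            ],
        )
        m = read_expression_matrix(tmp_path / "m.tsv")
        assert m.shape == (3, 4)
        assert m.probe_ids == ["P1", "P2", "P3"]
        assert m.sample_ids == ["s1", "s2", "s3", "s4"]
        np.testing.assert_array_equal(m.values[0], [1, 2, 3, 4])

    def test_duplicate_probe_id_names_offender(self, tmp_path):
        write_lines(
            tmp_path / "m.tsv",
            ["probe_id\ts1\ts2", "P1\t1\t2", "P1\t3\t4"],
        )
        with pytest.raises(ValueError, match="P1"):
            read_expression_matrix(tmp_path / "m.tsv")

    def test_ragged_row_reports_line_number(self, tmp_path):
        write_lines(
            tmp_path / "m.tsv",
            ["probe_id\ts1\ts2", "P1\t1\t2", "P2\t3"],
        )
        with pytest.raises(ValueError, match="line 3"):
            read_expression_matrix(tmp_path / "m.tsv")

    def test_empty_body_is_error(self, tmp_path):
        write_lines(tmp_path / "m.tsv", ["probe_id\ts1\ts2"])
        with pytest.raises(ValueError, match="empty"):
            read_expression_matrix(tmp_path / "m.tsv")

    def test_missing_value_default_error(self, tmp_path):
        write_lines(tmp_path / "m.tsv", ["probe_id\ts1\ts2", "P1\t1\tNA", "P2\t3\t4"])
        with pytest.raises(ValueError, match="P1"):
            read_expression_matrix(tmp_path / "m.tsv")

    def test_missing_value_drop_policy(self, tmp_path):
        write_lines(tmp_path / "m.tsv", ["probe_id\ts1\ts2", "P1\t1\tNA", "P2\t3\t4"])
        m = read_expression_matrix(tmp_path / "m.tsv", missing="drop")
        assert m.probe_ids == ["P2"]

    def test_linear_scale_applies_log2(self, tmp_path):
        write_lines(tmp_path / "m.tsv", ["probe_id\ts1\ts2", "P1\t0\t3"])
        m = read_expression_matrix(tmp_path / "m.tsv", linear_scale=True)
        np.testing.assert_allclose(m.values[0], [0.0, 2.0])

    def test_round_trip_random_matrices(self, tmp_path, rng):
        # full-precision write/read must be value-identical
        for i in range(100):
            m = random_expression(rng, int(rng.integers(1, 8)), int(rng.integers(1, 6)))
            path = tmp_path / f"m{i}.tsv"
            write_expression_matrix(m, path)
            back = read_expression_matrix(path)
            assert back.probe_ids == m.probe_ids
            assert back.sample_ids == m.sample_ids
            np.testing.assert_array_equal(back.values, m.values)


class TestInvariants:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(["P1"], ["s1", "s2"], np.zeros((1, 3)))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(["P1"], ["s1"], np.array([[np.nan]]))

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="sample id"):
            ExpressionMatrix(["P1"], ["s1", "s1"], np.zeros((1, 2)))


class TestSampleTable:
    def test_fixture_parses(self, tmp_path):
        write_lines(
            tmp_path / "t.tsv",
            [
                "sample_id\tcondition\tstage\tsubject_id\tsmoking",
                "s1\tnormal\tNA\tpA\tno",
                "s2\tnormal\tNA\tpB\tNA",
                "s3\ttumor\t2\tpA\tno",
                "s4\ttumor\t2\tpB\tNA",
            ],
        )
        t = read_sample_table(tmp_path / "t.tsv")
        assert len(t) == 4
        assert t.ids_where(condition="tumor") == ["s3", "s4"]
        assert t.stage == ["unknown", "unknown", "2", "2"]

    def test_strict_condition_vocabulary(self, tmp_path):
        write_lines(
            tmp_path / "t.tsv",
            [
                "sample_id\tcondition\tstage\tsubject_id\tsmoking",
                "s1\tTumour\t2\tpA\tno",
            ],
        )
        with pytest.raises(ValueError, match="condition"):
            read_sample_table(tmp_path / "t.tsv")

    def test_duplicate_sample_id(self, tmp_path):
        write_lines(
            tmp_path / "t.tsv",
            [
                "sample_id\tcondition\tstage\tsubject_id\tsmoking",
                "s1\tnormal\tNA\tpA\tno",
                "s1\ttumor\t2\tpA\tno",
            ],
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_sample_table(tmp_path / "t.tsv")

    def test_round_trip(self, tmp_path, small_samples):
        write_sample_table(small_samples, tmp_path / "t.tsv")
        back = read_sample_table(tmp_path / "t.tsv")
        assert back == small_samples


class TestGeneList:
    def test_round_trip_with_comments(self, tmp_path):
        (tmp_path / "g.txt").write_text("# candidates\nTP53\nRB1  # classic\n\nPTEN\n")
        g = read_gene_list(tmp_path / "g.txt", name="list1")
        assert g.members == {"TP53", "RB1", "PTEN"}
        write_gene_list(g, tmp_path / "out.txt")
        assert read_gene_list(tmp_path / "out.txt").members == g.members

    def test_empty_list_is_error(self, tmp_path):
        (tmp_path / "g.txt").write_text("# nothing here\n")
        with pytest.raises(ValueError, match="empty"):
            read_gene_list(tmp_path / "g.txt")


class TestSubsetStage:
    @pytest.fixture
    def mixed(self, rng):
        m = random_expression(rng, 4, 6)
        t = SampleTable(
            sample_ids=m.sample_ids,
            condition=["normal", "tumor", "tumor", "normal", "tumor", "tumor"],
            stage=["unknown", "1", "2", "unknown", "2", "3"],
            subject_id=[f"p{i}" for i in range(6)],
            smoking=["unknown"] * 6,
        )
        return m, t

    def test_stage_filter_keeps_normals(self, mixed):
        m, t = mixed
        sub, subt = subset_stage(m, t, 2, include_normals=True)
        assert sub.sample_ids == ["s0", "s2", "s3", "s4"]  # matrix order preserved
        assert subt.condition == ["normal", "tumor", "normal", "tumor"]

    def test_without_normals(self, mixed):
        m, t = mixed
        sub, _ = subset_stage(m, t, 2, include_normals=False)
        assert sub.sample_ids == ["s2", "s4"]

    def test_missing_stage_errors(self, mixed):
        m, t = mixed
        with pytest.raises(ValueError, match="stage 4"):
            subset_stage(m, t, 4)

    def test_column_counts_on_random_fixtures(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 20))
            m = random_expression(rng, 3, n)
            condition = [str(c) for c in rng.choice(["normal", "tumor"], size=n)]
            stage = [
                "unknown" if c == "normal" else str(rng.choice(["1", "2", "3"]))
                for c in condition
            ]
            t = SampleTable(m.sample_ids, condition, stage, [f"p{i}" for i in range(n)], ["unknown"] * n)
            n_normal = condition.count("normal")
            n_stage2 = sum(1 for c, s in zip(condition, stage) if c == "tumor" and s == "2")
            if n_stage2 == 0:
                with pytest.raises(ValueError):
                    subset_stage(m, t, 2)
            else:
                sub, _ = subset_stage(m, t, 2)
                assert len(sub.sample_ids) == n_normal + n_stage2


class TestZscoreRows:
    def test_hand_example(self):
        m = ExpressionMatrix(["P1"], ["a", "b", "c"], np.array([[1.0, 2.0, 3.0]]))
        z = zscore_rows(m)
        np.testing.assert_allclose(z.values[0], [-1.0, 0.0, 1.0])

    def test_constant_row_zeroed_with_warning(self, caplog):
        m = ExpressionMatrix(["P1"], list("abcd"), np.array([[5.0, 5.0, 5.0, 5.0]]))
        with caplog.at_level(logging.WARNING, logger="tsnet.expression_io"):
            z = zscore_rows(m)
        np.testing.assert_array_equal(z.values[0], [0, 0, 0, 0])
        assert "constant" in caplog.text

    def test_single_column_errors(self):
        m = ExpressionMatrix(["P1"], ["a"], np.array([[1.0]]))
        with pytest.raises(ValueError):
            zscore_rows(m)

    def test_rows_centered_and_idempotent(self, rng):
        for _ in range(20):
            m = random_expression(rng, int(rng.integers(2, 10)), int(rng.integers(3, 12)))
            z = zscore_rows(m)
            assert np.all(np.abs(z.values.mean(axis=1)) < 1e-12)
            np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-12)
            zz = zscore_rows(z)
            np.testing.assert_allclose(zz.values, z.values, atol=1e-12)


class TestCollapseProbes:
    def test_max_variance_representative(self):
        m = ExpressionMatrix(
            ["P1", "P2"],
            list("abcd"),
            np.array([[0.0, 2.0, 0.0, 2.0], [0.0, 1.0, 0.0, 1.0]]),
        )
        out = collapse_probes(m, {"P1": "G", "P2": "G"})
        assert out.probe_ids == ["G"]
        np.testing.assert_array_equal(out.values[0], m.values[0])  # higher variance wins

    def test_single_probe_gene_identity(self, small_matrix):
        out = collapse_probes(small_matrix, {"P2": "G2"})
        assert out.probe_ids == ["G2"]
        np.testing.assert_array_equal(out.values[0], small_matrix.values[1])

    def test_empty_intersection(self, small_matrix):
        with pytest.raises(ValueError):
            collapse_probes(small_matrix, {"PX": "G"})

    def test_gene_count_equals_distinct_mapped(self, rng):
        for _ in range(20):
            m = random_expression(rng, int(rng.integers(3, 15)), 5)
            mapping = {
                p: f"G{int(rng.integers(0, 5))}"
                for p in m.probe_ids
                if rng.random() < 0.8
            }
            if not mapping:
                continue
            out = collapse_probes(m, mapping)
            assert set(out.probe_ids) == set(mapping.values())
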