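import numpy as np
import pytest

from micelle_qspr.data_io import (
    DescriptorTable,
    TableError,
    ln_transform_response,
    prereduce,
    read_descriptor_table,
    standardize,
    apply_standardization,
    invert_standardization,
    write_descriptor_table,
)

from conftest import make_table


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path, rng):
        table = make_table(rng.standard_normal((3, 4)), response=[1.0, 2.0, 3.0])
        path = tmp_path / "t.csv"
        write_descriptor_table(table, path)
        back = read_descriptor_table(path, "LC")
        assert back.sample_ids == table.sample_ids
        assert back.descriptor_names == table.descriptor_names
        np.testing.assert_allclose(back.values, table.values)
        np.testing.assert_allclose(back.response, table.response)

    def test_response_column_split_off(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "sample_id,a,b,c,d,LC\nS1,1,2,3,4,10\nS2,2,3,4,5,11\nS3,0,1,2,3,12\n"
        )
        table = read_descriptor_table(path, "LC")
        assert table.n_samples == 3
        assert table.n_descriptors == 4
        assert "LC" not in table.descriptor_names
        assert table.response.shape == (3,)

    def test_duplicate_sample_id_named_in_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample_id,a,LC\nS1,1,10\nS1,2,11\nS3,1,9\n")
        with pytest.raises(TableError, match="S1"):
            read_descriptor_table(path, "LC")

    def test_non_numeric_cell_named_in_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample_id,a,LC\nS1,1,10\nS2,oops,11\n")
        with pytest.raises(TableError, match="S2.*'a'"):
            read_descriptor_table(path, "LC")

    def test_missing_response_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sample_id,a\nS1,1\nS2,2\n")
        with pytest.raises(TableError, match="LC"):
            read_descriptor_table(path, "LC")


class TestInvariants:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(TableError):
            DescriptorTable(("S1",), ("a", "b"), np.ones((1, 3)))

    def test_nan_rejected_with_location(self):
        with pytest.raises(TableError, match="S2.*'b'"):
            make_table([[1.0, 2.0], [3.0, np.nan]], names=["a", "b"])


class TestLnTransform:
    def test_known_values(self):
        # LC 14.5 -> ln(LC) ~ 2.674; LC 1 -> 0
        table = make_table(np.zeros((2, 1)), response=[14.5, 1.0])
        out = ln_transform_response(table)
        np.testing.assert_allclose(out.response, [np.log(14.5), 0.0])
        assert abs(out.response[0] - 2.674) < 5e-4
        assert out.response_scale == "ln"

    def test_non_positive_response_names_sample(self):
        table = make_table(np.zeros((2, 1)), response=[5.0, 0.0])
        with pytest.raises(TableError, match="S2"):
            ln_transform_response(table)

    def test_double_transform_rejected(self):
        table = make_table(np.zeros((2, 1)), response=[5.0, 6.0])
        with pytest.raises(TableError):
            ln_transform_response(ln_transform_response(table))


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        table = make_table(rng.standard_normal((20, 5)) * 7 + 3)
        out, params = standardize(table)
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1, rtol=1e-12)

    def test_inversion_recovers_input(self, rng):
        table = make_table(rng.standard_normal((15, 3)) * 100 + 50)
        out, params = standardize(table)
        back = invert_standardization(out, params)
        np.testing.assert_allclose(back.values, table.values, rtol=1e-10)

    def test_idempotent_on_z_scores(self, rng):
        table = make_table(rng.standard_normal((30, 2)))
        once, _ = standardize(table)
        twice, _ = standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_applies_to_new_samples(self, rng):
        train = make_table(rng.standard_normal((10, 2)) * 4 + 1)
        _, params = standardize(train)
        new = make_table(rng.standard_normal((5, 2)), names=None)
        out = apply_standardization(new, params)
        expected = (new.values - params.means) / params.sds
        np.testing.assert_allclose(out.values, expected)

    def test_constant_column_rejected(self):
        table = make_table([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(TableError, match="x1"):
            standardize(table)


class TestPrereduce:
    def test_constant_column_removed(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 4.2
        table = make_table(X, names=["a", "const", "c"])
        out, log = prereduce(table)
        assert log.removed_constant == ["const"]
        assert "const" not in out.descriptor_names

    def test_identical_pair_one_removed_and_logged(self, rng):
        x = rng.standard_normal(25)
        X = np.column_stack([x, x, rng.standard_normal(25)])
        table = make_table(X, names=["a", "a_copy", "b"])
        out, log = prereduce(table)
        assert out.n_descriptors == 2
        assert len(log.removed_correlated) == 1
        kept, removed, corr = log.removed_correlated[0]
        assert {kept, removed} == {"a", "a_copy"}
        assert abs(corr) > 0.99

    def test_pair_below_threshold_kept(self, rng):
        x = rng.standard_normal(500)
        # construct a pair with r ~ 0.98 < 0.99
        y = 0.98 * x + np.sqrt(1 - 0.98**2) * rng.standard_normal(500)
        table = make_table(np.column_stack([x, y]), names=["a", "b"])
        out, log = prereduce(table)
        assert out.n_descriptors == 2
        assert log.removed_correlated == []

    def test_idempotent(self, rng):
        X = rng.standard_normal((30, 6))
        X[:, 3] = X[:, 0] + 1e-6 * rng.standard_normal(30)
        X[:, 5] = 1.0
        out1, _ = prereduce(make_table(X))
        out2, log2 = prereduce(out1)
        assert out2.descriptor_names == out1.descriptor_names
        assert not (log2.removed_constant or log2.removed_near_constant
                    or log2.removed_correlated)

    def test_max_correlation_bounded_after(self, rng):
        base = rng.standard_normal((40, 4))
        extra = base[:, :3] + 0.005 * rng.standard_normal((40, 3))
        table = make_table(np.column_stack([base, extra]))
        out, _ = prereduce(table, corr_threshold=0.99)
        corr = np.corrcoef(out.values, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() <= 0.99

    def test_all_removed_is_error(self):
        table = make_table(np.ones((5, 2)))
        with pytest.raises(TableError):
            prereduce(table)
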