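"""Expression/gold-network I/O, normalization, and window construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aesgrn
from aesgrn.datasets import denormalize, ordered_pairs
from aesgrn.errors import ConsistencyError, DataError, FormatError


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadExpression:
    def test_single_file_with_time_column(self, tmp_path):
        p = write(
            tmp_path,
            "a.tsv",
            "Time\tG1\tG2\n" + "\n".join(f"{t}\t0.{t}\t0.{9 - t}" for t in range(5)),
        )
        ds = aesgrn.read_expression(p)
        assert ds.gene_names == ["G1", "G2"]
        assert ds.n_experiments == 1 and ds.n_observations == 5

    def test_blank_line_separated_experiments(self, tmp_path):
        block = "G1\tG2\n" + "\n".join(f"0.{t % 10}\t0.{(t + 1) % 10}" for t in range(21))
        p = write(tmp_path, "b.tsv", block + "\n\n" + block)
        ds = aesgrn.read_expression(p)
        assert ds.n_experiments == 2
        assert ds.n_observations == 21

    def test_second_block_without_repeated_header(self, tmp_path):
        p = write(tmp_path, "c.tsv", "G1\tG2\n0.1\t0.2\n0.3\t0.4\n\n0.5\t0.6\n0.7\t0.8")
        ds = aesgrn.read_expression(p)
        assert ds.n_experiments == 2
        np.testing.assert_allclose(ds.experiments[1][0], [0.5, 0.6])

    def test_ragged_rows_rejected(self, tmp_path):
        p = write(tmp_path, "d.tsv", "G1\tG2\n0.1\t0.2\n0.3\t0.4\t0.5")
        with pytest.raises(FormatError):
            aesgrn.read_expression(p)

    def test_mismatched_headers_across_files(self, tmp_path):
        p1 = write(tmp_path, "e1.tsv", "G1\tG2\n0.1\t0.2")
        p2 = write(tmp_path, "e2.tsv", "G1\tG3\n0.1\t0.2")
        with pytest.raises(ConsistencyError):
            aesgrn.read_expression([p1, p2])

    def test_non_monotonic_time_rejected(self, tmp_path):
        p = write(tmp_path, "f.tsv", "Time\tG1\n0\t0.1\n2\t0.2\n1\t0.3")
        with pytest.raises(FormatError):
            aesgrn.read_expression(p)

    def test_roundtrip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        ds = aesgrn.ExpressionDataset(["G1", "G2", "G3"], [rng.random((7, 3)) for _ in range(2)])
        path = tmp_path / "rt.tsv"
        aesgrn.write_expression(ds, path)
        back = aesgrn.read_expression(path)
        for a, b in zip(ds.experiments, back.experiments):
            assert np.array_equal(a, b)


class TestNormalize:
    def test_min_max_formula(self):
        ds = aesgrn.ExpressionDataset(["G1"], [np.array([[2.0], [4.0], [6.0]])])
        nds = aesgrn.min_max_normalize(ds)
        np.testing.assert_allclose(nds.experiments[0][:, 0], [0.0, 0.5, 1.0])

    def test_constant_gene_maps_to_zero_with_warning(self):
        ds = aesgrn.ExpressionDataset(["G1"], [np.array([[3.0], [3.0], [3.0]])])
        with pytest.warns(UserWarning, match="constant"):
            nds = aesgrn.min_max_normalize(ds)
        assert np.all(nds.experiments[0] == 0.0)

    def test_training_constants_applied_to_evaluation(self):
        ds = aesgrn.ExpressionDataset(
            ["G1"], [np.array([[0.0], [10.0]]), np.array([[12.0]])]
        )
        nds = aesgrn.min_max_normalize(ds, training_experiments=[0])
        assert nds.experiments[1][0, 0] == pytest.approx(1.2)

    def test_double_normalization_rejected(self):
        ds = aesgrn.ExpressionDataset(["G1"], [np.array([[1.0], [2.0]])])
        nds = aesgrn.min_max_normalize(ds)
        with pytest.raises(DataError):
            aesgrn.min_max_normalize(nds)

    def test_denormalize_is_inverse_on_training_experiments(self, small_dataset):
        nds = aesgrn.min_max_normalize(small_dataset, training_experiments=[0, 1, 2])
        back = denormalize(nds)
        for a, b in zip(small_dataset.experiments, back.experiments):
            np.testing.assert_allclose(a, b, atol=1e-12)


class TestMakeSupervised:
    def test_hand_windowed_example(self):
        d = np.array([[0.0, 0.1, 0.2, 0.3, 0.4], [1.0, 0.9, 0.8, 0.7, 0.6]]).T
        ds = aesgrn.ExpressionDataset(["G1", "G2"], [d], normalized=True)
        sup = aesgrn.make_supervised(ds, 0, 2)
        assert len(sup) == 3
        np.testing.assert_allclose(sup.inputs[0], [0.0, 0.1, 1.0, 0.9])
        assert sup.targets[0] == pytest.approx(0.2)
        assert sup.inputs.shape == (3, 4) and sup.targets.shape == (3,)

    def test_experiments_concatenate_without_crossing_boundaries(self):
        rng = np.random.default_rng(0)
        ds = aesgrn.ExpressionDataset(
            ["G1", "G2"], [rng.random((21, 2)) for _ in range(2)], normalized=True
        )
        sup = aesgrn.make_supervised(ds, 1, 10)
        assert len(sup) == 22
        # first row of the second experiment's windows uses only that experiment
        np.testing.assert_allclose(
            sup.inputs[11], ds.experiments[1][:10, :].T.reshape(-1)
        )

    def test_window_too_large_rejected(self):
        ds = aesgrn.ExpressionDataset(
            ["G1"], [np.random.default_rng(0).random((5, 1))], normalized=True
        )
        with pytest.raises(DataError):
            aesgrn.make_supervised(ds, 0, 5)

    @settings(max_examples=25, deadline=None)
    @given(
        n=st.integers(1, 5),
        b=st.integers(3, 30),
        m=st.integers(1, 10),
        k=st.integers(1, 3),
    )
    def test_row_count_property(self, n, b, m, k):
        if m >= b:
            return
        rng = np.random.default_rng(n * 100 + b)
        ds = aesgrn.ExpressionDataset(
            [f"G{i}" for i in range(n)],
            [rng.random((b, n)) for _ in range(k)],
            normalized=True,
        )
        sup = aesgrn.make_supervised(ds, 0, m)
        assert len(sup) == k * (b - m)
        assert sup.inputs.shape[1] == n * m


class TestGoldNetwork:
    def test_defaults_and_positive_count(self, tmp_path):
        p = write(tmp_path, "g.tsv", "G1\tG2\t1\nG2\tG1\t0")
        gold = aesgrn.read_gold_network(p, ["G1", "G2", "G3"])
        assert gold.label("G1", "G2") == 1
        assert gold.label("G1", "G3") == 0
        assert gold.n_positive() == 1

    def test_self_loop_warned_and_excluded(self, tmp_path):
        p = write(tmp_path, "h.tsv", "G1\tG1\t1\nG1\tG2\t1")
        with pytest.warns(UserWarning, match="self-loop"):
            gold = aesgrn.read_gold_network(p, ["G1", "G2"])
        assert ("G1", "G1") in gold.labels
        assert len(gold.label_vector()) == 2  # only off-diagonal pairs

    def test_unknown_gene_rejected(self, tmp_path):
        p = write(tmp_path, "i.tsv", "G9\tG1\t1")
        with pytest.raises(ConsistencyError):
            aesgrn.read_gold_network(p, ["G1", "G2"])

    def test_bad_label_rejected(self, tmp_path):
        p = write(tmp_path, "j.tsv", "G1\tG2\t2")
        with pytest.raises(FormatError):
            aesgrn.read_gold_network(p, ["G1", "G2"])

    def test_ordered_pairs_layout(self):
        pairs = ordered_pairs(["a", "b"], include_self_loops=False)
        assert pairs == [("a", "b"), ("b", "a")]
        assert len(ordered_pairs(["a", "b"], include_self_loops=True)) == 4
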