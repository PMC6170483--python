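from __future__ import annotations

import numpy as np
import pytest

from ivspec import (
    SpectralDataset,
    SplitResult,
    kennard_stone_split,
    mean_center,
    read_dataset,
    write_dataset,
)

from _oracles import naive_kennard_stone


def toy_csv(tmp_path, text, name="toy.csv"):
    f = tmp_path / name
    f.write_text(text, encoding="utf-8")
    return f


CANONICAL = (
    "sample_id,900.0,1000.0,1100.0,1200.0,IV\n"
    "a,0.1,0.2,0.3,0.4,95.5\n"
    "b,0.5,0.25,0.125,1.5,101.0\n"
    "c,1.5,2.5,3.5,4.5,88.25\n"
)


class TestIO:
    def test_read_shapes_and_values(self, tmp_path):
        ds = read_dataset(toy_csv(tmp_path, CANONICAL))
        assert ds.n_samples == 3 and ds.n_channels == 4
        assert ds.sample_ids == ["a", "b", "c"]
        np.testing.assert_array_equal(ds.axis, [900.0, 1000.0, 1100.0, 1200.0])
        np.testing.assert_array_equal(ds.y, [95.5, 101.0, 88.25])
        assert ds.X[1, 3] == 1.5

    def test_round_trip_bit_identical(self, tmp_path):
        ds = read_dataset(toy_csv(tmp_path, CANONICAL))
        out = tmp_path / "out.csv"
        write_dataset(ds, out)
        assert out.read_text(encoding="utf-8") == CANONICAL
        ds2 = read_dataset(out)
        np.testing.assert_array_equal(ds.X, ds2.X)
        np.testing.assert_array_equal(ds.axis, ds2.axis)
        np.testing.assert_array_equal(ds.y, ds2.y)

    def test_empty_cell_error_names_location(self, tmp_path):
        bad = CANONICAL.replace("0.25", "")
        with pytest.raises(ValueError, match=r"row 1.*1000"):
            read_dataset(toy_csv(tmp_path, bad))

    def test_non_numeric_cell_rejected(self, tmp_path):
        bad = CANONICAL.replace("3.5", "oops")
        with pytest.raises(ValueError, match="oops"):
            read_dataset(toy_csv(tmp_path, bad))

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        bad = CANONICAL.replace("b,", "a,")
        with pytest.raises(ValueError, match="duplicate sample id"):
            read_dataset(toy_csv(tmp_path, bad))


class TestValidation:
    def test_axis_must_be_monotone(self):
        with pytest.raises(ValueError, match="monotone"):
            SpectralDataset(np.ones((2, 3)), [1.0, 3.0, 2.0], [1.0, 2.0])

    def test_length_mismatches(self):
        with pytest.raises(ValueError):
            SpectralDataset(np.ones((2, 3)), [1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            SpectralDataset(np.ones((2, 3)), [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_descending_axis_allowed(self):
        ds = SpectralDataset(np.ones((2, 3)) * [[1, 2, 3], [4, 5, 6]], [3.0, 2.0, 1.0], [1.0, 2.0])
        assert ds.n_channels == 3


class TestCentering:
    def test_calibration_means_zero_and_test_uses_cal_means(self):
        ds = SpectralDataset(
            [[1.0, 10.0], [3.0, 30.0], [2.0, 20.0]], [1.0, 2.0], [5.0, 7.0, 6.0]
        )
        split = SplitResult([0, 1], [2])
        (Xc, yc), (Xt, yt), tr = mean_center(ds, split)
        np.testing.assert_allclose(Xc.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(yc.mean(), 0.0, atol=1e-10)
        # cal means are (2, 20) and y-mean 6: the test row equals the mean
        np.testing.assert_allclose(Xt, [[0.0, 0.0]])
        np.testing.assert_allclose(yt, [0.0])

    def test_uncentering_recovers_original(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        ds = SpectralDataset(X, np.arange(4.0), y)
        split = SplitResult([0, 1, 2, 3], [4, 5])
        (Xc, yc), _, tr = mean_center(ds, split)
        np.testing.assert_allclose(tr.uncenter_x(Xc), X[:4], atol=1e-12)
        np.testing.assert_allclose(tr.uncenter_y(yc), y[:4], atol=1e-12)


class TestKennardStone:
    def test_two_samples_both_calibrate(self):
        ds = SpectralDataset([[0.0, 0.0], [1.0, 1.0]], [1.0, 2.0], [1.0, 2.0])
        sp = kennard_stone_split(ds, 2)
        assert sorted(sp.cal_indices.tolist()) == [0, 1]
        assert sp.test_indices.size == 0

    def test_max_distance_pair_seeds_selection(self):
        # 1-D spectra at 0, 1, 10 (two channels to satisfy the container)
        ds = SpectralDataset([[0.0, 0.0], [1.0, 1.0], [10.0, 10.0]], [1.0, 2.0], [1.0, 2.0, 3.0])
        sp = kennard_stone_split(ds, 2)
        assert sorted(sp.cal_indices.tolist()) == [0, 2]

    def test_matches_naive_greedy_reference(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 9))
            n_cal = int(rng.integers(2, n + 1))
            X = rng.normal(size=(n, 3))
            ds = SpectralDataset(X, np.arange(3.0), rng.normal(size=n))
            sp = kennard_stone_split(ds, n_cal)
            assert sp.cal_indices.tolist() == naive_kennard_stone(X, n_cal)

    def test_permutation_covariance(self, rng):
        X = rng.normal(size=(7, 4))
        ds = SpectralDataset(X, np.arange(4.0), rng.normal(size=7))
        sp = kennard_stone_split(ds, 4)
        perm = rng.permutation(7)
        ds_p = SpectralDataset(X[perm], np.arange(4.0), ds.y[perm])
        sp_p = kennard_stone_split(ds_p, 4)
        # relabeling samples relabels the selection (as sets; ties aside)
        assert set(perm[sp_p.cal_indices].tolist()) == set(sp.cal_indices.tolist())

    def test_identical_rows_fall_back_to_index_order(self):
        ds = SpectralDataset(np.ones((4, 2)), [1.0, 2.0], [1.0, 2.0, 3.0, 4.0])
        sp = kennard_stone_split(ds, 3)
        assert sp.cal_indices.tolist() == [0, 1, 2]

    def test_invalid_n_cal(self):
        ds = SpectralDataset(np.eye(3), [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            kennard_stone_split(ds, 1)
        with pytest.raises(ValueError):
            kennard_stone_split(ds, 4)
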