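import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import pdist, squareform

from viromefmt.stats import (DistanceMatrix, bray_curtis, pco, permanova,
                             simper)


def _table(array, prefix="s"):
    array = np.asarray(array, dtype=float)
    return pd.DataFrame(array,
                        index=[f"v{i}" for i in range(array.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(array.shape[1])])


class TestBrayCurtis:
    def test_identical_zero_disjoint_one(self):
        table = _table([[1, 1, 0], [2, 2, 0], [0, 0, 5]])
        d = bray_curtis(table).as_frame()
        assert d.iloc[0, 1] == 0.0
        assert d.iloc[0, 2] == 1.0

    def test_worked_example(self):
        # x = (1, 2), y = (3, 0): (|1-3| + |2-0|) / (4 + 2) = 2/3
        d = bray_curtis(_table([[1, 3], [2, 0]]))
        assert d.values[0, 1] == pytest.approx(2.0 / 3.0)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            table = _table(rng.uniform(0, 10, size=(8, 6)))
            ours = bray_curtis(table).values
            ref = squareform(pdist(table.T.to_numpy(), metric="braycurtis"))
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(arrays(float, (4, 3),
                  elements=hst.floats(0, 100, allow_nan=False)))
    def test_symmetry_and_unit_range(self, array):
        d = bray_curtis(_table(array)).values
        assert np.allclose(d, d.T)
        assert ((d >= 0) & (d <= 1 + 1e-12)).all()
        assert np.allclose(np.diag(d), 0.0)

    def test_negative_rejected_and_empty_pair_zero(self):
        with pytest.raises(ValueError):
            bray_curtis(_table([[-1, 0]]))
        d = bray_curtis(_table([[0, 0], [0, 0]]))
        assert d.values[0, 1] == 0.0


class TestPco:
    def test_equilateral_triangle(self):
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                           ["a", "b", "c"])
        coords, eigvals = pco(d, k=2)
        assert eigvals[0] == pytest.approx(eigvals[1])
        embedded = squareform(pdist(coords.to_numpy()))
        np.testing.assert_allclose(embedded, d.values, atol=1e-9)

    def test_euclidean_input_exactly_recovered(self):
        rng = np.random.default_rng(4)
        points = rng.normal(size=(7, 3))
        d = DistanceMatrix(squareform(pdist(points)), [f"s{i}" for i in range(7)])
        coords, _ = pco(d, k=3)
        np.testing.assert_allclose(squareform(pdist(coords.to_numpy())),
                                   d.values, atol=1e-9)

    def test_identical_samples_coincide(self):
        d = DistanceMatrix(np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], float),
                           ["a", "b", "c"])
        coords, _ = pco(d, k=1)
        assert coords.loc["a", "PCO1"] == pytest.approx(coords.loc["b", "PCO1"])

    def test_k_beyond_rank_raises(self):
        # 3 collinear points have a rank-1 configuration
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float),
                           ["a", "b", "c"])
        with pytest.raises(ValueError):
            pco(d, k=2)


def _two_cluster_distance(n_per=5, gap=50.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, 1, (n_per, 2)),
                     rng.normal(gap, 1, (n_per, 2))])
    ids = [f"s{i}" for i in range(2 * n_per)]
    labels = pd.Series(["A"] * n_per + ["B"] * n_per, index=ids)
    return DistanceMatrix(squareform(pdist(pts)), ids), labels


class TestPermanova:
    def test_no_signal_gives_p_one(self):
        d = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        labels = pd.Series(["A", "A", "B", "B"], index=list("abcd"))
        f, p = permanova(d, labels, n_perm=99, seed=0)
        assert f == 0.0 and p == 1.0

    def test_separated_clusters_significant(self):
        d, labels = _two_cluster_distance(n_per=6)
        _, p = permanova(d, labels, n_perm=1000, seed=0)
        assert p <= 0.01

    def test_matches_scikit_bio_pseudo_f(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(12)
        x = rng.lognormal(0, 1, size=(6, 10))
        table = _table(x)
        d = bray_curtis(table)
        labels = pd.Series(["A"] * 5 + ["B"] * 5, index=d.ids)
        f, _ = permanova(d, labels, n_perm=10, seed=0)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d.values, d.ids), labels.to_numpy(),
            permutations=10)
        assert f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_singleton_group_rejected(self):
        d, labels = _two_cluster_distance(n_per=2)
        labels.iloc[0] = "C"
        with pytest.raises(ValueError):
            permanova(d, labels, n_perm=10)

    def test_zero_permutations_rejected(self):
        d, labels = _two_cluster_distance()
        with pytest.raises(ValueError):
            permanova(d, labels, n_perm=0)

    def test_seed_determinism(self):
        d, labels = _two_cluster_distance(gap=2.0)
        assert permanova(d, labels, 200, seed=3) == permanova(d, labels, 200, seed=3)


class TestSimper:
    def test_identical_groups_zero_contributions(self):
        table = _table([[1, 1, 1, 1], [2, 2, 2, 2]])
        labels = pd.Series(["A", "A", "B", "B"], index=table.columns)
        records = simper(table, labels, n_perm=9, seed=0)
        assert (records["contribution"] == 0).all()

    def test_single_differing_virus_takes_all(self):
        table = _table([[1, 1, 1, 1], [0, 0, 5, 5]])
        labels = pd.Series(["A", "A", "B", "B"], index=table.columns)
        records = simper(table, labels, n_perm=9, seed=0).set_index("virus_id")
        assert records.loc["v1", "fraction"] == pytest.approx(1.0)

    def test_decomposition_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            table = _table(rng.lognormal(0, 1, size=(5, 6)))
            labels = pd.Series(["A"] * 3 + ["B"] * 3, index=table.columns)
            records = simper(table, labels, n_perm=1, seed=0)
            d = bray_curtis(table).values
            mean_between = d[:3, 3:].mean()
            assert records["contribution"].sum() == pytest.approx(
                mean_between, abs=1e-12)

    def test_cumulative_sorted_and_p_in_unit_interval(self):
        rng = np.random.default_rng(2)
        table = _table(rng.lognormal(0, 1, size=(6, 8)))
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=table.columns)
        records = simper(table, labels, n_perm=99, seed=0)
        assert records["cumulative"].is_monotonic_increasing
        assert records["fraction"].sum() == pytest.approx(1.0)
        assert ((records["p"] > 0) & (records["p"] <= 1)).all()

    def test_more_than_two_groups_rejected(self):
        table = _table([[1, 2, 3]])
        labels = pd.Series(["A", "B", "C"], index=table.columns)
        with pytest.raises(ValueError, match="two-group"):
            simper(table, labels, n_perm=9)
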