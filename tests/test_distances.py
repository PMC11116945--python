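import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nemameta import (
    DistanceMatrix,
    ValidationError,
    bray_curtis,
    euclidean_env,
    geographic_distance,
    mantel,
)


def frame(rows, labels=None, columns=None):
    rows = np.asarray(rows, dtype=float)
    labels = labels or [f"s{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=labels, columns=columns)


def coords(lonlat):
    return frame(lonlat, columns=["longitude", "latitude"])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(frame([[1, 2, 3], [1, 2, 3]]))
        assert d.data[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        d = bray_curtis(frame([[1, 0], [0, 1]]))
        assert d.data[0, 1] == 1.0

    def test_hand_computed_value(self):
        # |1-2| + |2-2| + |3-1| = 3; (1+2)+(2+2)+(3+1) = 11
        d = bray_curtis(frame([[1, 2, 3], [2, 2, 1]]))
        assert d.data[0, 1] == pytest.approx(3 / 11)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis(frame([[0, 0], [1, 2]]))

    def test_bounded_in_unit_interval(self, rng):
        d = bray_curtis(frame(rng.integers(1, 50, (10, 6))))
        assert (d.data >= 0).all() and (d.data <= 1).all()


class TestEuclideanEnv:
    def test_identical_records_zero(self):
        d = euclidean_env(frame([[1, 2], [1, 2], [3, 4]]), standardize=True)
        assert d.data[0, 1] == 0.0

    def test_one_sd_difference_is_unit_distance(self):
        # {0, 1, (1+sqrt(15))/2} has population sd exactly 1, so the first two
        # samples differ by one sd in the only varying variable
        t = (1 + np.sqrt(15)) / 2
        col = np.array([0.0, 1.0, t])
        assert col.std() == pytest.approx(1.0)
        second = np.array([5.0, 5.0, 6.0])  # non-degenerate companion variable
        d = euclidean_env(frame(np.column_stack([col, second])))
        contrib_second = (second[1] - second[0]) / second.std()
        expected = np.hypot(1.0, contrib_second)
        assert d.data[0, 1] == pytest.approx(expected)

    def test_unstandardized_pythagorean(self):
        d = euclidean_env(frame([[0, 0], [3, 4]]), standardize=False)
        assert d.data[0, 1] == pytest.approx(5.0)

    def test_zero_variance_variable_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            d = euclidean_env(frame([[1, 7], [2, 7], [3, 7]]))
        assert d.data[0, 1] > 0


class TestGeographicDistance:
    def test_identical_points_zero(self):
        d = geographic_distance(coords([[10, 20], [10, 20]]))
        assert d.data[0, 1] == 0.0

    def test_one_degree_on_equator(self):
        d = geographic_distance(coords([[0, 0], [1, 0]]))
        assert d.data[0, 1] == pytest.approx(2 * np.pi * 6371 / 360, rel=1e-4)

    def test_antipodal_points(self):
        d = geographic_distance(coords([[0, 0], [180, 0]]))
        assert d.data[0, 1] == pytest.approx(np.pi * 6371, rel=1e-4)

    def test_euclidean_degrees_mode(self):
        d = geographic_distance(coords([[0, 0], [3, 4]]), mode="euclidean_degrees")
        assert d.data[0, 1] == pytest.approx(5.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            geographic_distance(coords([[0, 95], [1, 0]]))


class TestDistanceMatrixContract:
    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_constructors_symmetric_zero_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 30, (6, 5))
        for d in (
            bray_curtis(frame(counts)),
            euclidean_env(frame(rng.normal(size=(6, 4)))),
            geographic_distance(coords(rng.uniform(-60, 60, (6, 2)))),
        ):
            assert np.allclose(d.data, d.data.T)
            assert np.allclose(np.diag(d.data), 0)


class TestMantel:
    def test_scaled_matrix_perfect_rank_correlation(self, rng):
        base = bray_curtis(frame(rng.integers(1, 30, (8, 5))))
        doubled = DistanceMatrix(2 * base.data, base.labels, "euclidean_env")
        res = mantel(base, doubled, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200, abs=0.02)

    def test_self_comparison_minimal_p(self, rng):
        d = euclidean_env(frame(rng.normal(size=(10, 3))))
        res = mantel(d, d, n_perm=199, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.02

    def test_agrees_with_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        a = euclidean_env(frame(rng.normal(size=(9, 3))))
        b = euclidean_env(frame(rng.normal(size=(9, 3))))
        res = mantel(a, b, n_perm=99, seed=0)
        r_ref, _, _ = skbio_mantel(
            SkbioDM(a.data), SkbioDM(b.data), method="spearman",
            permutations=0, alternative="greater",
        )
        assert res.r == pytest.approx(float(r_ref), abs=1e-10)

    def test_relabeling_both_matrices_preserves_p(self, rng):
        a = euclidean_env(frame(rng.normal(size=(8, 3))))
        b = euclidean_env(frame(rng.normal(size=(8, 3))))
        perm = rng.permutation(8)
        a2 = DistanceMatrix(a.data[np.ix_(perm, perm)],
                            [a.labels[i] for i in perm], a.kind)
        b2 = DistanceMatrix(b.data[np.ix_(perm, perm)],
                            [b.labels[i] for i in perm], b.kind)
        r1 = mantel(a, b, n_perm=499, seed=3)
        r2 = mantel(a2, b2, n_perm=499, seed=3)
        assert r1.r == pytest.approx(r2.r)
        assert abs(r1.p - r2.p) < 0.05  # same distribution, finite permutations

    def test_constant_matrix_rejected(self, rng):
        a = euclidean_env(frame(rng.normal(size=(6, 3))))
        flat = DistanceMatrix(np.ones((6, 6)) - np.eye(6), a.labels, "euclidean_env")
        with pytest.raises(ValidationError):
            mantel(a, flat, n_perm=99, seed=0)

    def test_too_small_rejected(self, rng):
        d = euclidean_env(frame(rng.normal(size=(3, 3))))
        with pytest.raises(ValidationError):
            mantel(d, d, n_perm=99, seed=0)

    def test_mismatched_labels_rejected(self, rng):
        a = euclidean_env(frame(rng.normal(size=(5, 3))))
        b = euclidean_env(frame(rng.normal(size=(5, 3)),
                                labels=[f"x{i}" for i in range(5)]))
        with pytest.raises(ValidationError):
            mantel(a, b, n_perm=99, seed=0)

    def test_deterministic_given_seed(self, rng):
        a = euclidean_env(frame(rng.normal(size=(8, 3))))
        b = euclidean_env(frame(rng.normal(size=(8, 3))))
        assert mantel(a, b, n_perm=199, seed=5) == mantel(a, b, n_perm=199, seed=5)
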