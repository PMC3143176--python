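"""Spatial statistics vs naive pair-loop oracles and constructed patterns."""

import numpy as np
import pytest

from aedespop.spatial_stats import (
    CountMap,
    SpatialWeights,
    UndefinedStatisticError,
    cluster_size_profile,
    critical_z,
    getis_gi,
    l_statistics,
    morans_i,
    read_counts,
    write_counts,
)

# ---------------------------------------------------------------------------
# naive O(N^2) reference implementations


def manhattan(pos, i, j):
    return abs(pos[i, 0] - pos[j, 0]) + abs(pos[i, 1] - pos[j, 1])


def moran_brute(x, pos):
    n = len(x)
    xb = x.mean()
    num = W = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            w = 1.0 / manhattan(pos, i, j)
            W += w
            num += w * (x[i] - xb) * (x[j] - xb)
    return n / W * num / ((x - xb) ** 2).sum()


def lw_brute(x, pos, d):
    n = len(x)
    num = tot = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            tot += x[i] * x[j]
            if manhattan(pos, i, j) <= d:
                num += x[i] * x[j]
    return np.sqrt(n * num / tot / np.pi)


def gi_brute(x, pos, d, i):
    n = len(x)
    xb, s = x.mean(), x.std()
    sm, wi = 0.0, 0
    for j in range(n):
        if j == i:
            continue
        if manhattan(pos, i, j) <= d:
            sm += x[j]
            wi += 1
    den = s * np.sqrt(((n - 1) * wi - wi**2) / (n - 1))
    return (sm - wi * xb) / den


def lattice(nr, nc):
    return np.array([(r, c) for r in range(nr) for c in range(nc)])


# ---------------------------------------------------------------------------


class TestMoran:
    def test_two_point_antithesis(self):
        cm = CountMap(np.array([0.0, 2.0]), np.array([[0, 0], [0, 1]]))
        r = morans_i(cm, n_perm=0)
        assert r.I == pytest.approx(-1.0)
        assert r.expected == pytest.approx(-1.0)

    def test_matches_bruteforce_on_random_grids(self, rng):
        for _ in range(20):
            nr, nc = rng.integers(3, 7, size=2)
            pos = lattice(nr, nc)
            x = rng.integers(0, 40, len(pos)).astype(float)
            if x.std() == 0:
                continue
            r = morans_i(CountMap(x, pos), n_perm=0)
            assert r.I == pytest.approx(moran_brute(x, pos), abs=1e-12)

    def test_permutation_mean_near_expected(self, rng):
        pos = lattice(6, 6)
        x = rng.poisson(6, 36).astype(float)
        r = morans_i(CountMap(x, pos), n_perm=2000, seed=1)
        se = r.perm_values.std(ddof=1) / np.sqrt(len(r.perm_values))
        assert abs(r.perm_values.mean() - (-1.0 / 35)) < 3 * se

    def test_zero_variance_raises(self):
        cm = CountMap(np.full(9, 4.0), lattice(3, 3))
        with pytest.raises(UndefinedStatisticError):
            morans_i(cm, n_perm=0)

    def test_affine_invariance(self, rng):
        pos = lattice(5, 5)
        x = rng.integers(0, 30, 25).astype(float)
        a = morans_i(CountMap(x, pos), n_perm=0).I
        b = morans_i(CountMap(3.0 * x + 7.0, pos), n_perm=0).I
        assert a == pytest.approx(b, abs=1e-12)

    def test_weights_are_symmetric_zero_diagonal(self, rng):
        cm = CountMap(rng.integers(0, 9, 12).astype(float), lattice(4, 3))
        w = SpatialWeights.inverse_distance(cm).w
        assert np.allclose(w, w.T)
        assert np.all(np.diag(w) == 0)
        assert (w >= 0).all()


class TestLStatistics:
    def test_constant_counts_delta_exactly_zero(self):
        cm = CountMap(np.full(30, 7.0), lattice(5, 6))
        r = l_statistics(cm, d_max=6)
        assert np.all(r.delta == 0.0)
        np.testing.assert_array_equal(r.L_w, r.L)

    def test_matches_bruteforce(self, rng):
        pos = lattice(3, 3)
        x = rng.integers(1, 20, 9).astype(float)
        r = l_statistics(CountMap(x, pos), d_max=2)
        for d in (1, 2):
            assert r.L_w[d - 1] == pytest.approx(lw_brute(x, pos, d), abs=1e-12)
            assert r.L[d - 1] == pytest.approx(
                lw_brute(np.ones(9), pos, d), abs=1e-12
            )

    def test_scaling_invariance(self, rng):
        pos = lattice(4, 4)
        x = rng.integers(1, 25, 16).astype(float)
        a = l_statistics(CountMap(x, pos), 3)
        b = l_statistics(CountMap(10.0 * x, pos), 3)
        np.testing.assert_allclose(a.L_w, b.L_w, atol=1e-12)

    def test_adjacent_concentration_detected_above_envelope(self, rng):
        # all pupae piled into two adjacent cells: delta(1) positive and
        # outside the 95% permutation envelope
        pos = lattice(9, 9)
        x = np.zeros(81)
        x[3 * 9 + 3] = 50
        x[3 * 9 + 4] = 50
        x += rng.integers(0, 2, 81)
        r = l_statistics(CountMap(x, pos), 4, n_perm=199, seed=2)
        assert r.delta[0] > 0
        assert r.delta[0] > r.envelope_hi[0]

    def test_all_zero_counts_raise(self):
        with pytest.raises(UndefinedStatisticError):
            l_statistics(CountMap(np.zeros(9), lattice(3, 3)), 2)


class TestGetisGi:
    def test_matches_bruteforce(self, rng):
        pos = lattice(5, 5)
        x = rng.integers(0, 30, 25).astype(float)
        g = getis_gi(CountMap(x, pos), d=2)
        for i in range(25):
            if not g.degenerate[i]:
                assert g.z[i] == pytest.approx(gi_brute(x, pos, 2, i), abs=1e-12)

    def test_balanced_neighborhood_scores_zero(self):
        # house whose neighbors sum to W_i * xbar has G_i exactly 0
        pos = lattice(1, 5)
        x = np.array([5.0, 3.0, 3.0, 3.0, 1.0])  # xbar = 3
        g = getis_gi(CountMap(x, pos), d=1)
        assert g.z[2] == pytest.approx(0.0, abs=1e-12)

    def test_threshold_monotonicity(self, rng):
        pos = lattice(5, 5)
        x = rng.integers(0, 30, 25).astype(float)
        g = getis_gi(CountMap(x, pos), d=1)
        finite = np.abs(np.nan_to_num(g.z))
        high = getis_gi(CountMap(x, pos), d=1, threshold=finite.max() + 1.0)
        assert set(high.labels) == {"none"}

    def test_complete_neighborhood_degenerate(self):
        cm = CountMap(np.array([1.0, 2.0, 3.0, 4.0]), lattice(2, 2))
        g = getis_gi(cm, d=2)  # every house reaches all others
        assert g.degenerate.all()
        assert set(g.labels) == {"none"}

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            getis_gi(CountMap(np.full(9, 2.0), lattice(3, 3)), d=1)

    def test_null_label_rate_within_nominal(self, rng):
        # under shuffled counts, <= 2% of houses flagged at the 1% threshold
        pos = lattice(8, 8)
        x = rng.poisson(5, 64).astype(float)
        flags = total = 0
        for _ in range(150):
            g = getis_gi(CountMap(rng.permutation(x), pos), d=2)
            flags += int(np.sum(g.labels != "none"))
            total += int(np.sum(~g.degenerate))
        assert flags / total <= 0.02


HOT_CELLS = [(5, 5), (5, 6), (6, 5), (6, 6)]


def planted_hotspot_counts():
    """Frozen 12x12 fixture: uniform background, hot 2x2 block at center."""
    rng = np.random.default_rng(6)
    x = rng.integers(0, 6, 144).astype(float)
    for r, c in HOT_CELLS:
        x[r * 12 + c] = 12.0
    return CountMap(x, lattice(12, 12))


class TestClusterProfile:
    def test_uniform_counts_have_no_clusters(self):
        cm = CountMap(np.full(25, 3.0), lattice(5, 5))
        prof = cluster_size_profile(cm, [1, 2, 3])
        assert all(v == {"positive": 0, "negative": 0} for v in prof.values())

    def test_planted_hotspot_membership_profile(self):
        cm = planted_hotspot_counts()
        g1 = getis_gi(cm, d=1)
        hot_idx = [r * 12 + c for r, c in HOT_CELLS]
        assert all(g1.labels[i] == "positive-cluster" for i in hot_idx)
        assert all(g1.z[i] > critical_z() for i in hot_idx)
        prof = cluster_size_profile(cm, range(1, 11))
        assert prof[1]["positive"] >= 4
        for d in range(6, 11):
            assert prof[d] == {"positive": 0, "negative": 0}

    def test_profile_deterministic_function_of_gi(self):
        cm = planted_hotspot_counts()
        assert cluster_size_profile(cm, [1, 3]) == cluster_size_profile(cm, [1, 3])


class TestIO:
    def test_counts_roundtrip(self, tmp_path, rng):
        cm = CountMap(rng.integers(0, 9, 12).astype(float), lattice(4, 3))
        path = tmp_path / "counts.csv"
        write_counts(cm, path)
        back = read_counts(path)
        np.testing.assert_array_equal(back.x, cm.x)
        np.testing.assert_array_equal(back.positions, cm.positions)
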