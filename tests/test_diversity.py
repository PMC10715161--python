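import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import braycurtis

from enteroeco.containers import AbundanceTable, ConfigError, SchemaError
from enteroeco import diversity as div
from conftest import euclidean_dm


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

class TestShannon:
    @pytest.mark.parametrize("counts,expected", [
        ((5, 5, 5, 5), np.log(4)),
        ((7,), 0.0),
        ((3, 1), 0.75 * np.log(4 / 3) + 0.25 * np.log(4)),
    ])
    def test_hand_values(self, counts, expected):
        assert div.shannon(counts) == pytest.approx(expected, abs=1e-10)

    def test_base_two(self):
        assert div.shannon((1, 1), base=2) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(SchemaError):
            div.shannon((0, 0))


class TestChao1:
    @pytest.mark.parametrize("counts,expected", [
        ((3, 4, 5), 3.0),            # no singletons -> S_obs
        ((2, 2, 1, 1, 1), 6.0),      # 5 + 3*2/(2*3)
        ((1, 1, 3), 4.0),            # F2 = 0 branch: 3 + 2*1/2
    ])
    def test_hand_values(self, counts, expected):
        assert div.chao1(counts) == pytest.approx(expected, abs=1e-10)

    def test_never_below_observed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 5, size=20)
            if x.sum() == 0:
                continue
            assert div.chao1(x) >= div.observed_taxa(x)

    def test_non_integer_rejected(self):
        with pytest.raises(SchemaError):
            div.chao1((1.5, 2.0))


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

class TestBrayCurtis:
    def test_hand_values(self):
        t = AbundanceTable(pd.DataFrame(
            [[2, 2], [1, 3], [2, 2], [0, 4]],
            index=["x", "y", "x2", "z"], columns=["a", "b"]))
        dm = div.bray_curtis_matrix(t)
        assert dm["x", "y"] == pytest.approx(0.25, abs=1e-12)  # 1 - 6/8
        assert dm["x", "x2"] == 0

    def test_disjoint_supports(self):
        t = AbundanceTable(pd.DataFrame([[3, 0], [0, 5]],
                                        index=["x", "y"], columns=["a", "b"]))
        assert div.bray_curtis_matrix(t)["x", "y"] == 1

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 20, size=(6, 8)).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        t = AbundanceTable(pd.DataFrame(
            X, index=[f"s{i}" for i in range(6)],
            columns=[f"t{j}" for j in range(8)]))
        dm = div.bray_curtis_matrix(t)
        for i in range(6):
            for j in range(6):
                assert dm.data[i, j] == pytest.approx(
                    braycurtis(X[i], X[j]), abs=1e-10)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

class TestPCoA:
    def test_exact_for_one_dimensional_configuration(self):
        dm = euclidean_dm([0.0, 3.0, 4.0])
        res = div.pcoa(dm)
        assert len(res.eigenvalues) == 1
        emb = res.coordinates.to_numpy()
        D_emb = np.abs(emb - emb.T)
        assert np.allclose(D_emb, dm.data, atol=1e-10)

    def test_identical_points_give_no_positive_eigenvalues(self):
        dm = skbio.DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = div.pcoa(dm)
        assert len(res.eigenvalues) == 0

    def test_equilateral_triangle_two_equal_eigenvalues(self):
        D = np.ones((3, 3)) - np.eye(3)
        dm = skbio.DistanceMatrix(D, ids=list("abc"))
        res = div.pcoa(dm)
        assert len(res.eigenvalues) == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_matches_skbio_oracle_on_euclidean_input(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        dm = euclidean_dm(X)
        mine = div.pcoa(dm)
        ref = skbio.stats.ordination.pcoa(dm)
        ref_eig = ref.eigvals.to_numpy()
        ref_eig = ref_eig[ref_eig > 1e-9]
        assert np.allclose(np.sort(mine.eigenvalues),
                           np.sort(ref_eig), atol=1e-8)
        # embedded inter-point distances agree regardless of axis signs
        def pairdist(C):
            return np.sqrt(((C[:, None] - C[None]) ** 2).sum(-1))
        assert np.allclose(pairdist(mine.coordinates.to_numpy()),
                           dm.data, atol=1e-8)

    def test_truncation_warns(self):
        dm = euclidean_dm([0.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            div.pcoa(dm, n_axes=3)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def direct_pseudo_f(D, labels):
    """Independent evaluation of the sum-of-squares formulas."""
    labels = np.asarray(labels)
    n = len(labels)
    D2 = D ** 2
    ss_total = sum(D2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += sum(D2[i, j] for i in idx for j in idx if i < j) / len(idx)
    gk = len(np.unique(labels))
    return ((ss_total - ss_within) / (gk - 1)) / (ss_within / (n - gk))


class TestPermanova:
    def test_pseudo_f_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 2))
        dm = euclidean_dm(X)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = div.permanova(dm, labels, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(
            direct_pseudo_f(dm.data, labels), abs=1e-10)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 3))
        dm = euclidean_dm(X)
        labels = ["a"] * 6 + ["b"] * 6
        res = div.permanova(dm, labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(dm, grouping=labels,
                                             permutations=0)
        assert res.statistic == pytest.approx(ref["test statistic"],
                                              rel=1e-10)

    def test_extreme_separation_attains_minimal_p(self):
        # groups large enough that no permutation recreates the split
        rng = np.random.default_rng(8)
        X = np.concatenate([rng.normal(0, 0.01, 15),
                            rng.normal(100, 0.01, 15)])
        dm = euclidean_dm(X)
        labels = ["a"] * 15 + ["b"] * 15
        res = div.permanova(dm, labels, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.effect_size > 0.9

    def test_invariant_to_group_names_and_r2_range(self):
        rng = np.random.default_rng(2)
        dm = euclidean_dm(rng.normal(size=(10, 2)))
        lab1 = ["a"] * 5 + ["b"] * 5
        lab2 = ["grp_x"] * 5 + ["grp_y"] * 5
        r1 = div.permanova(dm, lab1, n_perm=99, seed=3)
        r2 = div.permanova(dm, lab2, n_perm=99, seed=3)
        assert r1.p_value == r2.p_value and r1.statistic == r2.statistic
        assert 0 <= r1.effect_size < 1

    def test_degenerate_distances_rejected(self):
        dm = skbio.DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.raises(ConfigError):
            div.permanova(dm, ["a", "a", "b", "b"], n_perm=9, seed=0)
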