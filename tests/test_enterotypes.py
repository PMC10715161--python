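import itertools

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import jensenshannon
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from enteroeco.containers import AbundanceTable, ConfigError
from enteroeco import enterotypes as ent
from enteroeco import io as eio


def rel_table(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(rows))]
    cols = [f"t{j}" for j in range(rows.shape[1])]
    return AbundanceTable(pd.DataFrame(rows, index=ids, columns=cols),
                          kind="relative")


def brute_force_pam(D, k):
    best = min(D[:, list(c)].min(axis=1).sum()
               for c in itertools.combinations(range(D.shape[0]), k))
    return best


# ---------------------------------------------------------------------------
# Jensen-Shannon distance
# ---------------------------------------------------------------------------

class TestJSD:
    def test_identical_rows_give_zero(self):
        d = ent.jsd_matrix(rel_table([[0.4, 0.6], [0.4, 0.6]]))
        assert d["s0", "s1"] == 0

    def test_disjoint_supports_hit_the_bound(self):
        d = ent.jsd_matrix(rel_table([[1, 0], [0, 1]]))
        assert d["s0", "s1"] == pytest.approx(np.sqrt(np.log(2)), abs=1e-12)

    def test_hand_computed_value(self):
        # 0.75 ln 1.5 + 0.25 ln 0.5 symmetrised = 0.130812; sqrt = 0.361679
        d = ent.jsd_matrix(rel_table([[0.75, 0.25], [0.25, 0.75]]))
        assert d["s0", "s1"] == pytest.approx(0.3616794657, abs=1e-9)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(0)
        P = rng.dirichlet(np.ones(6), size=5)
        d = ent.jsd_matrix(rel_table(P))
        for i in range(5):
            for j in range(5):
                assert d.data[i, j] == pytest.approx(
                    jensenshannon(P[i], P[j], base=np.e), abs=1e-10)

    def test_metric_on_random_triples(self):
        rng = np.random.default_rng(1)
        P = rng.dirichlet(np.ones(8) * 0.5, size=200)
        d = ent.jsd_matrix(rel_table(P)).data
        idx = rng.integers(0, 200, size=(200, 3))
        for a, b, c in idx:
            assert d[a, c] <= d[a, b] + d[b, c] + 1e-12
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_requires_relative_table(self, toy_counts):
        with pytest.raises(ConfigError):
            ent.jsd_matrix(toy_counts)


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

class TestPAM:
    def test_two_tight_pairs(self, four_point_dm):
        fit = ent.pam(four_point_dm, 2)
        assert fit.medoids == ["A", "C"] and fit.cost == 2
        assert fit.assignments["B"] == "A" and fit.assignments["D"] == "C"

    def test_k1_tie_breaks_to_smallest_id(self, four_point_dm):
        fit = ent.pam(four_point_dm, 1)
        assert fit.medoids == ["A"] and fit.cost == 21

    def test_zero_matrix_any_k(self):
        dm = skbio.DistanceMatrix(np.zeros((4, 4)), ids=list("wxyz"))
        assert ent.pam(dm, 3).cost == 0

    def test_k_out_of_range(self, four_point_dm):
        with pytest.raises(ConfigError):
            ent.pam(four_point_dm, 5)

    def test_matches_exhaustive_search_small_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            dm = skbio.DistanceMatrix(D, ids=[f"i{j}" for j in range(n)])
            k = int(rng.integers(2, 4))
            fit = ent.pam(dm, k)
            assert fit.cost == pytest.approx(brute_force_pam(D, k), abs=1e-9)

    def test_build_swap_never_beats_exact(self):
        # the local-search path (used above the enumeration cap) must land
        # at a cost no better than the optimum and usually equal
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 9
            X = rng.random((n, 2))
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            order = np.arange(n)
            medoids, cost = ent._pam_build_swap(D, 3, order)
            assert cost >= brute_force_pam(D, 3) - 1e-9


# ---------------------------------------------------------------------------
# CH index
# ---------------------------------------------------------------------------

class TestCHIndex:
    def test_worked_example(self, four_point_dm):
        labels = pd.Series(["u", "u", "v", "v"], index=list("ABCD"))
        # W = 2, B = 200 (global medoid A by tie-break) -> CH = 200
        assert ent.ch_index(four_point_dm, labels) == pytest.approx(200.0)

    def test_degenerate_zero_within_dispersion(self):
        D = np.array([[0, 0, 5, 5], [0, 0, 5, 5],
                      [5, 5, 0, 0], [5, 5, 0, 0]], float)
        dm = skbio.DistanceMatrix(D, ids=list("ABCD"))
        labels = pd.Series(["u", "u", "v", "v"], index=list("ABCD"))
        with pytest.warns(UserWarning, match="degenerate"):
            assert ent.ch_index(dm, labels) == np.inf

    def test_single_cluster_rejected(self, four_point_dm):
        labels = pd.Series(["u"] * 4, index=list("ABCD"))
        with pytest.raises(ConfigError):
            ent.ch_index(four_point_dm, labels)

    def test_planted_labels_beat_shuffled(self):
        rng = np.random.default_rng(5)
        wins = 0
        n_sim = 100
        for _ in range(n_sim):
            X = np.vstack([rng.normal(0, 1, (10, 3)),
                           rng.normal(4, 1, (10, 3))])
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            ids = [f"i{j}" for j in range(20)]
            dm = skbio.DistanceMatrix(D, ids=ids)
            planted = pd.Series(["a"] * 10 + ["b"] * 10, index=ids)
            shuffled = pd.Series(rng.permutation(planted.to_numpy()),
                                 index=ids)
            if shuffled.nunique() < 2:
                continue
            if ent.ch_index(dm, planted) > ent.ch_index(dm, shuffled):
                wins += 1
        assert wins >= 0.95 * n_sim

    def test_centroid_form_matches_sklearn(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        labels = rng.integers(0, 3, size=30)
        assert ent.ch_index_centroid(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels), rel=1e-10)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

class TestSelectK:
    def test_two_well_separated_blobs(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (12, 2)),
                       rng.normal(5, 0.3, (12, 2))])
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        dm = skbio.DistanceMatrix(D, ids=[f"i{j}" for j in range(24)])
        model = ent.select_k(dm, range(2, 6))
        assert model.chosen_k == 2

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.5, (8, 2)),
                       rng.normal(4, 0.5, (8, 2)),
                       rng.normal((0, 6), 0.5, (8, 2))])
        ids = [f"i{j:02d}" for j in range(24)]
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        dm = skbio.DistanceMatrix(D, ids=ids)
        model = ent.select_k(dm, range(2, 5))
        perm = rng.permutation(24)
        dm2 = skbio.DistanceMatrix(D[np.ix_(perm, perm)],
                                   ids=[ids[i] for i in perm])
        model2 = ent.select_k(dm2, range(2, 5))
        assert model2.chosen_k == model.chosen_k
        assert model2.assignments.sort_index().equals(
            model.assignments.sort_index())

    def test_labels_ordered_by_decreasing_size(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 0.3, (15, 2)),
                       rng.normal(6, 0.3, (5, 2))])
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        dm = skbio.DistanceMatrix(D, ids=[f"i{j}" for j in range(20)])
        model = ent.select_k(dm, [2])
        sizes = model.cluster_sizes()
        assert list(sizes.index) == [1, 2]
        assert sizes[1] >= sizes[2]

    def test_medoid_criterion_selectable(self, four_point_dm):
        model = ent.select_k(four_point_dm, [2], criterion="medoid")
        assert model.ch_scores[2] == pytest.approx(200.0)


class TestKMeansWSS:
    def test_monotone_and_elbow_on_triple_blob(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.4, (15, 2)),
                       rng.normal(5, 0.4, (15, 2)),
                       rng.normal((0, 7), 0.4, (15, 2))])
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        dm = skbio.DistanceMatrix(D, ids=[f"i{j}" for j in range(45)])
        wss, elbow = ent.kmeans_wss_curve(dm, range(2, 8), seed=0)
        vals = [wss[k] for k in sorted(wss)]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))
        assert elbow == 3

    def test_wss_zero_with_singleton_clusters(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        D = np.abs(X - X.T)
        dm = skbio.DistanceMatrix(D, ids=list("abcd"))
        wss, _ = ent.kmeans_wss_curve(dm, range(2, 5), seed=0)
        assert wss[4] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# driver taxa
# ---------------------------------------------------------------------------

class TestDriverTaxa:
    def _boosted_dataset(self, seed=0, boost=8.0):
        rng = np.random.default_rng(seed)
        base = np.ones(10)
        rows, labels = [], []
        for c, driver in ((1, 0), (2, 1)):
            alpha = base.copy()
            alpha[driver] *= boost
            for _ in range(15):
                rows.append(rng.dirichlet(alpha * 5))
                labels.append(c)
        t = rel_table(rows)
        return t, pd.Series(labels, index=t.sample_ids)

    def test_boosted_genus_is_sole_driver(self):
        t, labels = self._boosted_dataset()
        drivers = ent.driver_taxa(t, labels)
        assert [g for g, _, _ in drivers[1]] == ["t0"]
        assert [g for g, _, _ in drivers[2]] == ["t1"]

    def test_null_composition_rarely_yields_drivers(self):
        hits = 0
        for seed in range(10):
            t, labels = self._boosted_dataset(seed=seed, boost=1.0)
            drivers = ent.driver_taxa(t, labels)
            hits += any(len(v) for v in drivers.values())
        assert hits <= 1  # >= 90% of null runs find nothing

    def test_small_cluster_flagged_undetermined(self):
        t, labels = self._boosted_dataset()
        labels.iloc[:2] = 3  # a 2-sample cluster
        drivers = ent.driver_taxa(t, labels)
        assert drivers[3] == []
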