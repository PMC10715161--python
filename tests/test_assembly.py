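import numpy as np
import pandas as pd
import pytest
import skbio

from enteroeco.containers import AbundanceTable, ConfigError
from enteroeco import assembly as asb
from enteroeco import io as eio
from enteroeco.simulate import (ScenarioConfig, simulate_neutral_dataset,
                                simulate_phylogeny_communities, yule_tree)


def brute_force_mntd(taxa, dm):
    ids = list(dm.ids)
    total = 0.0
    for t in taxa:
        best = np.inf
        for u in taxa:
            if u != t:
                best = min(best, dm[t, u])
        total += best
    return total / len(taxa)


# ---------------------------------------------------------------------------
# MNTD
# ---------------------------------------------------------------------------

class TestMNTD:
    def test_pair_at_known_distance(self, toy_tree_file):
        dm = eio.cophenetic_matrix(eio.read_tree(toy_tree_file))
        assert asb.mntd_observed(["A", "B"], dm) == 2

    def test_star_tree_constant_distances(self):
        n = 5
        D = np.full((n, n), 2.0)
        np.fill_diagonal(D, 0)
        dm = skbio.DistanceMatrix(D, ids=[f"T{i}" for i in range(n)])
        assert asb.mntd_observed([f"T{i}" for i in range(3)], dm) == 2

    def test_three_tip_hand_value(self, toy_tree_file):
        dm = eio.cophenetic_matrix(eio.read_tree(toy_tree_file))
        assert asb.mntd_observed(["A", "B", "C"], dm) == pytest.approx(8 / 3)

    def test_matches_brute_force_on_random_communities(self):
        rng = np.random.default_rng(0)
        tree = yule_tree(12, seed=5)
        dm = eio.cophenetic_matrix(tree)
        ids = list(dm.ids)
        for _ in range(50):
            size = int(rng.integers(2, 11))
            taxa = list(rng.choice(ids, size=size, replace=False))
            assert asb.mntd_observed(taxa, dm) == pytest.approx(
                brute_force_mntd(taxa, dm), abs=1e-12)

    def test_single_taxon_undefined(self, toy_tree_file):
        dm = eio.cophenetic_matrix(eio.read_tree(toy_tree_file))
        with pytest.raises(ConfigError):
            asb.mntd_observed(["A"], dm)


# ---------------------------------------------------------------------------
# ses.MNTD
# ---------------------------------------------------------------------------

class TestSesMNTD:
    def test_full_pool_sample_is_undefined(self):
        tree = yule_tree(8, seed=1)
        dm = eio.cophenetic_matrix(tree)
        tips = list(dm.ids)
        table = AbundanceTable(pd.DataFrame(
            np.ones((1, 8), dtype=int), index=["all"], columns=tips))
        res = asb.ses_mntd(table, dm, n_null=99, seed=0)
        assert res.loc["all", "classification"] == "undefined"
        assert not np.isnan(res["null_mean"]).all()  # obs stats still reported

    def test_reproducible_for_fixed_seed(self):
        cfg = ScenarioConfig(n_taxa=32, n_samples=10, richness_per_sample=5)
        tree, table = simulate_phylogeny_communities(cfg, seed=3)
        dm = eio.cophenetic_matrix(tree)
        a = asb.ses_mntd(table, dm, n_null=99, seed=7)
        b = asb.ses_mntd(table, dm, n_null=99, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_random_assembly_is_calibrated(self):
        cfg = ScenarioConfig(n_taxa=200, n_samples=100,
                             assembly_scenario="random",
                             richness_per_sample=10)
        tree, table = simulate_phylogeny_communities(cfg, seed=2)
        res = asb.ses_mntd(table, eio.cophenetic_matrix(tree),
                           n_null=199, seed=4)
        assert abs(res["ses_mntd"].mean()) < 0.3
        assert (res["ses_mntd"].abs() > 2).mean() <= 0.10

    def test_clustered_assembly_detected(self):
        cfg = ScenarioConfig(n_taxa=200, n_samples=60,
                             assembly_scenario="clustered",
                             richness_per_sample=10)
        tree, table = simulate_phylogeny_communities(cfg, seed=2)
        res = asb.ses_mntd(table, eio.cophenetic_matrix(tree),
                           n_null=199, seed=4)
        props = asb.classify_assembly(res)
        assert props["clustered"] >= 0.7

    def test_n_null_floor(self, toy_counts, toy_tree_file):
        dm = eio.cophenetic_matrix(eio.read_tree(toy_tree_file))
        with pytest.raises(ConfigError):
            asb.ses_mntd(toy_counts, dm, n_null=10, seed=0)


class TestClassifyAssembly:
    @pytest.mark.parametrize("ses,expected", [
        (-2.5, "clustered"), (0.0, "random"), (2.5, "overdispersed"),
        (-2.0, "random"), (2.0, "random"),
    ])
    def test_thresholds(self, ses, expected):
        df = pd.DataFrame({"classification": [
            "clustered" if ses < -2 else
            "overdispersed" if ses > 2 else "random"]})
        assert asb.classify_assembly(df)[expected] == 1.0

    def test_proportions_sum_to_one(self):
        df = pd.DataFrame({"classification":
                           ["clustered", "random", "undefined", "random"]})
        props = asb.classify_assembly(df)
        assert sum(props.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Sloan neutral model
# ---------------------------------------------------------------------------

class TestNeutralModel:
    def test_predicted_frequency_limit_large_nm(self):
        p = np.array([0.01, 0.1, 0.5])
        pred = asb._predicted_freq(p, N=1000, m=1.0, d=1e-3)
        assert (pred > 0.999).all()

    def test_round_trip_recovery_default_settings(self):
        table, truth = simulate_neutral_dataset(m=0.1, seed=0)
        fit = asb.fit_neutral_model(table)
        assert abs(fit.m - 0.1) / 0.1 <= 0.2
        assert fit.r_squared >= 0.7
        assert fit.Nm == pytest.approx(fit.m * fit.N)

    def test_detected_mean_estimator_selectable_and_biased_high(self):
        table, _ = simulate_neutral_dataset(m=0.3, seed=1)
        naive = asb.fit_neutral_model(table,
                                      abundance_estimator="detected_mean")
        corrected = asb.fit_neutral_model(table)
        assert naive.m > corrected.m  # censoring inflates the naive fit

    def test_scale_consistency_with_fixed_community_size(self):
        table, _ = simulate_neutral_dataset(m=0.1, n_taxa=100, n_samples=40,
                                            seed=2)
        fit1 = asb.fit_neutral_model(table, community_size=1000)
        scaled = AbundanceTable(table.data * 3, kind="counts")
        fit2 = asb.fit_neutral_model(scaled, community_size=1000)
        assert fit1.m == pytest.approx(fit2.m, rel=1e-9)
        assert np.allclose(fit1.taxa["p"], fit2.taxa["p"])
        assert np.allclose(fit1.taxa["freq_obs"], fit2.taxa["freq_obs"])

    def test_degenerate_frequencies_rejected(self):
        table = AbundanceTable(pd.DataFrame(
            np.ones((25, 4)), index=[f"s{i}" for i in range(25)],
            columns=list("abcd")))
        with pytest.raises(ConfigError):
            asb.fit_neutral_model(table)


class TestPartitionNeutral:
    def test_wide_ci_makes_everything_neutral(self):
        table, _ = simulate_neutral_dataset(m=0.1, n_taxa=100, n_samples=40,
                                            seed=3)
        fit = asb.fit_neutral_model(table, ci_level=0.999999)
        assert (fit.taxa["partition"] == "neutral").all()

    def test_partition_counts_sum_to_fitted_taxa(self):
        table, _ = simulate_neutral_dataset(m=0.1, n_taxa=100, n_samples=40,
                                            seed=4)
        fit = asb.fit_neutral_model(table)
        assert sum(fit.partition_counts().values()) == len(fit.taxa)

    def test_always_present_rare_taxon_is_above(self):
        table, _ = simulate_neutral_dataset(m=0.05, n_taxa=100, n_samples=60,
                                            seed=5)
        data = table.data.copy()
        data["forced"] = 2.0  # present everywhere at ~2 reads (p near d)
        fit = asb.fit_neutral_model(AbundanceTable(data, kind="counts"))
        assert fit.taxa.loc["forced", "partition"] == "above"
        # oracle check of the Wilson bound at that taxon
        from statsmodels.stats.proportion import proportion_confint
        n = fit.n_samples
        pred = fit.taxa.loc["forced", "freq_pred"]
        lo, hi = proportion_confint(pred * n, n, alpha=0.05, method="wilson")
        assert fit.taxa.loc["forced", "freq_obs"] > hi

    def test_wilson_interval_matches_hand_formula(self):
        # closed-form Wilson score interval as the independent oracle
        from statsmodels.stats.proportion import proportion_confint
        z = 1.959963984540054
        for phat, n in ((0.3, 50), (0.9, 20)):
            lo, hi = proportion_confint(phat * n, n, alpha=0.05,
                                        method="wilson")
            centre = (phat + z ** 2 / (2 * n)) / (1 + z ** 2 / n)
            half = (z / (1 + z ** 2 / n)) * np.sqrt(
                phat * (1 - phat) / n + z ** 2 / (4 * n ** 2))
            assert lo == pytest.approx(centre - half, abs=1e-10)
            assert hi == pytest.approx(centre + half, abs=1e-10)
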