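"""Cross-experiment rank integration: ranking, profile distance, grouping."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_means
from rootpheno.integrate import (
    RankMatrix,
    cluster_central_values,
    group_integrated,
    rank_clusters,
    rank_heatmap,
    rank_profile_distance,
)


def _central(values_by_cluster: dict[int, dict[str, float]]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(values_by_cluster, orient="index")
    df.index.name = "cluster"
    return df


class TestRankClusters:
    def test_greatest_value_gets_rank_one(self):
        cv = _central({1: {"biomass": 3.52}, 2: {"biomass": 2.427}, 3: {"biomass": 1.472}})
        rm = rank_clusters(cv, "E")
        assert list(rm.ranks["biomass"]) == [1.0, 2.0, 3.0]

    def test_ties_share_minimum_rank(self):
        cv = _central({1: {"t": 5.0}, 2: {"t": 5.0}, 3: {"t": 1.0}})
        rm = rank_clusters(cv, "E")
        assert list(rm.ranks["t"]) == [1.0, 1.0, 3.0]

    def test_normalization_bounds_and_k1(self):
        cv = _central({1: {"t": 9.0}, 2: {"t": 5.0}, 3: {"t": 1.0}})
        norm = rank_clusters(cv, "E").normalized()
        np.testing.assert_allclose(norm["t"], [0.0, 0.5, 1.0])
        single = rank_clusters(_central({1: {"t": 4.0}}), "E2").normalized()
        assert single["t"].iloc[0] == 0.0

    def test_append_combines_experiments(self):
        a = rank_clusters(_central({1: {"t": 2.0}, 2: {"t": 1.0}}), "A")
        b = rank_clusters(_central({1: {"t": 5.0}, 2: {"t": 7.0}, 3: {"t": 6.0}}), "B")
        both = a.append(b)
        assert both.k_by_experiment == {"A": 2, "B": 3}
        assert len(both.ranks) == 5

    def test_append_rejects_mixed_statistics(self):
        a = rank_clusters(_central({1: {"t": 2.0}, 2: {"t": 1.0}}), "A", central_stat="mean")
        b = rank_clusters(_central({1: {"t": 2.0}, 2: {"t": 1.0}}), "B", central_stat="median")
        with pytest.raises(ValueError, match="central"):
            a.append(b)


class TestCentralValues:
    def _fixtures(self):
        means = pd.concat([
            make_means("E", "RXSA", {"g0": {"D": 1.0}, "g1": {"D": 3.0}, "g2": {"D": 10.0}}),
            make_means("E", "biomass", {"g0": {"D": 2.0}, "g1": {"D": 4.0}, "g2": {"D": 9.0}}),
        ])
        assignments = pd.DataFrame({"unit": ["g0", "g1", "g2"], "cluster": [1, 1, 2]})
        return means, assignments

    def test_means_per_cluster(self):
        means, assignments = self._fixtures()
        cv = cluster_central_values(means, assignments, ["RXSA", "biomass"], "E")
        assert cv.loc[1, "RXSA"] == pytest.approx(2.0)
        assert cv.loc[2, "biomass"] == pytest.approx(9.0)

    def test_median_statistic(self):
        means, assignments = self._fixtures()
        assignments["cluster"] = 1
        cv = cluster_central_values(means, assignments, ["RXSA"], "E", central_stat="median")
        assert cv.loc[1, "RXSA"] == pytest.approx(3.0)

    def test_unknown_statistic(self):
        means, assignments = self._fixtures()
        with pytest.raises(ValueError, match="central_stat"):
            cluster_central_values(means, assignments, ["RXSA"], "E", central_stat="mode")


class TestProfileDistance:
    def test_identical_profiles_zero(self):
        a = pd.Series({"t1": 0.0, "t2": 0.5, "t3": 1.0})
        assert rank_profile_distance(a, a.copy()) == 0.0

    def test_opposite_extremes_distance_one(self):
        a = pd.Series({"t1": 0.0, "t2": 0.0})
        b = pd.Series({"t1": 1.0, "t2": 1.0})
        assert rank_profile_distance(a, b) == pytest.approx(1.0)

    def test_normalization_by_shared_trait_count(self):
        # one unit apart on a single shared axis out of two
        a = pd.Series({"t1": 0.0, "t2": 0.0})
        b = pd.Series({"t1": 1.0, "t2": 0.0})
        assert rank_profile_distance(a, b) == pytest.approx(1.0 / np.sqrt(2.0))

    def test_only_shared_traits_count(self):
        a = pd.Series({"t1": 0.0, "t2": 0.0, "t3": np.nan})
        b = pd.Series({"t1": 1.0, "t2": 1.0, "t3": 0.7})
        assert rank_profile_distance(a, b) == pytest.approx(1.0)

    def test_too_few_shared_traits(self):
        a = pd.Series({"t1": 0.0, "t2": np.nan})
        b = pd.Series({"t1": 1.0, "t2": 0.3})
        with pytest.raises(ValueError, match="share"):
            rank_profile_distance(a, b)


def _rank_matrix(profiles: dict[tuple[str, int], dict[str, float]], k_by_exp) -> RankMatrix:
    idx = pd.MultiIndex.from_tuples(list(profiles), names=["experiment", "cluster"])
    ranks = pd.DataFrame([profiles[key] for key in profiles], index=idx)
    return RankMatrix(ranks=ranks, k_by_experiment=k_by_exp)


class TestGroupIntegrated:
    def _two_latent_profiles(self):
        # two experiments, each with a "steep-cheap" and a "shallow-expensive"
        # cluster; ranks 1/2 within each experiment
        profiles = {
            ("A", 1): {"biomass": 1.0, "RXSA": 2.0, "root_depth": 1.0},
            ("A", 2): {"biomass": 2.0, "RXSA": 1.0, "root_depth": 2.0},
            ("B", 1): {"biomass": 1.0, "RXSA": 2.0, "root_depth": 1.0},
            ("B", 2): {"biomass": 2.0, "RXSA": 1.0, "root_depth": 2.0},
        }
        return _rank_matrix(profiles, {"A": 2, "B": 2})

    def test_matching_profiles_merge_across_experiments(self):
        g = group_integrated(self._two_latent_profiles(), G=2)
        assert g.assignment[("A", 1)] == g.assignment[("B", 1)]
        assert g.assignment[("A", 2)] == g.assignment[("B", 2)]
        assert g.assignment[("A", 1)] != g.assignment[("A", 2)]

    def test_group_one_is_best_biomass(self):
        g = group_integrated(self._two_latent_profiles(), G=2)
        # clusters ranked 1 for biomass get group 1
        assert g.assignment[("A", 1)] == 1
        assert g.assignment[("A", 2)] == 2

    def test_g_equal_n_gives_singletons(self):
        rm = self._two_latent_profiles()
        g = group_integrated(rm, G=4)
        assert sorted(g.assignment.values()) == [1, 2, 3, 4]

    def test_g_exceeding_clusters_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            group_integrated(self._two_latent_profiles(), G=5)

    def test_invariant_to_input_row_order(self):
        rm = self._two_latent_profiles()
        shuffled = RankMatrix(ranks=rm.ranks.iloc[[3, 0, 2, 1]],
                              k_by_experiment=rm.k_by_experiment)
        a = group_integrated(rm, G=2).assignment
        b = group_integrated(shuffled, G=2).assignment
        assert a == b

    def test_disjoint_trait_sets_warn_and_use_max_distance(self):
        profiles = {
            ("A", 1): {"t1": 1.0, "t2": 2.0, "t3": np.nan, "t4": np.nan},
            ("A", 2): {"t1": 2.0, "t2": 1.0, "t3": np.nan, "t4": np.nan},
            ("B", 1): {"t1": np.nan, "t2": np.nan, "t3": 1.0, "t4": 2.0},
        }
        rm = _rank_matrix(profiles, {"A": 2, "B": 1})
        with pytest.warns(UserWarning, match="share"):
            g = group_integrated(rm, G=2)
        # every cluster still receives a group (tied distances may merge)
        assert set(g.assignment) == set(profiles)
        assert 1 <= g.G <= 2

    def test_recovers_two_latent_profiles_with_noise(self, rng):
        """Across many random draws, noisy copies of two latent rank profiles
        are grouped back together at least 90% of the time."""
        latent = {
            0: np.array([0.0, 0.1, 0.0, 0.2, 0.1]),
            1: np.array([1.0, 0.9, 1.0, 0.8, 0.9]),
        }
        traits = [f"t{i}" for i in range(5)]
        hits = 0
        n_trials = 50
        for trial in range(n_trials):
            profiles = {}
            truth = {}
            for e in range(4):
                for c, which in enumerate(rng.permutation([0, 1])):
                    vals = np.clip(latent[which] + rng.normal(0, 0.08, 5), 0, 1)
                    profiles[(f"E{e}", c + 1)] = dict(zip(traits, vals))
                    truth[(f"E{e}", c + 1)] = which
            # RankMatrix.normalized() divides by k-1; feed already-normalized
            # profiles by using rank 1/2 scale: rank = 1 + value*(k-1), k=2
            ranks = {key: {t: 1 + v for t, v in p.items()} for key, p in profiles.items()}
            rm = _rank_matrix(ranks, {f"E{e}": 2 for e in range(4)})
            g = group_integrated(rm, G=2)
            by_group: dict[int, set[int]] = {}
            for key, grp in g.assignment.items():
                by_group.setdefault(grp, set()).add(truth[key])
            if all(len(members) == 1 for members in by_group.values()):
                hits += 1
        assert hits / n_trials >= 0.9


class TestRankHeatmap:
    def test_csv_table_matches_rank_matrix(self, tmp_path):
        profiles = {
            ("A", 1): {"biomass": 1.0, "RXSA": 2.0},
            ("A", 2): {"biomass": 2.0, "RXSA": 1.0},
        }
        rm = _rank_matrix(profiles, {"A": 2})
        g = group_integrated(rm, G=2)
        csv = tmp_path / "heatmap.csv"
        png = tmp_path / "heatmap.png"
        table = rank_heatmap(rm, g, csv_path=csv, plot_path=png)
        assert csv.exists() and png.stat().st_size > 0
        # columns ordered by group id; group 1 = best biomass = cluster ("A",1)
        assert table.columns[0].startswith("A:c1")
        assert table.loc["biomass"].iloc[0] == 1.0

    def test_empty_trait_rows_dropped_with_warning(self, tmp_path):
        profiles = {
            ("A", 1): {"t1": 1.0, "t2": 2.0, "ghost": np.nan},
            ("A", 2): {"t1": 2.0, "t2": 1.0, "ghost": np.nan},
        }
        rm = _rank_matrix(profiles, {"A": 2})
        g = group_integrated(rm, G=1)
        with pytest.warns(UserWarning, match="ghost"):
            table = rank_heatmap(rm, g)
        assert "ghost" not in table.index
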