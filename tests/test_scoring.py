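import numpy as np
import pytest

from smoothscore import (
    GeneSet,
    auc_separation,
    rank_profile,
    score_average,
    score_cells,
    score_geneset_overlap,
    score_mean_z,
    score_median,
    score_rbo,
    score_singscore,
    score_ssgsea,
    score_summed_up,
)

from .conftest import make_dataset, random_sparse_counts
from . import oracles


def profile(values):
    return rank_profile(np.asarray(values, dtype=float))


def genes(idx):
    return frozenset(f"g{i}" for i in idx)


class TestRankProfile:
    def test_simple_ranks(self):
        assert list(profile([5, 1, 3]).ranks) == [3, 1, 2]

    def test_average_ties_for_zeros(self):
        assert list(profile([0, 0, 7]).ranks) == [1.5, 1.5, 3]

    def test_all_equal_vector(self):
        p = profile([2, 2, 2, 2])
        assert np.allclose(p.ranks, 2.5)

    def test_rank_sum_invariant(self, rng):
        for _ in range(5):
            v = rng.integers(0, 4, size=11)
            assert profile(v).ranks.sum() == pytest.approx(11 * 12 / 2)


class TestSummedUp:
    def test_top_gene_of_ten(self):
        v = list(range(1, 11))
        assert score_summed_up(profile(v), GeneSet("s", genes([9]))) == 10

    def test_two_part_top_minus_bottom(self):
        v = list(range(1, 11))
        gs = GeneSet("s", genes([9]), genes([0]))
        assert score_summed_up(profile(v), gs) == 10 - 1

    def test_unmeasured_set_is_missing(self):
        p = profile([1, 2, 3])
        assert np.isnan(score_summed_up(p, GeneSet("s", {"zz"})))

    def test_complement_rank_sums_add_to_total(self, rng):
        """score(S) + score(complement of S) = N(N+1)/2 for up-only sets."""
        for _ in range(5):
            v = rng.random(9)
            members = set(rng.choice(9, size=4, replace=False).tolist())
            rest = set(range(9)) - members
            s1 = score_summed_up(profile(v), GeneSet("a", genes(members)))
            s2 = score_summed_up(profile(v), GeneSet("b", genes(rest)))
            assert s1 + s2 == pytest.approx(9 * 10 / 2)


class TestAverageMedian:
    def test_mean_and_median_of_two_genes(self):
        p = profile([2, 4, 9])
        gs = GeneSet("s", genes([0, 1]))
        assert score_average(p, gs) == 3 and score_median(p, gs) == 3

    def test_single_gene_set_equals_value(self):
        p = profile([2, 4, 9])
        gs = GeneSet("s", genes([2]))
        assert score_average(p, gs) == score_median(p, gs) == 9

    def test_two_part_subtracts_down_statistic(self):
        p = profile([5, 5, 2, 2])
        gs = GeneSet("s", genes([0, 1]), genes([2, 3]))
        assert score_average(p, gs) == 3


class TestMeanZ:
    def test_gene_at_population_mean_contributes_zero(self):
        p = profile([3.0, 10.0])
        assert score_mean_z(p, GeneSet("s", genes([0])), [3.0, 1.0], [2.0, 1.0]) == 0

    def test_cell_identical_to_mean_profile_scores_zero(self):
        mean = np.array([1.0, 2.0, 3.0])
        p = rank_profile(mean)
        assert score_mean_z(p, GeneSet("s", genes([0, 1, 2])), mean, np.ones(3)) == 0

    def test_balanced_z_scores_cancel(self):
        p = profile([4.0, 2.0])
        gs = GeneSet("s", genes([0, 1]))
        assert score_mean_z(p, gs, [3.0, 3.0], [1.0, 1.0]) == 0

    def test_zero_sd_genes_excluded(self):
        p = profile([4.0, 100.0])
        gs = GeneSet("s", genes([0, 1]))
        assert score_mean_z(p, gs, [3.0, 0.0], [1.0, 0.0]) == 1.0


class TestOverlap:
    def test_count_and_fraction(self):
        p = profile([1, 0, 2])
        gs = GeneSet("s", genes([0, 1, 2]))
        assert score_geneset_overlap(p, gs) == 2
        assert score_geneset_overlap(p, gs, as_fraction=True) == pytest.approx(2 / 3)

    def test_threshold_above_everything_gives_zero(self):
        p = profile([1, 0, 2])
        assert score_geneset_overlap(p, GeneSet("s", genes([0, 1, 2])), threshold=10) == 0

    def test_two_part_counts_both_halves(self):
        p = profile([1, 1, 0])
        assert score_geneset_overlap(p, GeneSet("s", genes([0]), genes([1, 2]))) == 2


class TestSingscore:
    def test_top_n_genes_score_half(self):
        # up-set = the n top-ranked genes: up-score 1.0, centered 0.5
        v = list(range(10))
        assert score_singscore(profile(v), GeneSet("s", genes([7, 8, 9]))) == pytest.approx(0.5)

    def test_bottom_n_genes_score_minus_half(self):
        v = list(range(10))
        assert score_singscore(profile(v), GeneSet("s", genes([0, 1, 2]))) == pytest.approx(-0.5)

    def test_matches_formula_oracle_on_random_profiles(self, rng):
        for _ in range(20):
            v = list(rng.integers(0, 6, size=10).astype(float))
            up = sorted(rng.choice(10, size=3, replace=False).tolist())
            got = score_singscore(profile(v), GeneSet("s", genes(up)))
            assert got == pytest.approx(oracles.naive_singscore(v, up), abs=1e-12)

    def test_two_part_range_and_perfect_score(self):
        v = list(range(6))
        gs = GeneSet("s", genes([4, 5]), genes([0, 1]))
        assert score_singscore(profile(v), gs) == pytest.approx(1.0)

    def test_whole_universe_set_degenerates_to_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            s = score_singscore(profile([1, 2, 3]), GeneSet("s", genes([0, 1, 2])))
        assert s == 0


class TestSsgsea:
    def test_hand_enumerated_running_sum(self):
        # single set gene at the top of N=4: running sum 1, 2/3, 1/3, 0 -> 2.0
        v = [1.0, 2.0, 3.0, 4.0]
        assert score_ssgsea(profile(v), GeneSet("s", genes([3]))) == pytest.approx(2.0)

    def test_bottom_placement_is_unique_minimum(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        scores = [score_ssgsea(profile(v), GeneSet("s", genes([i]))) for i in range(5)]
        assert int(np.argmin(scores)) == 0  # lowest-expressed gene

    def test_alpha_zero_matches_uniform_weight_oracle(self, rng):
        for _ in range(10):
            v = list(rng.random(8))
            up = sorted(rng.choice(8, size=3, replace=False).tolist())
            got = score_ssgsea(profile(v), GeneSet("s", genes(up)), alpha=0.0)
            assert got == pytest.approx(oracles.naive_ssgsea(v, up, alpha=0.0), abs=1e-10)

    def test_whole_universe_is_missing(self):
        assert np.isnan(score_ssgsea(profile([1, 2]), GeneSet("s", genes([0, 1]))))


class TestRbo:
    def test_perfect_prefix_scores_one(self):
        v = list(range(8))
        assert score_rbo(profile(v), GeneSet("s", genes([5, 6, 7]))) == pytest.approx(1.0)

    def test_no_overlap_in_top_depth_scores_zero(self):
        v = list(range(8))
        assert score_rbo(profile(v), GeneSet("s", genes([0, 1]))) == 0.0

    def test_term_by_term_hand_summation(self):
        # N=5, set genes at ranking positions 1 and 3, p=0.9, D=2:
        # A_1 = 1, A_2 = 1/2; score = (1*1 + 0.9*0.5)/(1 + 0.9) = 1.45/1.9
        v = [10.0, 7.0, 8.0, 5.0, 1.0]  # descending order: g0, g2, g1, g3, g4
        gs = GeneSet("s", genes([0, 1]))  # positions 1 and 3 of the ranking
        assert score_rbo(profile(v), gs, persistence=0.9) == pytest.approx(1.45 / 1.9)

    def test_two_part_separates_concordant_from_discordant(self):
        gene_ids = [f"g{i}" for i in range(8)]
        gs = GeneSet("s", genes([0, 1]), genes([6, 7]))
        concordant = rank_profile([9, 8, 5, 4, 3, 2, 1, 0], gene_ids)
        discordant = rank_profile([0, 1, 2, 3, 4, 5, 8, 9], gene_ids)
        assert score_rbo(concordant, gs) == pytest.approx(1.0)
        assert score_rbo(discordant, gs) == pytest.approx(-1.0)

    def test_depth_parameter_respected(self):
        v = [3.0, 2.0, 1.0, 0.0]
        gs = GeneSet("s", genes([0]))
        # depth 2: A_1=1, A_2=1/2 -> (1 + 0.9/2)/1.9
        assert score_rbo(profile(v), gs, depth=2) == pytest.approx((1 + 0.45) / 1.9)


class TestDirectionalSymmetries:
    @pytest.mark.parametrize(
        "fn",
        [score_singscore, score_ssgsea, score_rbo, score_summed_up],
        ids=["singscore", "ssgsea", "rbo", "summed_up"],
    )
    def test_swapping_up_and_down_negates_score(self, rng, fn):
        for _ in range(10):
            v = rng.random(9)
            picks = rng.choice(9, size=5, replace=False)
            up, dn = genes(picks[:3]), genes(picks[3:])
            p = profile(v)
            a = fn(p, GeneSet("s", up, dn))
            b = fn(p, GeneSet("s", dn, up))
            assert a == pytest.approx(-b, abs=1e-10)


class TestRankInvariance:
    @pytest.mark.parametrize(
        "fn",
        [score_singscore, score_ssgsea, score_rbo, score_summed_up],
        ids=["singscore", "ssgsea", "rbo", "summed_up"],
    )
    def test_strictly_monotone_transforms_leave_scores_unchanged(self, rng, fn):
        transforms = [np.exp, lambda x: 3 * x + 7, lambda x: x**3, np.expm1]
        for _ in range(5):
            v = rng.integers(0, 5, size=12).astype(float)  # ties included
            picks = rng.choice(12, size=4, replace=False)
            gs = GeneSet("s", genes(picks[:2]), genes(picks[2:]))
            base = fn(profile(v), gs)
            for t in transforms:
                assert fn(profile(t(v)), gs) == pytest.approx(base, abs=1e-10)


class TestAuc:
    def test_perfect_separation(self):
        assert auc_separation([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_identical_scores_give_half(self):
        assert auc_separation([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(10):
            s = rng.integers(0, 6, size=30).astype(float)
            lab = rng.random(30) < 0.4
            assert auc_separation(s, lab) == pytest.approx(oracles.naive_auc(list(s), list(lab)))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        s = rng.normal(size=50)
        lab = rng.random(50) < 0.5
        assert auc_separation(s, lab) == pytest.approx(roc_auc_score(lab, s))


class TestScoreCells:
    def test_overlap_on_toy_fixture_matches_hand_count(self, toy_dataset, marker_geneset):
        res = score_cells(
            toy_dataset, marker_geneset, method="geneset_overlap", smooth_mode="off"
        )
        # g0,g2 per cell: cell0 has both >0, cell1 neither, cell2 only g0
        assert list(res.scores.iloc[:, 0]) == [2.0, 0.0, 1.0]
        assert res.scores.columns[0] == "sig__geneset_overlap"

    def test_smooth_off_equals_knn_zero(self, rng):
        ds = make_dataset(random_sparse_counts(rng, 15, 8))
        a = score_cells(ds, GeneSet("s", genes([0, 3])), method="singscore",
                        smooth_mode="off", append_to_annotations=False)
        b = score_cells(ds, GeneSet("s", genes([0, 3])), method="singscore",
                        smooth_mode="connectivity", knn=0, append_to_annotations=False)
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy())

    def test_unscorable_set_yields_missing_not_zero(self, toy_dataset):
        res = score_cells(toy_dataset, GeneSet("gone", {"zz"}), method="summed_up",
                          smooth_mode="off")
        assert res.scores.iloc[:, 0].isna().all()
        assert res.report["gene_sets"][0]["scorable"] is False

    def test_scores_appended_to_annotations(self, toy_dataset, marker_geneset):
        score_cells(toy_dataset, marker_geneset, method="summed_up", smooth_mode="off")
        assert "sig__summed_up" in toy_dataset.cell_annotations.columns

    def test_unknown_method_rejected(self, toy_dataset, marker_geneset):
        with pytest.raises(ValueError, match="unknown method"):
            score_cells(toy_dataset, marker_geneset, method="nope")

    def test_tiny_groups_scored_unsmoothed_and_flagged(self, toy_dataset, marker_geneset):
        res = score_cells(toy_dataset, marker_geneset, method="summed_up",
                          groupby=["label"], knn=8)
        assert not res.scores.iloc[:, 0].isna().any()
        assert all(g["K_used"] == 0 for g in res.report["groups"])

    def test_group_independence_for_rank_methods(self, rng):
        """Groupby run equals per-label runs concatenated, exactly."""
        counts = random_sparse_counts(rng, 24, 10)
        labels = ["p"] * 12 + ["q"] * 12
        ds = make_dataset(counts, labels=labels)
        gs = GeneSet("s", genes([1, 4]), genes([7]))
        joint = score_cells(ds, gs, method="singscore", groupby=["label"], knn=4,
                            min_group_size=1, seed=3, append_to_annotations=False)
        for lab, rows in (("p", slice(0, 12)), ("q", slice(12, 24))):
            sub = make_dataset(counts[rows.start or 0: rows.stop], labels=[lab] * 12)
            alone = score_cells(sub, gs, method="singscore", knn=4, min_group_size=1,
                                seed=3, append_to_annotations=False)
            assert np.array_equal(
                joint.scores.iloc[rows, 0].to_numpy(), alone.scores.iloc[:, 0].to_numpy()
            )
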