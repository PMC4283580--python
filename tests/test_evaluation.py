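import numpy as np
import pandas as pd
import pytest
from scipy import stats

from funnorm.data_model import BetaMatrix
from funnorm.errors import ValidationError
from funnorm.evaluation import (batch_r2, concordance_curve, effect_sizes,
                                find_dmps, ranking_from_dmps,
                                replicate_variance, roc_vs_gold,
                                subsample_roc)


def beta_frame(values, probes=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=probes,
                        columns=[f"s{j}" for j in range(values.shape[1])])


class TestFindDmps:
    def test_hand_anova_example(self):
        """{0.1, 0.2} vs {0.8, 0.9}: SSB = 0.49, SSW = 0.01, F = 98."""
        beta = beta_frame([[0.1, 0.2, 0.8, 0.9]])
        out = find_dmps(beta, ["a", "a", "b", "b"])
        assert out["F"].iloc[0] == pytest.approx(98.0, abs=1e-9)

    def test_identical_group_means_give_zero(self):
        beta = beta_frame([[0.3, 0.5, 0.3, 0.5]])
        out = find_dmps(beta, ["a", "a", "b", "b"])
        assert out["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_group_f_equals_squared_pooled_t(self, rng):
        values = rng.uniform(0.1, 0.9, size=(100, 12))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        out = find_dmps(beta_frame(values), groups)
        t, _ = stats.ttest_ind(values[:, :6], values[:, 6:], axis=1)
        assert np.abs(out["F"].to_numpy() - t ** 2).max() < 1e-9

    def test_matches_statsmodels_anova_oracle(self, rng):
        import statsmodels.api as sm

        values = rng.uniform(0.1, 0.9, size=(5, 9))
        groups = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        out = find_dmps(beta_frame(values), groups)
        X = pd.get_dummies(pd.Series(groups), drop_first=True, dtype=float)
        X.insert(0, "const", 1.0)
        for i in range(5):
            fit = sm.OLS(values[i], X).fit()
            assert out["F"].iloc[i] == pytest.approx(fit.fvalue, rel=1e-9)

    def test_batch_adjustment_changes_statistic(self, rng):
        values = rng.uniform(0.1, 0.9, size=(50, 12))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        batch = np.tile(["p1", "p2"], 6)
        plain = find_dmps(beta_frame(values), groups)
        adjusted = find_dmps(beta_frame(values), groups, batch)
        assert not np.allclose(plain["F"], adjusted["F"])

    def test_effect_is_group_mean_difference(self):
        beta = beta_frame([[0.2, 0.2, 0.7, 0.7]])
        out = find_dmps(beta, ["a", "a", "b", "b"])
        assert out["effect"].iloc[0] == pytest.approx(-0.5)

    def test_ranks_are_a_permutation_with_id_tiebreak(self):
        beta = beta_frame([[0.1, 0.1, 0.1, 0.1]] * 3, probes=["z", "a", "m"])
        out = find_dmps(beta, ["a", "a", "b", "b"])
        assert sorted(out["rank"]) == [1, 2, 3]
        assert list(out.sort_values("rank").index) == ["a", "m", "z"]

    def test_singleton_group_rejected(self):
        beta = beta_frame([[0.1, 0.2, 0.3]])
        with pytest.raises(ValidationError, match="at least two samples"):
            find_dmps(beta, ["a", "a", "b"])


class TestRoc:
    def test_identical_ranking_gives_auc_one(self):
        ranking = [f"p{i}" for i in range(100)]
        curve = roc_vs_gold(set(ranking[:10]), ranking)
        assert curve.auc == pytest.approx(1.0)
        assert curve.x[0] == 0.0 and curve.y[-1] == 1.0

    def test_reversed_ranking_gives_auc_zero(self):
        ranking = [f"p{i}" for i in range(100)]
        curve = roc_vs_gold(set(ranking[:10]), ranking[::-1])
        assert curve.auc == pytest.approx(0.0)

    def test_random_ranking_near_half(self):
        universe = [f"p{i}" for i in range(10_000)]
        gold = set(universe[:1000])
        inside = 0
        for seed in range(20):
            shuffled = list(np.random.default_rng(seed).permutation(universe))
            auc = roc_vs_gold(gold, shuffled).auc
            inside += 0.45 <= auc <= 0.55
        assert inside >= 18

    def test_invariant_to_monotone_transform_of_statistic(self):
        """Ranking is all that matters, so any strictly monotone re-scoring
        yields the same curve."""
        rng = np.random.default_rng(1)
        universe = [f"p{i}" for i in range(500)]
        scores = rng.normal(size=500)
        order = [universe[i] for i in np.argsort(-scores)]
        gold = set(rng.choice(universe, 50, replace=False))
        a = roc_vs_gold(gold, order).auc
        order2 = [universe[i] for i in np.argsort(-np.exp(scores))]
        assert roc_vs_gold(gold, order2).auc == pytest.approx(a)

    def test_empty_gold_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            roc_vs_gold(set(), ["p1", "p2"])


class TestConcordance:
    def test_identical_rankings_are_100_percent(self):
        r = [f"p{i}" for i in range(50)]
        curve = concordance_curve(r, r, k_values=[1, 5, 50])
        assert np.allclose(curve.y, 100.0)

    def test_disjoint_top_lists_are_zero(self):
        r1 = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        r2 = [f"b{i}" for i in range(10)] + [f"a{i}" for i in range(10)]
        curve = concordance_curve(r1, r2, k_values=[5, 10])
        assert np.allclose(curve.y, 0.0)

    def test_enumeration_example(self):
        curve = concordance_curve(["a", "b", "c"], ["b", "a", "d"],
                                  k_values=[1, 2, 3])
        assert np.allclose(curve.y, [0.0, 100.0, 200.0 / 3.0])

    def test_symmetric_in_rankings(self, rng):
        r1 = list(rng.permutation([f"p{i}" for i in range(200)]))
        r2 = list(rng.permutation([f"p{i}" for i in range(200)]))
        ks = [1, 3, 10, 60, 200]
        a = concordance_curve(r1, r2, k_values=ks)
        b = concordance_curve(r2, r1, k_values=ks)
        assert np.allclose(a.y, b.y)

    def test_k_max_clamped_with_warning(self):
        r = [f"p{i}" for i in range(10)]
        with pytest.warns(UserWarning, match="clamped"):
            curve = concordance_curve(r, r, k_max=50)
        assert curve.x.max() <= 10


class TestReplicateVariance:
    def test_identical_replicates_have_zero_variance(self):
        beta = beta_frame(np.tile([[0.4], [0.6]], (1, 6)))
        out = replicate_variance(beta, {"g1": ["s0", "s1", "s2"],
                                        "g2": ["s3", "s4", "s5"]})
        assert np.allclose(out, 0.0)

    def test_triplicate_sample_variance(self):
        beta = beta_frame([[0.1, 0.2, 0.3]])
        out = replicate_variance(beta, {"g": ["s0", "s1", "s2"]})
        assert out.iloc[0] == pytest.approx(0.01)

    def test_singleton_group_excluded_with_warning(self):
        beta = beta_frame([[0.1, 0.2, 0.3]])
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = replicate_variance(beta, {"g": ["s0", "s1"], "solo": ["s2"]})
        assert out.iloc[0] == pytest.approx(np.var([0.1, 0.2], ddof=1))


class TestEffectSizes:
    def test_equal_groups_are_zero(self):
        beta = beta_frame([[0.4, 0.4, 0.4, 0.4]] * 3)
        out = effect_sizes(beta, ["p0", "p1"], ["a", "a", "b", "b"], k=2)
        assert np.allclose(out, 0.0)

    def test_constructed_shift_recovered(self, rng):
        base = rng.uniform(0.2, 0.6, size=(20, 1))
        values = np.hstack([base, base, base + 0.15, base + 0.15])
        beta = beta_frame(values)
        ranking = [f"p{i}" for i in range(20)]
        out = effect_sizes(beta, ranking, ["a", "a", "b", "b"], k=10)
        assert np.allclose(out, -0.15)

    def test_matches_direct_subtraction_oracle(self, rng):
        values = rng.uniform(0, 1, size=(30, 8))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        beta = beta_frame(values)
        ranking = [f"p{i}" for i in range(30)]
        out = effect_sizes(beta, ranking, groups, k=30)
        oracle = values[:, :4].mean(1) - values[:, 4:].mean(1)
        assert np.allclose(out.to_numpy(), oracle)


class TestSubsampleRoc:
    @staticmethod
    def _setup(rng):
        universe = [f"p{i}" for i in range(300)]
        gold = set(universe[:30])
        scores = {pid: (10.0 if pid in gold else 0.0) + rng.normal()
                  for pid in universe}
        samples = [f"s{i}" for i in range(24)]
        groups = ["a", "b"] * 12

        def rank_subset(chosen):
            sub_rng = np.random.default_rng(len("".join(chosen)))
            noisy = {pid: s + sub_rng.normal(scale=3.0)
                     for pid, s in scores.items()}
            return sorted(universe, key=lambda p: -noisy[p])

        return samples, groups, gold, rank_subset

    def test_single_draw_band_collapses(self, rng):
        samples, groups, gold, rank_subset = self._setup(rng)
        out = subsample_roc(samples, groups, gold, rank_subset,
                            sizes=(6,), B=1, seed=0)
        band = out[6]
        assert np.allclose(band.lower_tpr, band.mean_tpr)
        assert np.allclose(band.upper_tpr, band.mean_tpr)

    def test_same_seed_reproduces(self, rng):
        samples, groups, gold, rank_subset = self._setup(rng)
        a = subsample_roc(samples, groups, gold, rank_subset,
                          sizes=(6, 10), B=3, seed=5)
        b = subsample_roc(samples, groups, gold, rank_subset,
                          sizes=(6, 10), B=3, seed=5)
        for size in (6, 10):
            assert np.allclose(a[size].mean_tpr, b[size].mean_tpr)
            assert np.allclose(a[size].aucs, b[size].aucs)

    def test_oversized_subsample_rejected(self, rng):
        samples, groups, gold, rank_subset = self._setup(rng)
        with pytest.raises(ValidationError, match="exceeds"):
            subsample_roc(samples, groups, gold, rank_subset,
                          sizes=(100,), B=1, seed=0)


class TestBatchR2:
    def test_label_aligned_shift_gives_high_r2(self, rng):
        X = rng.normal(size=(20, 5))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        X[labels == "b"] += 5.0
        assert batch_r2(X, labels) > 0.8

    def test_permuted_labels_give_low_r2(self, rng):
        X = rng.normal(size=(40, 5))
        labels = np.array(["a", "b"] * 20)
        assert batch_r2(X, labels) < 0.2
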