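"""Trial statistics: power, randomization, Welch, Fisher, questionnaires."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from thyromesh.stats import (
    SummaryStats,
    block_randomize,
    compare_arms,
    fisher_exact,
    sample_size_two_group,
    score_questionnaire,
    second_questionnaire_from_counts,
    summarize_second_questionnaire,
    welch_t_from_summary,
)


class TestSampleSize:
    def test_base_n_before_dropout_is_26_by_simulation_oracle(self):
        """Monte-Carlo power of the two-sample t at d = 0.8 brackets the
        80% target between n = 25 and n = 26 per group."""
        rng = np.random.default_rng(2024)
        reps = 4000

        def mc_power(n):
            a = rng.normal(0.8, 1.0, size=(reps, n))
            b = rng.normal(0.0, 1.0, size=(reps, n))
            t, p = sps.ttest_ind(a, b, axis=1)
            return float((p < 0.05).mean())

        assert mc_power(25) < 0.80 + 0.02
        assert mc_power(26) > 0.80 - 0.02
        assert sample_size_two_group(dropout=0.0) == 26

    def test_default_trial_design_gives_30_per_group(self):
        assert sample_size_two_group(diff=20, sd=25, power=0.80,
                                     alpha_two_sided=0.05, dropout=0.15) == 30

    def test_monotone_in_power_and_effect(self):
        n_low = sample_size_two_group(power=0.70, dropout=0.0)
        n_high = sample_size_two_group(power=0.90, dropout=0.0)
        assert n_low <= n_high
        n_small_d = sample_size_two_group(diff=10, sd=25, dropout=0.0)
        n_big_d = sample_size_two_group(diff=30, sd=25, dropout=0.0)
        assert n_small_d >= n_big_d

    def test_invalid_effect_raises(self):
        with pytest.raises(ValueError):
            sample_size_two_group(diff=0)


class TestBlockRandomize:
    def test_every_complete_block_is_balanced(self):
        for seed in range(50):
            seq = np.array(block_randomize(60, 4, seed=seed))
            blocks = seq.reshape(-1, 4)
            assert np.all(blocks.sum(axis=1) == 2)  # 2:2 within each block

    def test_prefix_balance_over_many_seeds(self):
        """Arm-1 count in any complete-block prefix is exactly half."""
        for seed in range(1000):
            seq = np.array(block_randomize(16, 4, seed=seed))
            for k in range(4, 17, 4):
                assert seq[:k].sum() == k // 2

    def test_single_block_multiset(self):
        assert sorted(block_randomize(4, 4, seed=123)) == [0, 0, 1, 1]

    def test_deterministic_under_seed(self):
        assert block_randomize(60, seed=7) == block_randomize(60, seed=7)

    def test_indivisible_block_raises(self):
        with pytest.raises(ValueError):
            block_randomize(10, block_size=3, arms=2)

    def test_permutations_are_uniform(self):
        """Each of the 6 balanced orderings of a block appears ~1/6 of the time."""
        counts = {}
        for seed in range(3000):
            key = tuple(block_randomize(4, 4, seed=seed))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        freqs = np.array(list(counts.values())) / 3000
        assert np.all(np.abs(freqs - 1 / 6) < 0.03)


class TestWelch:
    def test_matches_scipy_from_stats(self):
        a = SummaryStats(49.2, 11.3, 28)
        b = SummaryStats(42.4, 15.8, 25)
        res = welch_t_from_summary(a, b)
        t_ref, p_ref = sps.ttest_ind_from_stats(
            a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
        )
        assert res.t == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)

    def test_reproduces_raw_data_welch(self, rng):
        """Summaries computed from a raw sample reproduce scipy's raw Welch."""
        for _ in range(20):
            x = rng.normal(10, 2, size=int(rng.integers(5, 40)))
            y = rng.normal(11, 3, size=int(rng.integers(5, 40)))
            res = welch_t_from_summary(
                SummaryStats(x.mean(), x.std(ddof=1), len(x)),
                SummaryStats(y.mean(), y.std(ddof=1), len(y)),
            )
            t_ref, p_ref = sps.ttest_ind(x, y, equal_var=False)
            assert res.t == pytest.approx(t_ref)
            assert res.p == pytest.approx(p_ref)

    def test_identical_groups(self):
        g = SummaryStats(5.0, 1.0, 10)
        res = welch_t_from_summary(g, g)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_degenerate_zero_variance(self):
        g = SummaryStats(5.0, 0.0, 10)
        assert welch_t_from_summary(g, g).p == 1.0

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            SummaryStats(5.0, 1.0, 1)


class TestFisherExact:
    def test_matches_scipy_on_random_2x2_tables(self, rng):
        """The r x c enumeration specializes to scipy's 2x2 Fisher on 200
        random tables."""
        for _ in range(200):
            tab = rng.integers(0, 12, size=(2, 2))
            if tab.sum() == 0:
                tab[0, 0] = 1
            p_ref = sps.fisher_exact(tab)[1]
            assert fisher_exact(tab) == pytest.approx(p_ref, rel=1e-6, abs=1e-12)

    def test_symmetric_table_p_is_one(self):
        assert fisher_exact([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_2x3_matches_r_reference_value(self):
        # fisher.test(matrix(c(13,6,6,15,7,3), nrow=3)) -> 0.6386199
        assert fisher_exact([[13, 15], [6, 7], [6, 3]]) == pytest.approx(0.6386199, abs=1e-6)

    def test_enumeration_cap_raises(self):
        big = [[50, 60, 70], [80, 90, 100], [60, 70, 80]]
        with pytest.raises(RuntimeError, match="Monte Carlo"):
            fisher_exact(big, table_cap=100)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])


def _responses(scores_by_patient, arms):
    rows = []
    for pid, (scores, arm) in enumerate(zip(scores_by_patient, arms)):
        rows.append({"id": pid, "arm": arm, **{f"item{i+1}": s for i, s in enumerate(scores)}})
    return pd.DataFrame(rows)


class TestScoreQuestionnaire:
    def test_all_fives_and_all_ones(self):
        df = _responses([[5] * 12, [1] * 12], ["a", "b"])
        scored = score_questionnaire(df)
        assert (scored.iloc[0][list(scored.columns[2:])] == 15).all()
        assert (scored.iloc[1][list(scored.columns[2:])] == 3).all()

    def test_mixed_item_sums(self):
        items = [5, 5, 4, 5, 5, 5, 3, 4, 4, 5, 5, 5]
        scored = score_questionnaire(_responses([items], ["a"]))
        row = scored.iloc[0]
        assert (
            row["general_knowledge"], row["benefits"], row["risks"], row["satisfaction"]
        ) == (14, 15, 11, 15)

    def test_out_of_range_raises(self):
        df = _responses([[6] + [3] * 11], ["a"])
        with pytest.raises(ValueError, match="1..5"):
            score_questionnaire(df)


class TestCompareArms:
    def test_duplicated_arms_give_p_one(self, rng):
        scores = rng.integers(1, 6, size=(10, 12))
        df = pd.concat(
            [
                _responses(scores.tolist(), ["model"] * 10),
                _responses(scores.tolist(), ["conventional"] * 10),
            ]
        )
        out = compare_arms(score_questionnaire(df))
        assert np.allclose(out["p"], 1.0)

    def test_single_arm_raises(self, rng):
        df = _responses(rng.integers(1, 6, size=(5, 12)).tolist(), ["a"] * 5)
        with pytest.raises(ValueError, match="2 arms"):
            compare_arms(score_questionnaire(df))

    def test_agrees_with_direct_welch(self, rng):
        df = pd.concat(
            [
                _responses(rng.integers(1, 6, size=(12, 12)).tolist(), ["a"] * 12),
                _responses(rng.integers(1, 6, size=(9, 12)).tolist(), ["b"] * 9),
            ]
        )
        scored = score_questionnaire(df)
        out = compare_arms(scored)
        for _, row in out.iterrows():
            cat = row["category"]
            xa = scored.loc[scored["arm"] == "a", cat].astype(float)
            xb = scored.loc[scored["arm"] == "b", cat].astype(float)
            res = welch_t_from_summary(
                SummaryStats(xa.mean(), xa.std(ddof=1), len(xa)),
                SummaryStats(xb.mean(), xb.std(ddof=1), len(xb)),
            )
            assert row["p"] == pytest.approx(res.p)


class TestCompareSecondItems:
    def test_matches_scipy_paired_t(self, rng):
        from thyromesh.stats import compare_second_items

        df = pd.DataFrame(
            {f"item{i}": rng.integers(1, 6, 30) for i in range(1, 5)} | {"choice": 1}
        )
        res = compare_second_items(df, 1, 3)
        t_ref, p_ref = sps.ttest_rel(df["item1"], df["item3"])
        assert res.t == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)

    def test_identical_items_give_p_one(self):
        from thyromesh.stats import compare_second_items

        df = pd.DataFrame({"item1": [4, 5, 3], "item2": [4, 5, 3]})
        assert compare_second_items(df, 1, 2).p == 1.0


class TestSecondQuestionnaire:
    def test_published_style_counts(self):
        pct = second_questionnaire_from_counts([38, 6, 0, 9])
        assert pct["understanding the disease"] == 71.7
        assert pct["understanding the operation"] == 11.3
        assert pct["overall satisfaction"] == 17.0

    def test_single_response(self):
        df = pd.DataFrame([{"item1": 4, "item2": 5, "item3": 4, "item4": 5, "choice": 2}])
        out = summarize_second_questionnaire(df)
        assert out["forced_choice_pct"]["understanding the operation"] == 100.0
        assert out["forced_choice_pct"]["understanding the disease"] == 0.0

    def test_percentages_sum_to_100(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 80))
            df = pd.DataFrame(
                {
                    **{f"item{i}": rng.integers(1, 6, n) for i in range(1, 5)},
                    "choice": rng.integers(1, 5, n),
                }
            )
            out = summarize_second_questionnaire(df)
            assert sum(out["forced_choice_pct"].values()) == pytest.approx(100.0, abs=0.2)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_second_questionnaire(pd.DataFrame())
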