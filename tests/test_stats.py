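import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motorgraph.stats import (
    BehavioralRecord,
    UndefinedTestError,
    change_scores,
    classify,
    fdr_bh,
    load_behavior,
    pearson_with_p,
    wilcoxon_signed_rank_exact,
)

from .oracles import enumerate_signed_rank_p


class TestWilcoxonExact:
    def test_study_arat_pairs_give_printed_p(self):
        records = load_behavior()
        pre = np.array([np.nan if r.arat_pre is None else r.arat_pre for r in records])
        post = np.array([np.nan if r.arat_post is None else r.arat_post for r in records])
        res = wilcoxon_signed_rank_exact(pre, post)
        assert res.n_total == 11  # two subjects could not perform the ARAT
        assert res.n_effective == 7  # zero differences dropped
        assert res.p == pytest.approx(2 / 2**7)
        assert round(res.p, 4) == 0.0156

    def test_study_hpt_pairs_give_printed_p(self):
        records = load_behavior()
        res = wilcoxon_signed_rank_exact(
            [r.hpt_pre for r in records], [r.hpt_post for r in records]
        )
        assert res.n_effective == 13
        assert res.p == pytest.approx(2 / 2**13)
        assert round(res.p, 4) == 0.0002

    def test_three_untied_positive_differences(self):
        res = wilcoxon_signed_rank_exact([0, 0, 0], [1, 2, 3])
        assert res.p == pytest.approx(0.25)  # 2 / 2^3

    def test_all_zero_differences_is_undefined(self):
        with pytest.raises(UndefinedTestError):
            wilcoxon_signed_rank_exact([1, 2, 3], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_literal_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        pre = rng.integers(0, 6, size=n).astype(float)
        post = pre + rng.integers(-3, 4, size=n)
        d = post - pre
        if np.all(d == 0):
            return
        res = wilcoxon_signed_rank_exact(pre, post)
        assert res.p == pytest.approx(enumerate_signed_rank_p(d), abs=1e-12)

    def test_large_n_falls_back_to_normal_approximation(self):
        rng = np.random.default_rng(0)
        pre = rng.standard_normal(40)
        post = pre + rng.standard_normal(40)
        with pytest.warns(UserWarning, match="normal approximation"):
            res = wilcoxon_signed_rank_exact(pre, post)
        assert res.method == "normal"
        assert 0 < res.p <= 1

    def test_null_rejection_rate_is_calibrated(self):
        # paired i.i.d. values, no effect: raw p < 0.05 should occur ~5%
        rng = np.random.default_rng(123)
        hits = 0
        reps = 1000
        for _ in range(reps):
            pre = rng.standard_normal(13)
            post = rng.standard_normal(13)
            hits += wilcoxon_signed_rank_exact(pre, post).p < 0.05
        assert 0.03 <= hits / reps <= 0.07


class TestFdrBh:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.03]), [0.03])

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjustment_inflates_and_caps(self, pvals):
        q = fdr_bh(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0)

    def test_never_rejects_more_than_unadjusted(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(0.001, 1.0, size=15)
            q = fdr_bh(p)
            assert (q < 0.05).sum() <= (p < 0.05).sum()

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([])


class TestClassify:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            (0.001, 0.01, "significant"),
            (0.05, 0.20, "trend"),
            (0.5, 0.5, "null"),
            (0.069, 0.3, "trend"),
            (0.07, 0.3, "null"),
        ],
    )
    def test_flag_rules(self, p, q, expected):
        assert classify(p, q) == expected


class TestPearson:
    def test_perfect_linear_relationships(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_with_p(x, [2 * v + 1 for v in x]).R == pytest.approx(1.0)
        assert pearson_with_p(x, [-v for v in x]).R == pytest.approx(-1.0)

    def test_hand_computed_half_correlation(self):
        res = pearson_with_p([1, 2, 3], [1, 3, 2])
        assert res.R == pytest.approx(0.5)
        assert res.n == 3

    def test_pairwise_deletion_and_minimum_n(self):
        res = pearson_with_p([1, 2, np.nan, 4], [1, 2, 3, 4])
        assert res.n == 3
        with pytest.raises(ValueError, match="at least 3"):
            pearson_with_p([1, np.nan, 3], [1, 2, np.nan])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_with_p([1, 1, 1], [1, 2, 3])


class TestChangeScores:
    def test_table_row_delta_and_missing_handling(self):
        records = load_behavior()
        deltas = change_scores(records)
        assert deltas.loc["1", "hpt_delta"] == pytest.approx(21.06 - 29.31)
        assert np.isnan(deltas.loc["5", "arat_delta"])
        assert deltas["arat_delta"].notna().sum() == 11

    def test_no_change_gives_zero(self):
        rec = BehavioralRecord("s", 10.0, 10.0, 20.0, 20.0)
        deltas = change_scores([rec])
        assert deltas.loc["s", "arat_delta"] == 0.0
        assert deltas.loc["s", "hpt_delta"] == 0.0
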