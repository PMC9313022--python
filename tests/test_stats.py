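import numpy as np
import pytest
from scipy import stats as scipy_stats

from splicescan.profile import NucleotideProfile, per_nucleotide_profile
from splicescan.stats import (
    block_permutation_test,
    compare_region_to_background,
    unpaired_t_test,
)

from oracles import t_p_two_sided_numeric


def score_profile(scores):
    scores = np.asarray(scores, dtype=float)
    return NucleotideProfile("A" * scores.size, scores, np.ones(scores.size, dtype=int))


class TestUnpairedTTest:
    def test_identical_samples_give_t_zero_p_one(self):
        res = unpaired_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0 and res.p_two_sided == 1.0

    def test_closed_form_pooled_t(self):
        res = unpaired_t_test([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3 * np.sqrt(1.5), abs=1e-12)
        assert res.df == 4
        assert res.p_two_sided == pytest.approx(
            t_p_two_sided_numeric(res.t, res.df), abs=1e-6
        )

    def test_swapping_samples_flips_t_keeps_p(self):
        a = unpaired_t_test([1, 2, 3], [4, 5, 6])
        b = unpaired_t_test([4, 5, 6], [1, 2, 3])
        assert b.t == pytest.approx(-a.t)
        assert b.p_two_sided == pytest.approx(a.p_two_sided)

    def test_degenerate_samples_are_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            unpaired_t_test([2, 2, 2], [2, 2, 2])
        with pytest.raises(ValueError):
            unpaired_t_test([1], [1, 2])

    def test_p_values_match_numerical_integration(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, size=int(rng.integers(3, 15)))
            y = rng.normal(0.5, 1.4, size=int(rng.integers(3, 15)))
            for variant in ("pooled", "welch"):
                res = unpaired_t_test(x, y, variant=variant)
                assert res.p_two_sided == pytest.approx(
                    t_p_two_sided_numeric(res.t, res.df), abs=1e-6
                )

    def test_agrees_with_scipy_reference(self, rng):
        x = rng.normal(0, 1, size=12)
        y = rng.normal(0.3, 1, size=9)
        mine = unpaired_t_test(x, y)
        ref = scipy_stats.ttest_ind(x, y)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)
        mine_w = unpaired_t_test(x, y, variant="welch")
        ref_w = scipy_stats.ttest_ind(x, y, equal_var=False)
        assert mine_w.t == pytest.approx(ref_w.statistic, abs=1e-12)
        assert mine_w.p_two_sided == pytest.approx(ref_w.pvalue, abs=1e-12)

    def test_pooled_equals_welch_for_balanced_equal_variance(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 3.0, 4.0, 5.0]  # same spread, same n
        a = unpaired_t_test(x, y, variant="pooled")
        b = unpaired_t_test(x, y, variant="welch")
        assert a.t == pytest.approx(b.t, abs=1e-12)
        assert a.df == pytest.approx(b.df, abs=1e-9)
        assert a.p_two_sided == pytest.approx(b.p_two_sided, abs=1e-12)

    def test_rejections_agree_with_permutation_oracle(self, rng):
        # 20 small two-sample problems with varying shifts; label-shuffling
        # permutation p-values must agree on alpha=0.05 decisions in >= 18
        # and order p-values concordantly
        agree = 0
        t_ps, perm_ps = [], []
        for k in range(20):
            shift = 0.25 * (k % 5)
            x = rng.normal(shift, 1, size=10)
            y = rng.normal(0, 1, size=10)
            res = unpaired_t_test(x, y)
            pooled = np.concatenate([x, y])
            obs = abs(x.mean() - y.mean())
            count = 0
            n_perm = 2000
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                if abs(perm[:10].mean() - perm[10:].mean()) >= obs:
                    count += 1
            p_perm = (count + 1) / (n_perm + 1)
            agree += (res.p_two_sided < 0.05) == (p_perm < 0.05)
            t_ps.append(res.p_two_sided)
            perm_ps.append(p_perm)
        assert agree >= 18
        rho = scipy_stats.spearmanr(t_ps, perm_ps).statistic
        assert rho > 0.9

    def test_type_i_error_is_calibrated(self, rng):
        # iid scores, an arbitrary "region" with nothing planted: the
        # region-vs-complement test should reject at ~5%
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            prof = score_profile(rng.normal(0, 1, size=120))
            res = compare_region_to_background(prof, [(30, 60)], background="complement")
            rejections += res.p_two_sided < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestCompareRegionToBackground:
    def test_constant_profile_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_region_to_background(score_profile([0.2] * 40), [(5, 15)])

    def test_region_equal_to_whole_gives_t_zero(self, rng):
        prof = score_profile(rng.normal(0, 1, size=50))
        res = compare_region_to_background(prof, [(0, 50)], background="whole")
        assert res.t == pytest.approx(0.0) and res.p_two_sided == pytest.approx(1.0)

    def test_planted_insertion_is_significant(self, expanded_gene, planted_table):
        prof = per_nucleotide_profile(expanded_gene.sequence, planted_table)
        res = compare_region_to_background(
            prof, [expanded_gene.annotations["insertion"]], background="whole"
        )
        assert res.mean_region > res.mean_background
        assert res.p_two_sided < 0.01

    def test_missing_scores_are_excluded(self):
        scores = np.array([np.nan, np.nan, 1.0, 2.0, 3.0, 0.0, 0.5, 1.5])
        prof = NucleotideProfile("A" * 8, scores, (~np.isnan(scores)).astype(int))
        res = compare_region_to_background(prof, [(0, 5)], background="complement")
        assert res.n_region == 3 and res.n_background == 3

    def test_union_of_intervals_forms_one_region(self, rng):
        prof = score_profile(rng.normal(0, 1, size=60))
        res = compare_region_to_background(
            prof, [(0, 10), (5, 15), (40, 50)], background="complement"
        )
        assert res.n_region == 25  # overlapping intervals collapse to a union

    def test_unknown_background_mode_rejected(self, rng):
        prof = score_profile(rng.normal(0, 1, size=30))
        with pytest.raises(ValueError):
            compare_region_to_background(prof, [(0, 5)], background="flanks")


class TestBlockPermutation:
    def test_detects_planted_region_and_respects_null(self, rng):
        scores = rng.normal(0, 1, size=120)
        scores[40:70] += 2.0
        prof = score_profile(scores)
        diff, p = block_permutation_test(
            prof, [(40, 70)], background="complement", n_permutations=500, seed=3
        )
        assert diff > 1.0 and p < 0.05
        null_prof = score_profile(rng.normal(0, 1, size=120))
        _, p_null = block_permutation_test(
            null_prof, [(40, 70)], background="complement",
            n_permutations=500, seed=3,
        )
        assert p_null > 0.05
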