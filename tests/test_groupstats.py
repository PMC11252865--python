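"""Adaptive two-sample decision tree: summaries, branch logic, error rates."""

import numpy as np
import pytest
from scipy import stats

from aortamech import (
    GroupSample,
    InsufficientDataError,
    check_normality,
    compare_all_groups,
    compare_variances,
    select_and_test,
    summarize,
)
from aortamech.synthetic import gen_group_dataset


def sample(values, group="g"):
    return GroupSample(tuple(values), group=group)


class TestSummarize:
    @pytest.mark.parametrize(
        "values, mean, sem",
        [
            ([1, 2, 3], 2.0, 1.0 / np.sqrt(3)),
            ([5, 5, 5, 5], 5.0, 0.0),
            ([2, 4, 4, 4, 5, 5, 7, 9], 5.0, np.sqrt(32 / 7) / np.sqrt(8)),
        ],
    )
    def test_mean_and_sem(self, values, mean, sem):
        m, s = summarize(sample(values))
        assert m == pytest.approx(mean, rel=1e-12)
        assert s == pytest.approx(sem, abs=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            GroupSample((1.0, 2.0))


class TestNormality:
    def test_null_rejection_rate_near_alpha(self):
        """Lilliefors at n=8 rejects ~5% of truly normal samples."""
        rng = np.random.default_rng(0)
        rejections = sum(
            not check_normality(sample(rng.normal(0, 1, 8))).is_normal
            for _ in range(400)
        )
        assert 0.01 <= rejections / 400 <= 0.12

    def test_skewed_alternative_rejected(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            not check_normality(sample(rng.exponential(1.0, 50))).is_normal
            for _ in range(50)
        )
        assert rejections / 50 > 0.8

    def test_constant_sample_degenerate(self):
        res = check_normality(sample([5.0] * 6))
        assert not res.is_normal
        assert res.p_value == 0.0
        assert "degenerate" in res.flags

    def test_plain_variant_differs_from_lilliefors(self):
        rng = np.random.default_rng(2)
        x = sample(rng.normal(0, 1, 12))
        p_lill = check_normality(x, variant="lilliefors").p_value
        p_plain = check_normality(x, variant="plain").p_value
        assert p_plain > p_lill  # naive KS with estimated params is anticonservative


class TestVarianceComparison:
    def test_identical_samples(self):
        a = sample([1.0, 2.0, 3.0, 4.0])
        res = compare_variances(a, a)
        assert res.f_statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.equal_variance

    def test_hundredfold_variance_detected(self):
        rng = np.random.default_rng(3)
        a = sample(rng.normal(0, 1, 8))
        b = sample(rng.normal(0, 10, 5))
        assert not compare_variances(a, b).equal_variance

    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(4)
        fp = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = sample(rng.normal(0, 1, 8))
            b = sample(rng.normal(0, 1, 5))
            fp += not compare_variances(a, b).equal_variance
        # 99% binomial band around 0.05 at 1000 replicates
        band = 2.576 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(fp / n_rep - 0.05) < band + 0.005

    def test_zero_variance_degenerate(self):
        res = compare_variances(sample([1.0, 1.0, 1.0]), sample([1.0, 2.0, 3.0]))
        assert not res.equal_variance
        assert "degenerate" in res.flags


class TestBranchSelection:
    def test_normal_equal_variance_uses_student(self):
        rng = np.random.default_rng(10)
        a = sample(rng.normal(0, 1, 8), "a")
        b = sample(rng.normal(0.5, 1, 5), "b")
        res = select_and_test(a, b)
        assert res.test_used == "unpaired_t"
        assert all(p > res.alpha for p in res.normality_p)
        assert res.variance_p > res.alpha

    def test_heteroscedastic_normals_use_welch(self):
        rng = np.random.default_rng(17)
        for _ in range(50):  # find a seed-stream state where F rejects
            a = sample(rng.normal(0, 1, 8), "a")
            b = sample(rng.normal(0, 25, 8), "b")
            res = select_and_test(a, b)
            if res.test_used == "welch_t":
                break
        assert res.test_used == "welch_t"
        assert res.variance_p <= res.alpha
        assert all(p > res.alpha for p in res.normality_p)

    def test_lognormal_group_uses_mann_whitney(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            a = sample(rng.lognormal(0, 1.5, 60), "a")
            b = sample(rng.normal(0, 1, 8), "b")
            res = select_and_test(a, b)
            if res.test_used == "mann_whitney":
                break
        assert res.test_used == "mann_whitney"
        assert min(res.normality_p) <= res.alpha
        assert res.variance_p is None

    def test_branch_exclusivity_and_significance_consistency(self):
        """Every comparison selects exactly one test justified by the recorded
        p-values, and significant <=> p <= alpha."""
        rng = np.random.default_rng(13)
        for _ in range(200):
            a = sample(rng.normal(0, rng.uniform(0.5, 3), rng.integers(5, 12)), "a")
            b = sample(rng.lognormal(0, rng.uniform(0.1, 1), rng.integers(5, 12)), "b")
            res = select_and_test(a, b)
            assert res.test_used in {"unpaired_t", "welch_t", "mann_whitney"}
            assert res.significant == (res.p_value <= res.alpha)
            both_normal = all(p > res.alpha for p in res.normality_p)
            if res.test_used == "mann_whitney":
                assert not both_normal
            else:
                assert both_normal
                assert (res.variance_p > res.alpha) == (res.test_used == "unpaired_t")

    def test_welch_equals_student_for_equal_variance_equal_n(self):
        """Shifting a sample preserves its variance: Welch and Student agree
        to machine precision with equal n."""
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 8)
        a, b = x, x + 0.8
        p_student = stats.ttest_ind(a, b, equal_var=True).pvalue
        p_welch = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert abs(p_student - p_welch) < 1e-12

    def test_mann_whitney_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(15)
        a = sample(rng.normal(0, 1.5, 30), "a")
        b = sample(rng.normal(0.7, 1.5, 30), "b")
        res1 = select_and_test(sample(np.asarray(a.values), "a"),
                               sample(np.asarray(b.values), "b"))
        ea = sample(np.exp(a.array), "a")
        eb = sample(np.exp(b.array), "b")
        from aortamech.groupstats import _mann_whitney

        assert _mann_whitney(a.array, b.array) == pytest.approx(
            _mann_whitney(ea.array, eb.array), abs=1e-12
        )


class TestAllPairs:
    def test_pair_counts(self):
        rng = np.random.default_rng(16)
        groups = [sample(rng.normal(0, 1, 6), f"g{i}") for i in range(3)]
        assert len(compare_all_groups(groups)) == 3
        assert len(compare_all_groups(groups[:2])) == 1

    def test_identical_groups_not_significant(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = compare_all_groups([sample(vals, "a"), sample(vals, "b")])
        assert not res[0].significant

    def test_holm_adjustment_never_more_liberal(self):
        rng = np.random.default_rng(18)
        groups = [sample(rng.normal(i * 0.5, 1, 8), f"g{i}") for i in range(3)]
        plain = compare_all_groups(groups)
        holm = compare_all_groups(groups, adjust="holm")
        for p, h in zip(plain, holm):
            assert h.p_adjusted >= p.p_value - 1e-15
            assert (not p.significant) or h.p_adjusted >= p.p_value


class TestGeneratedGroupDatasets:
    def test_null_normal_prefers_student_branch(self):
        spec = [{"group": "a", "n": 8, "dist": "normal"},
                {"group": "b", "n": 5, "dist": "normal"}]
        used = []
        for seed in range(200):
            a, b = gen_group_dataset(spec, seed=seed)
            used.append(select_and_test(a, b).test_used)
        assert used.count("unpaired_t") / len(used) > 0.7

    def test_sd_ratio_five_prefers_welch(self):
        spec = [{"group": "a", "n": 10, "dist": "normal", "sd": 1.0},
                {"group": "b", "n": 10, "dist": "normal", "sd": 5.0}]
        used = []
        for seed in range(100):
            a, b = gen_group_dataset(spec, seed=seed)
            used.append(select_and_test(a, b).test_used)
        assert used.count("welch_t") / len(used) > 0.6

    def test_lognormal_prefers_mann_whitney_at_large_n(self):
        spec = [{"group": "a", "n": 60, "dist": "lognormal", "sigma": 1.5},
                {"group": "b", "n": 8, "dist": "normal"}]
        used = []
        for seed in range(50):
            a, b = gen_group_dataset(spec, seed=seed)
            used.append(select_and_test(a, b).test_used)
        assert used.count("mann_whitney") / len(used) > 0.8
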