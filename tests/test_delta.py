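"""Expression screening (paired t + Cohen's d) and inter-observer agreement."""

import numpy as np
import pandas as pd
import pytest

from teatherm import (
    ZeroVarianceError,
    cohens_d,
    expression_screen,
    interobserver_compare,
    paired_ttest,
)


def _ttest_naive(pre, post):
    """Textbook paired t from hand-rolled sums."""
    import math

    d = [b - a for a, b in zip(pre, post)]
    n = len(d)
    mean = sum(d) / n
    s2 = sum((x - mean) ** 2 for x in d) / (n - 1)
    t = mean / math.sqrt(s2 / n)
    from scipy import stats

    return 2 * stats.t.sf(abs(t), n - 1)


class TestPairedTtest:
    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(1)
        pre = rng.normal(31, 1, size=18)
        post = pre + rng.normal(0.5, 0.4, size=18)
        assert paired_ttest(pre, post) == pytest.approx(_ttest_naive(pre, post), abs=1e-12)

    def test_constant_shift_flags_zero_variance(self):
        pre = np.arange(10.0)
        with pytest.raises(ZeroVarianceError):
            paired_ttest(pre, pre + 2.0)

    def test_identical_pairs_flag(self):
        pre = np.random.default_rng(2).normal(size=20)
        with pytest.raises(ZeroVarianceError):
            paired_ttest(pre, pre)

    def test_unpaired_variant(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        from scipy import stats

        assert paired_ttest(a, b, paired=False) == pytest.approx(
            stats.ttest_ind(b, a).pvalue
        )


class TestCohensD:
    def test_identical_groups_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert cohens_d(x, x) == 0.0

    def test_shift_by_pooled_sd_gives_one(self):
        rng = np.random.default_rng(4)
        pre = rng.normal(size=30)
        n = pre.size
        s_pooled = np.sqrt(((n - 1) * pre.var(ddof=1) * 2) / (2 * n - 2))
        assert cohens_d(pre, pre + s_pooled) == pytest.approx(1.0, rel=1e-12)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(2, 1.5, 12), rng.normal(3, 0.5, 12)
        m1 = sum(a) / len(a)
        m2 = sum(b) / len(b)
        s1 = sum((x - m1) ** 2 for x in a) / (len(a) - 1)
        s2 = sum((x - m2) ** 2 for x in b) / (len(b) - 1)
        sp = np.sqrt(((len(a) - 1) * s1 + (len(b) - 1) * s2) / (len(a) + len(b) - 2))
        assert cohens_d(a, b) == pytest.approx((m2 - m1) / sp, abs=1e-12)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 10)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))
        assert paired_ttest(a, b) == pytest.approx(paired_ttest(b, a))

    def test_zero_pooled_variance_flag(self):
        with pytest.raises(ZeroVarianceError):
            cohens_d([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])


def _paired_tables(n=18, n_feat=5, shift=None, seed=0, pair_noise=0.2):
    rng = np.random.default_rng(seed)
    idx = [f"teat-{k}" for k in range(n)]
    cols = [f"f{j}" for j in range(n_feat)]
    pre = pd.DataFrame(rng.normal(31, 1, size=(n, n_feat)), index=idx, columns=cols)
    post = pre + rng.normal(0, pair_noise, size=(n, n_feat))
    if shift:
        for col, delta in shift.items():
            post[col] += delta
    return pre, post


class TestExpressionScreen:
    def test_conjunction_required(self):
        """p < 0.01 with |d| <= 1.2 (or vice versa) is not expression."""
        # a tiny but consistent shift: highly significant, negligible effect size
        pre, post = _paired_tables(shift={"f0": 0.05}, seed=7, pair_noise=0.01)
        res = expression_screen(pre, post)
        row = res.table.loc["f0"]
        assert row["p_value"] < 0.01
        assert row["abs_d"] <= 1.2
        assert not row["expressed"]

    def test_injected_shift_expressed(self):
        pre, post = _paired_tables(shift={"f1": 3.0}, seed=8)
        res = expression_screen(pre, post)
        assert res.table.loc["f1", "expressed"]
        assert res.counts["expressed"] >= 1

    def test_percent_diff_formula(self):
        pre, post = _paired_tables(shift={"f2": 2.0}, seed=9)
        res = expression_screen(pre, post)
        expect = abs(post["f2"].mean() - pre["f2"].mean()) / abs(pre["f2"].mean()) * 100
        assert res.table.loc["f2", "percent_diff"] == pytest.approx(expect)

    def test_invariant_to_column_order(self):
        pre, post = _paired_tables(shift={"f1": 3.0}, seed=10)
        res1 = expression_screen(pre, post)
        shuffled = list(reversed(pre.columns))
        res2 = expression_screen(pre[shuffled], post[shuffled])
        pd.testing.assert_frame_equal(
            res1.table.sort_index(), res2.table.sort_index()
        )

    def test_degenerate_feature_flagged_not_expressed(self):
        pre, post = _paired_tables(seed=11)
        pre["flat"] = 1.0
        post["flat"] = 3.0  # constant shift: zero difference variance
        res = expression_screen(pre, post)
        assert res.table.loc["flat", "degenerate"]
        assert not res.table.loc["flat", "expressed"]

    def test_empty_table_rejected(self):
        empty = pd.DataFrame()
        with pytest.raises(ValueError):
            expression_screen(empty, empty)


class TestInterobserver:
    def test_identical_tables_perfect_agreement(self):
        a, _ = _paired_tables(seed=12)
        out = interobserver_compare(a, a.copy())
        assert (out["abs_d"] == 0).all()
        assert out["degenerate"].all()

    def test_small_perturbation_small_effect(self):
        """Tiny mask-jitter-sized noise keeps all |d| well under the study's 0.36."""
        a, _ = _paired_tables(n=25, seed=13)
        b = a + np.random.default_rng(14).normal(0, 1e-3, size=a.shape)
        out = interobserver_compare(a, b)
        assert out.attrs["summary"]["max_abs_d"] < 0.36
        assert np.isfinite(out["p_value"]).all()

    def test_shuffled_correspondence_rejected(self):
        a, _ = _paired_tables(seed=15)
        b = a.iloc[::-1]
        with pytest.raises(ValueError):
            interobserver_compare(a, b)

    def test_name_mismatch_rejected(self):
        a, _ = _paired_tables(seed=16)
        b = a.rename(columns={"f0": "other"})
        with pytest.raises(ValueError):
            interobserver_compare(a, b)
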