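"""Statistical layer against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nigraquant.stats import (cohen_kappa, empirical_auc,
                              empirical_auc_ci, fleiss_kappa, group_compare,
                              group_summary_table, hedges_g,
                              icc_absolute_agreement,
                              relative_difference_summary,
                              spearman_bonferroni_table,
                              youden_operating_point)


class TestHedgesG:
    def test_unit_pooled_sd(self):
        assert hedges_g(0, 1, 2, 1, 1, 2) == pytest.approx(1.0)

    def test_identical_groups_zero(self):
        assert hedges_g(5, 2, 30, 5, 2, 30) == 0.0

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="pooled variance"):
            hedges_g(1, 0, 10, 2, 0, 10)

    def test_small_sample_correction_shrinks(self):
        raw = hedges_g(84.5, 27.5, 111, 119.2, 33.5, 80)
        corr = hedges_g(84.5, 27.5, 111, 119.2, 33.5, 80, corrected=True)
        assert corr < raw
        assert corr == pytest.approx(raw * (1 - 3 / (4 * 189 - 1)))


class TestGroupCompare:
    def test_duplicated_groups_give_p_near_one(self):
        x = np.concatenate([np.arange(20.0), np.arange(20.0)])
        labels = np.array(["a"] * 20 + ["b"] * 20)
        assert group_compare(x, labels, method="t_test") == pytest.approx(1.0)

    def test_strong_separation_is_significant(self, rng):
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(3, 1, 50)])
        labels = np.array(["a"] * 50 + ["b"] * 50)
        assert group_compare(x, labels, method="auto") < 1e-4

    def test_null_p_values_are_uniform(self):
        """Under H0 the t-test p-values are U(0,1) across replicates."""
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(300):
            x = rng.normal(size=80)
            labels = np.array(["a"] * 40 + ["b"] * 40)
            ps.append(group_compare(x, labels, method="t_test"))
        assert sps.kstest(ps, "uniform").pvalue > 1e-3

    def test_constant_data_rank_test_rejected(self):
        x = np.ones(20)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        with pytest.raises(ValueError, match="constant"):
            group_compare(x, labels, method="kruskal_wallis")


def _auc_bruteforce(scores, y):
    """O(n^2) concordance enumeration."""
    pos = scores[y]
    neg = scores[~y]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        s = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        assert empirical_auc(s, y) == 1.0

    def test_all_ties_give_half(self):
        s = np.zeros(10)
        y = np.arange(10) < 4
        assert empirical_auc(s, y) == 0.5

    def test_matches_bruteforce_enumeration(self):
        """Rank-based AUC equals pair counting for n <= 12 per class."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_pos = rng.integers(2, 13)
            n_neg = rng.integers(2, 13)
            scores = np.round(rng.normal(size=n_pos + n_neg), 1)  # force ties
            y = np.zeros(n_pos + n_neg, bool)
            y[:n_pos] = True
            assert empirical_auc(scores, y) == pytest.approx(
                _auc_bruteforce(scores, y))

    def test_reversed_direction_complements(self, rng):
        scores = rng.normal(size=40)
        y = rng.random(40) < 0.4
        y[0], y[1] = True, False
        a_hi, _ = empirical_auc_ci(scores, y, "higher")
        a_lo, _ = empirical_auc_ci(scores, y, "lower")
        assert a_hi == pytest.approx(1.0 - a_lo)

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError, match="class absent"):
            empirical_auc(np.arange(5.0), np.ones(5, bool))

    def test_delong_ci_brackets_auc_and_tightens(self, rng):
        small = rng.normal(size=60)
        ys = np.concatenate([np.zeros(30, bool), np.ones(30, bool)])
        small[ys] += 1.0
        auc_s, ci_s = empirical_auc_ci(small, ys)
        assert ci_s[0] <= auc_s <= ci_s[1]
        big = rng.normal(size=600)
        yb = np.concatenate([np.zeros(300, bool), np.ones(300, bool)])
        big[yb] += 1.0
        _, ci_b = empirical_auc_ci(big, yb)
        assert ci_b[1] - ci_b[0] < ci_s[1] - ci_s[0]


def _youden_oracle(scores, y):
    """Exhaustive J over all cutoffs between observed scores."""
    uniq = np.unique(scores)
    cuts = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2,
                           [uniq[-1] + 1]])
    best = -np.inf
    for c in cuts:
        pred = scores > c
        j = (pred & y).sum() / y.sum() + (~pred & ~y).sum() / (~y).sum() - 1
        best = max(best, j)
    return best


class TestYouden:
    def test_separable_data_perfect_operating_point(self):
        s = np.array([0, 1, 2, 10, 11], dtype=float)
        y = np.array([0, 0, 0, 1, 1], dtype=bool)
        op = youden_operating_point(s, y)
        assert (op.sensitivity, op.specificity, op.accuracy) == (1, 1, 1)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(6, 21))
            scores = np.round(rng.normal(size=n), 1)
            y = rng.random(n) < 0.5
            y[0], y[1] = True, False
            op = youden_operating_point(scores, y)
            j = op.sensitivity + op.specificity - 1
            assert j == pytest.approx(_youden_oracle(scores, y))

    def test_label_swap_symmetry(self, rng):
        scores = rng.normal(size=30)
        y = rng.random(30) < 0.5
        y[0], y[1] = True, False
        op1 = youden_operating_point(scores, y, "higher")
        op2 = youden_operating_point(scores, ~y, "lower")
        j1 = op1.sensitivity + op1.specificity
        j2 = op2.sensitivity + op2.specificity
        assert j1 == pytest.approx(j2)


def _spearman_oracle(x, y):
    """Rank formula 1 - 6 sum d^2 / (n (n^2-1)); tie-free inputs."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d = rx - ry
    n = len(x)
    return 1 - 6 * float(d @ d) / (n * (n**2 - 1))


class TestSpearmanTable:
    def test_monotone_pairs(self):
        f = pd.DataFrame({"a": [1.0, 2, 3, 4, 5]})
        c = pd.DataFrame({"up": [2.0, 4, 9, 16, 30],
                          "down": [5.0, 4, 3, 2, 1]})
        tab = spearman_bonferroni_table(f, c, ["a"], ["up", "down"])
        assert tab.set_index("clinical").loc["up", "r"] == pytest.approx(1.0)
        assert tab.set_index("clinical").loc["down", "r"] == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self, rng):
        x = rng.permutation(8).astype(float)
        y = rng.permutation(8).astype(float)
        f = pd.DataFrame({"x": x})
        c = pd.DataFrame({"y": y})
        tab = spearman_bonferroni_table(f, c, ["x"], ["y"])
        assert tab.r.iloc[0] == pytest.approx(_spearman_oracle(x, y))

    def test_bonferroni_family_threshold(self):
        rng = np.random.default_rng(3)
        n = 60
        base = rng.normal(size=n)
        f = pd.DataFrame({f"f{i}": base + rng.normal(0, 1.2, n)
                          for i in range(4)})
        c = pd.DataFrame({f"c{j}": base + rng.normal(0, 1.2, n)
                          for j in range(5)})
        tab = spearman_bonferroni_table(f, c, list(f), list(c))
        cutoff = 0.05 / 20
        assert (tab.significant == (tab.p < cutoff)).all()

    def test_too_few_pairs_undefined(self):
        f = pd.DataFrame({"x": [1.0, 2.0, np.nan]})
        c = pd.DataFrame({"y": [1.0, np.nan, 3.0]})
        tab = spearman_bonferroni_table(f, c, ["x"], ["y"])
        assert np.isnan(tab.r.iloc[0]) and not tab.significant.iloc[0]


def _icc21_oracle(mat):
    """ICC(2,1) from explicit two-way ANOVA mean squares."""
    n, k = mat.shape
    grand = mat.mean()
    row_means = mat.mean(axis=1)
    col_means = mat.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((mat - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_raters_give_one(self):
        mat = np.column_stack([np.arange(6.0), np.arange(6.0)])
        assert icc_absolute_agreement(mat).value == pytest.approx(1.0)

    def test_matches_anova_oracle(self):
        mat = np.array([[9.0, 2.0], [4.5, 4.0], [7.0, 6.5], [10.0, 8.0]])
        got = icc_absolute_agreement(mat)
        assert got.value == pytest.approx(_icc21_oracle(mat), abs=1e-9)
        assert (got.n_subjects, got.n_raters) == (4, 2)

    def test_constant_offset_lowers_absolute_agreement(self, rng):
        base = rng.normal(size=12)
        same = np.column_stack([base, base])
        offset = np.column_stack([base, base + 1.5])
        assert (icc_absolute_agreement(offset).value
                < icc_absolute_agreement(same).value)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement(np.ones((5, 2)))


def _fleiss_oracle(table):
    """P-bar / Pe-bar construction from the category-count table."""
    n, _ = table.shape
    k = table[0].sum()
    p_cat = table.sum(axis=0) / (n * k)
    p_i = ((table**2).sum(axis=1) - k) / (k * (k - 1))
    p_bar = p_i.mean()
    pe = (p_cat**2).sum()
    return (p_bar - pe) / (1 - pe)


class TestFleissKappa:
    def test_unanimous_mixed_categories(self):
        mat = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1]])
        assert fleiss_kappa(mat).value == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        mat = np.array([[0, 0, 1], [1, 1, 1], [0, 1, 2], [2, 2, 2],
                        [0, 0, 0], [1, 2, 2]])
        counts = np.array([[np.sum(row == c) for c in range(3)]
                           for row in mat])
        assert fleiss_kappa(mat).value == pytest.approx(
            _fleiss_oracle(counts), abs=1e-12)

    def test_uniform_random_ratings_near_zero(self):
        rng = np.random.default_rng(9)
        mat = rng.integers(0, 3, size=(3000, 4))
        assert abs(fleiss_kappa(mat).value) < 0.03

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="one category"):
            fleiss_kappa(np.ones((5, 3), dtype=int))


class TestCohenKappa:
    def test_identical_raters(self):
        a = np.array([0, 1, 1, 0, 1])
        assert cohen_kappa(a, a).value == pytest.approx(1.0)

    def test_contingency_closed_form(self):
        # 2x2 contingency (a, b, c, d) = (40, 5, 5, 30)
        a = np.array([0] * 45 + [1] * 35)
        b = np.array([0] * 40 + [1] * 5 + [0] * 5 + [1] * 30)
        po = 70 / 80
        pe = (45 / 80) * (45 / 80) + (35 / 80) * (35 / 80)
        assert cohen_kappa(a, b).value == pytest.approx((po - pe) / (1 - pe))

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(21)
        a = rng.integers(0, 2, 5000)
        b = rng.integers(0, 2, 5000)
        assert abs(cohen_kappa(a, b).value) < 0.03

    def test_degenerate_chance_agreement_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(np.zeros(5, int), np.zeros(5, int))


class TestRelativeDifferences:
    def test_equal_means(self):
        out = relative_difference_summary({"x": (10.0, 10.0)})
        assert out.loc["x", "pct_reduction"] == 0.0
        assert out.loc["x", "ratio_patient_control"] == 1.0

    def test_mask_size_contrasts(self):
        out = relative_difference_summary(
            {"qsm_size": (277.7, 240.6), "smwi_low": (46.2, 83.2)})
        assert round(out.loc["qsm_size", "pct_reduction"]) == 13
        assert out.loc["smwi_low", "ratio_patient_control"] == pytest.approx(
            1.8, abs=0.05)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            relative_difference_summary({"x": (0.0, 1.0)})


def test_group_summary_table_shape_and_direction(default_tables):
    feats, _ = default_tables
    tab = group_summary_table(feats, ["qsm_chi_mean", "nm_contrast_range"])
    assert set(tab.direction) == {"higher", "lower"}
    assert ((tab.auc >= 0) & (tab.auc <= 1)).all()
    assert (tab.auc_ci_low <= tab.auc).all() and (tab.auc <= tab.auc_ci_high).all()
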