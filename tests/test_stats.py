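import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from perfconcord import stats


class TestInterpret:
    @pytest.mark.parametrize("value, band", [
        (0.668, "strong"), (0.672, "strong"), (0.770, "strong"),
        (0.818, "very strong"), (0.392, "weak"), (0.200, "weak"),
        (0.80, "very strong"), (0.15, "very weak"), (-0.65, "strong"),
    ])
    def test_correlation_bands(self, value, band):
        assert stats.interpret(value, "correlation") == band

    @pytest.mark.parametrize("value, band", [
        (0.8545, "excellent"), (0.9338, "excellent"), (0.7406, "good"),
        (0.7519, "good"), (0.80, "good"), (0.81, "excellent"),
        (0.50, "moderate"), (0.10, "poor"),
    ])
    def test_icc_bands(self, value, band):
        assert stats.interpret(value, "icc") == band

    @pytest.mark.parametrize("value, band", [
        (0.937, "outstanding"), (0.902, "outstanding"), (0.888, "excellent"),
        (0.874, "excellent"), (0.737, "acceptable"),
        (0.514, "none"), (0.90, "outstanding"), (0.80, "excellent"),
    ])
    def test_auc_bands(self, value, band):
        assert stats.interpret(value, "auc") == band

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            stats.interpret(1.2, "correlation")
        with pytest.raises(ValueError):
            stats.interpret(1.5, "auc")
        with pytest.raises(ValueError):
            stats.interpret(0.5, "bogus")


def exhaustive_spearman_p(x, y):
    """Brute-force permutation oracle for the two-sided Spearman p."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
            count += 1
    return count / total


class TestSpearman:
    def test_perfect_monotone(self):
        r = stats.spearman([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
        assert r.rho == pytest.approx(1.0)
        r = stats.spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r.rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        r = stats.spearman(x, y)
        assert r.p_two_sided == pytest.approx(exhaustive_spearman_p(x, y))

    def test_exact_p_with_ties(self):
        x = [1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 2.0, 4.0, 3.0, 6.0, 5.0]
        r = stats.spearman(x, y)
        assert r.p_two_sided == pytest.approx(exhaustive_spearman_p(x, y))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            stats.spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_large_n_t_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        r = stats.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert r.rho == pytest.approx(ref.statistic)
        assert r.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)


class TestMengZ:
    def test_equal_correlations_give_zero(self):
        c = stats.meng_z(0.5, 0.5, 0.3, 20)
        assert c.z == 0.0
        assert c.p_two_sided == pytest.approx(1.0)
        assert not c.significant

    def test_sign_antisymmetry(self):
        a = stats.meng_z(0.7, 0.4, 0.5, 25)
        b = stats.meng_z(0.4, 0.7, 0.5, 25)
        assert a.z == pytest.approx(-b.z)

    def test_formula_against_hand_computation(self):
        # Hand evaluation of the published formula chain.
        r_jh, r_kh, r_jk, n = 0.770, 0.697, 0.600, 10
        rbar2 = (r_jh**2 + r_kh**2) / 2
        fbar = min(1.0, (1 - r_jk) / (2 * (1 - rbar2)))
        h = (1 - fbar * rbar2) / (1 - rbar2)
        z_expect = (math.atanh(r_jh) - math.atanh(r_kh)) * math.sqrt(
            (n - 3) / (2 * (1 - r_jk) * h)
        )
        c = stats.meng_z(r_jh, r_kh, r_jk, n)
        assert c.z == pytest.approx(z_expect)

    def test_monotone_in_first_correlation(self):
        zs = [stats.meng_z(r, 0.4, 0.5, 30).z for r in (0.45, 0.6, 0.75)]
        assert zs[0] < zs[1] < zs[2]

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            stats.meng_z(1.0, 0.5, 0.3, 20)

    def test_type_one_error_quick(self, rng):
        """Null rejection rate near 5% (small Monte-Carlo; the full
        calibration lives in the acceptance suite)."""
        n, reps = 50, 3000
        cov = np.array([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]])
        L = np.linalg.cholesky(cov)
        rej = 0
        for _ in range(reps):
            x = rng.standard_normal((n, 3)) @ L.T
            r = np.corrcoef(x, rowvar=False)
            c = stats.meng_z(r[0, 2], r[1, 2], r[0, 1], n)
            rej += c.significant
        assert abs(rej / reps - 0.05) < 0.02


def hand_icc21(x):
    """Independent ICC(2,1) from explicit ANOVA sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
    mse = (((x - grand) ** 2).sum()
           - k * ((x.mean(1) - grand) ** 2).sum()
           - n * ((x.mean(0) - grand) ** 2).sum()) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_raters(self):
        x = np.column_stack([np.arange(8.0), np.arange(8.0)])
        r = stats.icc_two_way_random(x)
        assert r.icc == pytest.approx(1.0)
        assert r.band == "excellent"

    def test_independent_raters_near_zero(self, rng):
        x = rng.normal(size=(300, 2))
        r = stats.icc_two_way_random(x)
        assert abs(r.icc) < 0.15

    def test_toy_table_matches_anova_oracle(self):
        x = np.array([[9, 2], [1, 10], [8, 8], [2, 6], [7, 8], [8, 4.0]])
        r = stats.icc_two_way_random(x)
        assert r.icc == pytest.approx(hand_icc21(x))

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile([0, 1], 12),
            "score": x.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        mine = stats.icc_two_way_random(x)
        assert mine.icc == pytest.approx(row["ICC"], abs=1e-6)
        # pingouin prints the CI rounded to 2 decimals.
        assert mine.ci95[0] == pytest.approx(row[ci_col][0], abs=0.015)
        assert mine.ci95[1] == pytest.approx(row[ci_col][1], abs=0.015)

    def test_missing_cells_rejected(self):
        x = np.array([[1, 2], [3, np.nan], [4, 5], [6, 7], [8, 9.0]])
        with pytest.raises(ValueError, match="complete"):
            stats.icc_two_way_random(x)


def pair_count_auc(values, labels):
    """Exhaustive concordance-probability oracle (ties count half)."""
    pos = [v for v, l in zip(values, labels) if l == 1]
    neg = [v for v, l in zip(values, labels) if l == 0]
    score = 0.0
    for p in pos:
        for q in neg:
            score += 1.0 if p > q else (0.5 if p == q else 0.0)
    return score / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        r = stats.roc_analyze([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity + r.specificity - 1 == pytest.approx(1.0)
        assert r.band == "outstanding"

    def test_null_labels(self, rng):
        v = rng.normal(size=400)
        labels = rng.integers(0, 2, size=400)
        r = stats.roc_analyze(v, labels)
        assert abs(r.auc - 0.5) < 0.08

    def test_auc_matches_pair_count_oracle(self, rng):
        values = [3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8]
        labels = [0, 0, 0, 0, 0, 1, 0, 1, 1, 1, 1, 1]
        r = stats.roc_analyze(values, labels, direction="ge")
        assert r.auc == pytest.approx(pair_count_auc(values, labels))

    def test_monotone_transform_invariance(self, rng):
        v = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        r1 = stats.roc_analyze(v, labels)
        r2 = stats.roc_analyze(np.exp(2 * v), labels)
        assert r1.auc == pytest.approx(r2.auc)
        assert r1.sensitivity == pytest.approx(r2.sensitivity)

    def test_tumor_low_direction(self):
        # Tumor (label 1) has LOW values; 'le' orientation flips the scale.
        r = stats.roc_analyze([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0],
                              direction="le")
        assert r.auc == 1.0
        assert r.cutoff == 3

    def test_youden_tie_break_prefers_specificity(self):
        # Two cutoffs reach J = 0.5; the higher-specificity one wins.
        values = [1, 2, 3, 4, 5, 6, 7, 8]
        labels = [1, 1, 0, 1, 1, 0, 0, 0]
        r = stats.roc_analyze(values, labels, direction="le")
        best_j = r.sensitivity + r.specificity - 1
        for c in values:
            called = np.array(values) <= c
            sens = called[np.array(labels) == 1].mean()
            spec = (~called)[np.array(labels) == 0].mean()
            j = sens + spec - 1
            assert j < best_j + 1e-12 or spec <= r.specificity + 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stats.roc_analyze([1, 2, 3], [1, 1, 1])


class TestDelong:
    def test_self_comparison(self, rng):
        v = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        c = stats.delong_compare(v, v, labels)
        assert c.p_two_sided == 1.0
        assert c.auc_a == c.auc_b

    def test_variance_matches_jackknife(self, rng):
        n = 30
        labels = np.r_[np.ones(15, int), np.zeros(15, int)]
        base = np.r_[rng.normal(1, 1, 15), rng.normal(0, 1, 15)]
        a = base + rng.normal(0, 0.5, n)
        b = base + rng.normal(0, 0.5, n)
        c = stats.delong_compare(a, b, labels)
        d_obs = c.auc_a - c.auc_b
        if abs(c.z) > 1e-12:
            var_delong = (d_obs / c.z) ** 2
            # Leave-one-out jackknife of the AUC difference.
            deltas = []
            for i in range(n):
                m = np.ones(n, bool)
                m[i] = False
                ca = stats.roc_analyze(a[m], labels[m]).auc
                cb = stats.roc_analyze(b[m], labels[m]).auc
                deltas.append(ca - cb)
            deltas = np.array(deltas)
            var_jack = (n - 1) / n * ((deltas - deltas.mean()) ** 2).sum()
            assert var_delong == pytest.approx(var_jack, rel=0.25)

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            stats.delong_compare([1, 2, 3], [1, 2], [1, 0, 1])


def exhaustive_mannwhitney_p(x, y):
    """Enumerate all group assignments of the pooled ranks."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


class TestGroupTests:
    def test_wilcoxon_five_uniform_pairs(self):
        """Five uniformly signed paired differences give the smallest
        attainable exact two-sided p, 2/32 = 0.0625."""
        x = np.array([22.5, 21.0, 24.0, 23.0, 25.0])
        y = x - np.array([1.0, 2.0, 0.5, 3.0, 1.5])
        _, p = stats.wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(0.0625)

    def test_wilcoxon_degenerate(self):
        with pytest.raises(ValueError):
            stats.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_mann_whitney_identical_groups(self):
        _, p = stats.mann_whitney([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_mann_whitney_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(1.0, 1.0, size=4)
        _, p = stats.mann_whitney(x, y)
        assert p == pytest.approx(exhaustive_mannwhitney_p(x, y))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney([], [1.0])
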