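"""Agreement and association statistics against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hipscore import (
    AnglePair,
    UndefinedStatisticError,
    ValidationError,
    angle_agreement,
    anova_oneway,
    icc,
    pearson_r,
    ttest_independent,
)

# ---------------------------------------------------------------------------
# independent textbook-formula oracles (explicit loops, no shared code path)


def oracle_icc(Y, variant="absolute"):
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    grand = Y.mean()
    msr = k * sum((Y[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((Y[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (Y[i, j] - Y[i].mean() - Y[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    if variant == "absolute":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return (msr - mse) / (msr + (k - 1) * mse)


def oracle_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    cx, cy = x - x.mean(), y - y.mean()
    return float(np.sum(cx * cy) / np.sqrt(np.sum(cx**2) * np.sum(cy**2)))


def oracle_pooled_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b))))


def oracle_f(groups):
    allv = np.concatenate(groups)
    gm = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - gm) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    return float((ssb / (len(groups) - 1)) / (ssw / (len(allv) - len(groups))))


# ---------------------------------------------------------------------------


class TestICC:
    def test_fixed_fixture_matches_frozen_oracle_value(self):
        Y = [[3.0, 4.0], [2.0, 2.0], [5.0, 4.0], [4.0, 5.0]]
        assert icc(Y).icc == pytest.approx(0.7567567567567566, abs=1e-12)
        assert icc(Y, "consistency").icc == pytest.approx(0.7179487179487178, abs=1e-12)

    def test_identical_raters_give_perfect_agreement(self):
        col = np.array([2.0, 3.0, 5.0, 4.0])
        assert icc(np.column_stack([col, col])).icc == pytest.approx(1.0)

    def test_constant_offset_absolute_below_consistency(self):
        r1 = np.array([2.0, 3.0, 4.0, 5.0, 3.5])
        Y = np.column_stack([r1, r1 + 0.7])
        assert icc(Y, "absolute").icc < icc(Y, "consistency").icc
        assert icc(Y, "consistency").icc == pytest.approx(1.0)

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            n, k = rng.integers(3, 9), rng.integers(2, 5)
            Y = rng.normal(3, 1, size=(n, k)) + rng.normal(0, 1, size=(n, 1))
            for variant in ("absolute", "consistency"):
                assert icc(Y, variant).icc == pytest.approx(
                    oracle_icc(Y, variant), abs=1e-10
                )

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        r = np.random.default_rng(7)
        Y = r.normal(3, 1, size=(12, 2)) + r.normal(0, 1, size=(12, 1))
        long = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(12), 2),
                "rater": np.tile(["a", "b"], 12),
                "y": Y.ravel(),
            }
        )
        tab = pg.intraclass_corr(long, targets="subj", raters="rater", ratings="y")
        ref = dict(zip(tab["Type"], tab["ICC"]))
        assert icc(Y, "absolute").icc == pytest.approx(ref["ICC(A,1)"], abs=1e-6)
        assert icc(Y, "consistency").icc == pytest.approx(ref["ICC(C,1)"], abs=1e-6)

    def test_consistency_invariant_under_common_affine_transform(self, rng):
        Y = rng.normal(3, 1, size=(10, 3))
        a, b = 2.5, -1.0
        assert icc(a * Y + b, "consistency").icc == pytest.approx(
            icc(Y, "consistency").icc, abs=1e-10
        )

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc(np.full((4, 2), 3.0))

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValidationError):
            icc([[1.0, 2.0]])


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_fixture_matches_covariance_oracle(self):
        x = [1.0, 2.0, 4.0, 4.5, 6.0, 8.0]
        y = [2.1, 1.9, 3.5, 3.2, 5.0, 6.1]
        r, p = pearson_r(x, y)
        assert r == pytest.approx(0.9702400256824608, abs=1e-12)
        assert p == pytest.approx(0.0013153055561016583, rel=1e-9)
        assert r == pytest.approx(oracle_pearson(x, y), abs=1e-12)

    def test_affine_invariance_and_sign_flip(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        r0 = pearson_r(x, y)[0]
        assert pearson_r(3 * x + 2, y)[0] == pytest.approx(r0, abs=1e-12)
        assert pearson_r(-x, y)[0] == pytest.approx(-r0, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTTest:
    def test_identical_groups_give_t_zero_p_one(self):
        a = [3.0, 3.5, 2.8]
        t, p = ttest_independent(a, a)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fixture_matches_hand_formula(self):
        a = [3.1, 2.8, 3.4, 3.0, 2.9]
        b = [3.5, 3.6, 3.2, 3.8, 3.4]
        t, p = ttest_independent(a, b)
        assert t == pytest.approx(-3.204971865741441, abs=1e-12)
        assert p == pytest.approx(0.012518482603527574, rel=1e-9)
        assert t == pytest.approx(oracle_pooled_t(a, b), abs=1e-12)

    def test_far_separated_groups_tiny_p(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(10, 1, 50)
        assert ttest_independent(a, b)[1] < 1e-6

    def test_welch_flag_differs_under_unequal_variance(self, rng):
        a = rng.normal(0, 0.2, 8)
        b = rng.normal(1, 3.0, 40)
        assert ttest_independent(a, b)[0] != pytest.approx(
            ttest_independent(a, b, equal_var=False)[0]
        )

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            ttest_independent([1.0], [2.0, 3.0])


class TestANOVA:
    def test_identical_groups_give_f_zero(self):
        g = [1.0, 2.0, 3.0]
        assert anova_oneway([g, g, g])[0] == pytest.approx(0.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 10))
            b = rng.normal(0.5, 1, rng.integers(3, 10))
            f = anova_oneway([a, b])[0]
            t = ttest_independent(a, b)[0]
            assert f == pytest.approx(t**2, abs=1e-10)

    def test_three_group_fixture_matches_sum_of_squares_oracle(self):
        g = [[3.0, 3.2, 2.8], [3.5, 3.7, 3.4, 3.6], [2.5, 2.9, 2.7]]
        f, p = anova_oneway(g)
        assert f == pytest.approx(21.84999999999994, abs=1e-10)
        assert p == pytest.approx(0.0009779469180779415, rel=1e-9)
        assert f == pytest.approx(oracle_f([np.array(x) for x in g]), abs=1e-10)

    def test_random_fixtures_match_oracle(self, rng):
        for _ in range(100):
            groups = [rng.normal(0, 1, rng.integers(2, 8)) for _ in range(rng.integers(2, 5))]
            assert anova_oneway(groups)[0] == pytest.approx(oracle_f(groups), abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            anova_oneway([[1.0, 2.0]])


class TestAngles:
    def test_angle_pair_range_enforced(self):
        AnglePair(69.3, 46.8)
        with pytest.raises(ValidationError):
            AnglePair(-5.0, 46.8)

    def test_method_agreement_matches_plain_icc(self, rng):
        manual = rng.normal(69, 3.5, 15)
        ai = manual + rng.normal(0, 1.0, 15)
        beta_m = rng.normal(47, 2.2, 15)
        beta_a = beta_m + rng.normal(0, 1.5, 15)
        long = pd.DataFrame(
            {
                "case_id": np.repeat(np.arange(15), 2),
                "method": np.tile(["manual", "ai"], 15),
                "alpha_deg": np.column_stack([manual, ai]).ravel(),
                "beta_deg": np.column_stack([beta_m, beta_a]).ravel(),
            }
        )
        res = angle_agreement(long)
        assert res["alpha"].icc == pytest.approx(
            oracle_icc(np.column_stack([ai, manual])), abs=1e-10
        )
        assert res["beta"].icc == pytest.approx(
            oracle_icc(np.column_stack([beta_a, beta_m])), abs=1e-10
        )
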