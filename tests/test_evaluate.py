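import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from salispect.evaluate import (
    DegenerateInputError,
    bland_altman,
    compare_segmentations,
    dice,
    icc_two_way,
    mape,
    paired_t,
    r_squared,
)


class TestDice:
    def test_identical(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0], b[4] = True, True
        assert dice(a, b) == 0.0

    def test_formula(self):
        a = np.array([[1, 1, 0]], bool)
        b = np.array([[1, 0, 0]], bool)
        assert dice(a, b) == pytest.approx(2 / 3)

    def test_both_empty_reported_missing(self):
        z = np.zeros((3, 3), bool)
        assert dice(z, z) is None

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.random(200) > 0.6
        b = rng.random(200) > 0.6
        assert dice(a, b) == dice(b, a)
        perm = rng.permutation(200)
        assert dice(a[perm], b[perm]) == dice(a, b)


class TestMape:
    def test_arithmetic(self):
        mean, _ = mape([0.30, 0.20], [0.33, 0.18])
        assert mean == pytest.approx(10.0)

    def test_zero_for_equal(self):
        mean, sd = mape([1.0, 2.0], [1.0, 2.0])
        assert mean == 0.0 and sd == 0.0

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ref = rng.uniform(0.1, 1.0, 20)
            tst = ref + rng.normal(0, 0.05, 20)
            mean, sd = mape(ref, tst)
            ape = 100 * np.abs(tst - ref) / ref  # independent one-liner
            assert mean == pytest.approx(ape.mean(), abs=1e-12)
            assert sd == pytest.approx(ape.std(ddof=1), abs=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            mape([0.0, 1.0], [1.0, 1.0])


class TestBlandAltman:
    def test_equal_vectors(self):
        bias, lo, hi = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_symmetric_differences(self):
        bias, lo, hi = bland_altman([1.0, -1.0], [0.0, 0.0])
        assert bias == 0.0
        assert lo == pytest.approx(-hi)

    def test_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.normal(0, 1, 15)
            b = rng.normal(0, 1, 15)
            bias, lo, hi = bland_altman(a, b)
            d = a - b
            assert bias == pytest.approx(d.mean(), abs=1e-12)
            assert lo == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)
            assert hi == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)


class TestPairedT:
    def test_identical_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_swap_flips_sign(self):
        rng = np.random.default_rng(7)
        a = rng.normal(1, 1, 12)
        b = rng.normal(0, 1, 12)
        t1, p1 = paired_t(a, b)
        t2, p2 = paired_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_textbook_formula(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.5, 1, 10)
        b = rng.normal(0.0, 1, 10)
        t, p = paired_t(a, b)
        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_ref = 2 * stats.t.sf(abs(t_ref), len(d) - 1)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)


class TestRSquared:
    def test_perfect_linearity(self):
        a = np.arange(8.0)
        assert r_squared(a, 2 * a + 1) == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(13)
        assert r_squared(rng.normal(0, 1, 4000), rng.normal(0, 1, 4000)) < 0.01

    def test_covariance_formula_oracle(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 1, 8)
        b = 0.7 * a + rng.normal(0, 0.5, 8)
        cov = ((a - a.mean()) * (b - b.mean())).sum()
        r2_ref = cov ** 2 / (((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        assert r_squared(a, b) == pytest.approx(r2_ref, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPropertyInvariants:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=64),
           st.lists(st.booleans(), min_size=1, max_size=64))
    def test_dice_bounded_and_symmetric(self, a, b):
        n = max(len(a), len(b))
        p = np.resize(np.asarray(a, bool), n)
        t = np.resize(np.asarray(b, bool), n)
        d = dice(p, t)
        if d is None:
            assert not p.any() and not t.any()
        else:
            assert 0.0 <= d <= 1.0
            assert d == dice(t, p)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30),
           st.floats(-50, 50))
    def test_bland_altman_shift_moves_bias_only(self, vals, shift):
        a = np.asarray(vals)
        b = np.zeros_like(a)
        bias0, lo0, hi0 = bland_altman(a, b)
        bias1, lo1, hi1 = bland_altman(a + shift, b)
        assert bias1 == pytest.approx(bias0 + shift, abs=1e-9)
        assert hi1 - lo1 == pytest.approx(hi0 - lo0, abs=1e-9)


def _icc_anova_oracle(x):
    """Brute-force two-way ANOVA decomposition for ICC(A,1)."""
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_raters(self):
        x = np.column_stack([np.arange(6.0), np.arange(6.0)])
        assert icc_two_way(x).icc == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        base = np.arange(6.0)
        x = np.column_stack([base, base + 2.0])
        res = icc_two_way(x)
        assert res.icc < 1.0

    def test_anova_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(30):
            x = rng.normal(0, 1, (6, 2)) + rng.normal(0, 1, (6, 1))
            res = icc_two_way(x)
            assert res.icc == pytest.approx(_icc_anova_oracle(x), abs=1e-10)
            lo, hi = res.ci95
            assert lo <= res.icc <= hi

    def test_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(23)
        x = rng.normal(0, 1, (10, 3)) + rng.normal(0, 2, (10, 1))
        res = icc_two_way(x)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 3),
                "rater": np.tile(np.arange(3), 10),
                "score": x.ravel(),
            }
        )
        tab = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc2 = tab.set_index("Type").loc["ICC(A,1)"]
        assert res.icc == pytest.approx(float(icc2["ICC"]), abs=1e-8)
        lo, hi = icc2["CI95"]
        assert res.ci95[0] == pytest.approx(lo, abs=0.02)
        assert res.ci95[1] == pytest.approx(hi, abs=0.02)

    def test_constant_table_degenerate(self):
        with pytest.raises(DegenerateInputError):
            icc_two_way(np.ones((5, 2)))


class TestCompareSegmentations:
    def test_self_comparison(self, aligned_noiseless_study):
        rec = aligned_noiseless_study
        rep = compare_segmentations([rec], [rec.truth_labels], [rec.truth_labels])
        assert rep.dsc_mean == 1.0
        assert rep.mape_mean == 0.0
        assert rep.bias == 0.0
        assert rep.n == 4  # four glands present

    def test_row_bookkeeping(self, aligned_noiseless_study):
        rec = aligned_noiseless_study
        rep = compare_segmentations(
            [rec, rec], [rec.truth_labels] * 2, [rec.truth_labels] * 2
        )
        assert len(rep.per_gland) == 8

    def test_missing_source_rejected(self, aligned_noiseless_study):
        rec = aligned_noiseless_study
        with pytest.raises(ValueError):
            compare_segmentations([rec], [rec.truth_labels], [None])
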