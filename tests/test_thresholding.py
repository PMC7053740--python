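"""Class statistics, the relative-entropy criterion, and all five selectors."""

import numpy as np
import pytest
from _oracles import (
    brute_kapur_1d,
    brute_kapur_gllre,
    brute_otsu_1d,
    brute_otsu_gllre,
    brute_select_min_re,
    naive_class_stats,
    naive_criterion,
    random_histogram,
)

from gllre import (
    InvalidParameterError,
    NoThresholdError,
    PhantomSpec,
    apply_threshold,
    class_statistics,
    generate_phantom,
    gllre_histogram,
    kapur_1d,
    kapur_gllre,
    otsu_1d,
    otsu_gllre,
    relative_entropy_criterion,
    select_threshold_min_re,
)


def two_delta(L=256, cells=((50, 3, 0.5), (200, 4, 0.5))):
    p = np.zeros((L, L))
    for i, j, m in cells:
        p[i, j] = m
    return p


class TestClassStatistics:
    def test_all_mass_in_c0(self):
        p = np.zeros((16, 16))
        p[2, 3] = 1.0
        st = class_statistics(p, (5, 6))
        assert st.P0 == 1.0 and st.P1 == 0.0
        assert st.mu0 == (2.0, 3.0) and st.mu1 is None

    def test_uniform_strip_proportions(self):
        L, t = 16, 5
        p = np.full((L, L), 1.0 / (L * L))
        st = class_statistics(p, (4, t))
        assert st.P0 == pytest.approx(4 * t / (L * L))
        assert st.P1 == pytest.approx((L - 4) * t / (L * L))

    def test_matches_literal_double_sums(self, rng):
        for _ in range(10):
            p = random_histogram(rng, L=8)
            s, t = rng.integers(1, 8), rng.integers(1, 8)
            st = class_statistics(p, (s, t))
            P0, P1, mu0, mu1 = naive_class_stats(p, s, t)
            assert st.P0 == pytest.approx(P0, abs=1e-12)
            assert st.P1 == pytest.approx(P1, abs=1e-12)
            for got, want in ((st.mu0, mu0), (st.mu1, mu1)):
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want, abs=1e-12)

    def test_monotone_mass(self, rng):
        """P0 grows with s and t; P1 grows with t and shrinks with s."""
        p = random_histogram(rng, L=16, sparsity=0.9)
        for t in (3, 9, 15):
            P0s = [class_statistics(p, (s, t)).P0 for s in range(1, 16)]
            P1s = [class_statistics(p, (s, t)).P1 for s in range(1, 16)]
            assert np.all(np.diff(P0s) >= -1e-15)
            assert np.all(np.diff(P1s) <= 1e-15)
        for s in (3, 9, 15):
            P0t = [class_statistics(p, (s, t)).P0 for t in range(1, 16)]
            P1t = [class_statistics(p, (s, t)).P1 for t in range(1, 16)]
            assert np.all(np.diff(P0t) >= -1e-15)
            assert np.all(np.diff(P1t) >= -1e-15)

    @pytest.mark.parametrize("tv", [(0, 5), (5, 0), (16, 5), (5, 16), (-1, 3)])
    def test_out_of_range_thresholds_rejected(self, tv):
        with pytest.raises(InvalidParameterError):
            class_statistics(np.full((16, 16), 1 / 256), tv)


class TestRelativeEntropyCriterion:
    def test_point_classes_give_zero(self):
        """Each class concentrated at one cell: coordinates equal the class
        mean, every log ratio is log 1 = 0."""
        p = two_delta()
        cv = relative_entropy_criterion(p, (51, 5))
        assert cv.defined
        assert cv.D == pytest.approx(0.0, abs=1e-12)

    def test_empty_class_undefined(self):
        p = two_delta()
        cv = relative_entropy_criterion(p, (51, 4))  # t=4 excludes (200, 4)
        assert not cv.defined
        cv2 = relative_entropy_criterion(p, (30, 5))  # s=30 empties C0
        assert not cv2.defined

    def test_matches_literal_loop(self, rng):
        for _ in range(10):
            p = random_histogram(rng, L=16, sparsity=0.7)
            s, t = rng.integers(1, 16), rng.integers(1, 16)
            want = naive_criterion(p, s, t)
            cv = relative_entropy_criterion(p, (s, t))
            if want is None:
                assert not cv.defined
            else:
                assert cv.defined
                assert cv.D == pytest.approx(want, abs=1e-10)

    def test_finite_whenever_defined(self, rng):
        for _ in range(5):
            p = random_histogram(rng, L=16, sparsity=0.9)
            for s in range(1, 16, 3):
                for t in range(1, 16, 3):
                    cv = relative_entropy_criterion(p, (s, t))
                    if cv.defined:
                        assert np.isfinite(cv.D)


class TestSelectMinRE:
    def test_two_delta_lexicographic_minimum(self):
        """D = 0 on every separating (s, t); the smallest admissible one is
        s = 51 (first cut right of gray 50) and t = 5 (first cut that keeps
        LRE bin 4 inside the strip)."""
        tv = select_threshold_min_re(two_delta())
        assert tuple(tv) == (51, 5)
        assert tuple(tv) == brute_select_min_re(two_delta())

    def test_equals_brute_force_search(self, rng):
        for _ in range(10):
            p = random_histogram(rng, L=16)
            assert tuple(select_threshold_min_re(p)) == brute_select_min_re(p)

    def test_constant_image_has_no_threshold(self):
        h = gllre_histogram(np.full((8, 8), 9, dtype=int))
        with pytest.raises(NoThresholdError):
            select_threshold_min_re(h)

    def test_phantom_threshold_separates_modes(self):
        img, _ = generate_phantom(PhantomSpec(seed=3))
        tv = select_threshold_min_re(gllre_histogram(img))
        assert 60 < tv.s <= 180


class TestOtsu1D:
    def test_two_delta_tie_break(self):
        h = np.zeros(256)
        h[40], h[90] = 10, 30
        # every s in (40, 90] separates the deltas with identical variance
        assert otsu_1d(h) == 41 == brute_otsu_1d(h)

    def test_symmetric_bimodal_center(self):
        """Broad enough modes that the optimum is numerically unique; the
        threshold lands at the symmetry center up to rounding."""
        x = np.arange(256)
        h = np.exp(-((x - 80) ** 2) / 400) + np.exp(-((x - 160) ** 2) / 400)
        s = otsu_1d(h)
        assert abs(s - 120) <= 1
        assert s == brute_otsu_1d(h)

    def test_equals_brute_force(self, rng):
        for _ in range(20):
            h = rng.random(16) * (rng.random(16) < 0.6)
            if np.count_nonzero(h) < 2:
                continue
            assert otsu_1d(h) == brute_otsu_1d(h)

    def test_agrees_with_skimage(self, rng):
        """Cross-check against an independent library implementation: the
        foreground partition {i >= s} must match skimage's {i > thresh}."""
        from skimage.filters import threshold_otsu

        img = np.concatenate(
            [rng.normal(70, 10, 600), rng.normal(190, 12, 400)]
        ).clip(0, 255).round().astype(int)
        h = np.bincount(img, minlength=256)
        s = otsu_1d(h)
        t_sk = threshold_otsu(hist=(h, np.arange(256)))
        assert s == t_sk + 1

    def test_single_level_errors(self):
        h = np.zeros(256)
        h[7] = 5
        with pytest.raises(NoThresholdError):
            otsu_1d(h)


class TestKapur1D:
    def test_uniform_histogram_splits_in_half(self):
        """Equal-size classes maximize log s + log(L - s)."""
        assert kapur_1d(np.ones(16)) == 8
        assert brute_kapur_1d(np.ones(16)) == 8

    def test_two_delta_tie_break(self):
        h = np.zeros(64)
        h[10], h[50] = 1, 1
        # both class entropies are 0 for any separating s; smallest wins
        assert kapur_1d(h) == 11 == brute_kapur_1d(h)

    def test_equals_brute_force(self, rng):
        for _ in range(20):
            h = rng.random(16) * (rng.random(16) < 0.6)
            if np.count_nonzero(h) < 2:
                continue
            assert kapur_1d(h) == brute_kapur_1d(h)

    def test_single_level_errors(self):
        h = np.zeros(16)
        h[3] = 2
        with pytest.raises(NoThresholdError):
            kapur_1d(h)


class TestGLLRESelectors:
    def test_otsu_gllre_separates_two_deltas(self):
        s, t = otsu_gllre(two_delta())
        assert 50 < s <= 200 and t >= 5

    def test_kapur_gllre_separates_two_deltas(self):
        s, t = kapur_gllre(two_delta())
        assert 50 < s <= 200 and t >= 5

    @pytest.mark.parametrize(
        "fast,brute", [(otsu_gllre, brute_otsu_gllre), (kapur_gllre, brute_kapur_gllre)]
    )
    def test_equals_brute_force(self, rng, fast, brute):
        for _ in range(10):
            p = random_histogram(rng, L=16)
            assert tuple(fast(p)) == brute(p)

    @pytest.mark.parametrize("selector", [otsu_gllre, kapur_gllre])
    def test_single_column_mass_errors(self, selector):
        p = np.zeros((16, 16))
        p[7, 2] = 1.0
        with pytest.raises(NoThresholdError):
            selector(p)


class TestApplyThreshold:
    def test_strictly_below_is_foreground(self):
        img = np.full((3, 3), 10, dtype=int)
        assert np.all(apply_threshold(img, (11, 1)) == 1)
        assert np.all(apply_threshold(img, (10, 1)) == 0)  # I == s -> background

    def test_invert_flips_labels(self):
        img = np.arange(9).reshape(3, 3)
        m = apply_threshold(img, (5, 1))
        np.testing.assert_array_equal(apply_threshold(img, (5, 1), invert=True), 1 - m)

    def test_scalar_threshold_accepted(self):
        img = np.arange(9).reshape(3, 3)
        np.testing.assert_array_equal(apply_threshold(img, 5), apply_threshold(img, (5, 1)))
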