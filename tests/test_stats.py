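"""Statistics: constancy fits, ratios, ploidy peaks, Spearman, densitometry."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucquant import (
    DegenerateInputError,
    GeometryError,
    blot_volume,
    concentration_ratio,
    fit_constant_concentration,
    ploidy_peaks,
    spearman_bootstrap_ci,
    spearman_correlation,
)


class TestConstantConcentrationFit:
    def test_noiseless_line_through_origin(self):
        v = np.linspace(100, 400, 12)
        fit = fit_constant_concentration((v, 5.0 * v), seed=0)
        assert fit.slope == pytest.approx(5.0, rel=1e-12)
        assert fit.r2_through_origin == pytest.approx(1.0, abs=1e-12)
        assert fit.volume_concentration_spearman == 0.0

    def test_adversarial_quadratic_flagged(self):
        v = np.linspace(100, 400, 20)
        fit = fit_constant_concentration((v, 0.01 * v**2), seed=0)
        assert fit.volume_concentration_spearman > 0.99

    @given(c=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_slope_scale_equivariance(self, c):
        rng = np.random.default_rng(42)
        v = rng.uniform(100, 400, 30)
        t = 3.0 * v * rng.lognormal(0, 0.05, 30)
        base = fit_constant_concentration((v, t), n_boot=50, seed=0).slope
        assert fit_constant_concentration((v, c * t), n_boot=50, seed=0).slope == pytest.approx(
            c * base, rel=1e-9
        )
        assert fit_constant_concentration((c * v, t), n_boot=50, seed=0).slope == pytest.approx(
            base / c, rel=1e-9
        )

    def test_bootstrap_is_seed_reproducible_and_widens_at_small_n(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(100, 400, 100)
        t = 3.0 * v * rng.lognormal(0, 0.2, 100)
        widths = {}
        for n in (10, 30, 100):
            f1 = fit_constant_concentration((v[:n], t[:n]), seed=5)
            f2 = fit_constant_concentration((v[:n], t[:n]), seed=5)
            assert f1.slope_ci == f2.slope_ci
            widths[n] = f1.slope_ci[1] - f1.slope_ci[0]
        assert widths[10] > widths[30] > widths[100]

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_constant_concentration(([1, 2, 3], [1, 2, 3]))

    def test_equal_volumes_warns(self):
        with pytest.warns(UserWarning, match="volumes equal"):
            fit = fit_constant_concentration((np.full(6, 200.0), np.full(6, 600.0)))
        assert fit.volume_concentration_spearman is None
        assert fit.slope == pytest.approx(3.0)


class TestConcentrationRatio:
    def test_identical_groups(self):
        g = (np.full(5, 100.0), np.full(5, 300.0))
        r = concentration_ratio(g, g, seed=0)
        assert r.ratio == pytest.approx(1.0)
        assert r.ratio_ci == pytest.approx((1.0, 1.0))
        assert r.percent == pytest.approx(100.0)

    def test_swapping_groups_inverts_exactly(self):
        rng = np.random.default_rng(0)
        a = (rng.uniform(100, 200, 8), rng.uniform(100, 600, 8))
        b = (rng.uniform(100, 200, 8), rng.uniform(500, 3000, 8))
        r_ab = concentration_ratio(a, b, seed=1)
        r_ba = concentration_ratio(b, a, seed=1)
        assert r_ab.ratio == pytest.approx(1.0 / r_ba.ratio, rel=1e-12)
        assert r_ab.inverse == pytest.approx(r_ba.ratio, rel=1e-12)

    def test_small_groups_raise(self):
        g = (np.full(2, 1.0), np.full(2, 1.0))
        with pytest.raises(ValueError):
            concentration_ratio(g, g)


class TestPloidyPeaks:
    def test_exact_two_populations(self):
        totals = np.r_[np.full(100, 1.0), np.full(60, 2.0)]
        rng = np.random.default_rng(0)
        totals = totals * rng.normal(1, 0.01, totals.size)
        p = ploidy_peaks(totals, seed=0)
        assert p.peak_positions[0] == 1.0
        assert p.second_peak == pytest.approx(2.0, abs=0.05)

    def test_scale_invariance_of_normalized_peaks(self):
        rng = np.random.default_rng(1)
        totals = np.r_[rng.normal(300, 10, 150), rng.normal(600, 20, 80)]
        a = ploidy_peaks(totals, seed=0)
        b = ploidy_peaks(totals * 37.5, seed=0)
        assert np.allclose(a.peak_positions, b.peak_positions, atol=0.02)

    def test_normalization_idempotent(self):
        rng = np.random.default_rng(2)
        totals = np.r_[rng.normal(300, 10, 150), rng.normal(600, 20, 80)]
        once = ploidy_peaks(totals, seed=0)
        # feeding back data already on the normalized scale is a no-op
        again = ploidy_peaks(totals / once.raw_peak_positions[0], seed=0)
        assert np.allclose(once.peak_positions, again.peak_positions, atol=0.02)

    def test_single_population_warns(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="single population"):
            p = ploidy_peaks(rng.normal(300, 10, 200), seed=0)
        assert p.second_peak is None

    def test_small_sample_warns(self):
        rng = np.random.default_rng(4)
        totals = np.r_[rng.normal(300, 5, 20), rng.normal(600, 10, 20)]
        with pytest.warns(UserWarning, match="recommended"):
            ploidy_peaks(totals, seed=0)


def _rho_oracle(x, y):
    """Brute-force Spearman: mid-ranks by counting, then Pearson of ranks."""
    def midranks(a):
        a = np.asarray(a, dtype=float)
        out = np.empty(a.size)
        for i, v in enumerate(a):
            less = np.sum(a < v)
            eq = np.sum(a == v)
            out[i] = less + (eq + 1) / 2.0
        return out

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_strictly_increasing_is_one(self):
        r = spearman_correlation([1, 2, 3, 4], [10, 20, 25, 70])
        assert r.rho == 1.0

    def test_hand_computed_example(self):
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4: rho = 1 - 6*4/(5*24) = 0.8
        r = spearman_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r.rho == pytest.approx(0.8, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_matches_rank_oracle_with_and_without_ties(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            x = rng.integers(0, max(2, n - 1), n).astype(float)  # forces ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            r = spearman_correlation(x, y)
            assert r.rho == pytest.approx(_rho_oracle(x, y), abs=1e-12)
            assert r.method == "exact-permutation"

    def test_exact_p_matches_enumeration_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0])
        r = spearman_correlation(x, y)
        hits = total = 0
        for perm in itertools.permutations(y):
            total += 1
            if abs(_rho_oracle(x, perm)) >= abs(r.rho) - 1e-12:
                hits += 1
        assert r.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        y = x + rng.normal(0, 0.5, 30)
        base = spearman_correlation(x, y).rho
        assert spearman_correlation(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman_correlation(x, y**3).rho == pytest.approx(base, abs=1e-12)

    def test_constant_variable_raises(self):
        with pytest.raises(DegenerateInputError):
            spearman_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_bootstrap_ci_seeded(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=40)
        y = x + rng.normal(0, 1.0, 40)
        assert spearman_bootstrap_ci(x, y, seed=3) == spearman_bootstrap_ci(x, y, seed=3)


class TestDensitometry:
    def test_uniform_image_volume_is_zero(self):
        img = np.full((50, 80), 137.0)
        res = blot_volume(img, {"a": (10, 10, 12, 20)})
        assert res.lane_volumes["a"] == 0.0

    def test_synthetic_band_exact(self):
        img = np.full((60, 90), 20.0)
        img[20:30, 10:40] = 120.0  # band of +100 over background
        res = blot_volume(img, {"a": (18, 8, 14, 36)})
        assert res.lane_volumes["a"] == pytest.approx(100.0 * 300, rel=1e-12)

    def test_fold_change_recovery_with_noise(self):
        rng = np.random.default_rng(0)
        img = rng.normal(50.0, 1.0, (80, 160))
        img[20:30, 20:50] += 200.0  # reference band
        img[20:30, 90:120] += 320.0  # 1.6x band
        img[55:65, 20:50] += 150.0  # equal loading controls
        img[55:65, 90:120] += 150.0
        res = blot_volume(
            img,
            {"ref": (18, 16, 14, 38), "stim": (18, 86, 14, 38)},
            loading_rectangles={"ref": (53, 16, 14, 38), "stim": (53, 86, 14, 38)},
            reference="ref",
        )
        assert res.fold_change["ref"] == 1.0
        assert res.fold_change["stim"] == pytest.approx(1.6, rel=0.02)

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.normal(40.0, 1.0, (60, 80))
        img[20:30, 20:50] += 100.0
        rects = {"a": (18, 18, 14, 34)}
        a = blot_volume(img, rects)
        b = blot_volume(img + 500.0, rects)
        assert a.lane_volumes["a"] == pytest.approx(b.lane_volumes["a"], rel=1e-9)

    def test_frame_outside_image_raises(self):
        img = np.zeros((20, 20))
        with pytest.raises(GeometryError, match="frame"):
            blot_volume(img, {"a": (0, 5, 5, 5)})

    def test_overlapping_rectangles_raise(self):
        img = np.zeros((40, 40))
        with pytest.raises(GeometryError, match="overlaps"):
            blot_volume(img, {"a": (10, 10, 10, 10), "b": (15, 15, 10, 10)})
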