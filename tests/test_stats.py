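"""Freezing-by-speed estimation, deceleration fits and the randomization test."""

import math

import numpy as np
import pytest

import loomassay as la
from loomassay.ethogram import TrialResponse
from loomassay.stats import (
    fit_deceleration,
    freeze_prob_by_speed,
    pdf_hist,
    randomization_test_c,
    rank_sum_test,
    chi2_proportions,
    kruskal_wallis,
    response_fractions_timecourse,
    walking_speed_delta,
)


def make_trial(speed, response, pre_state="walk", index=0):
    return TrialResponse(
        looming_index=index, onset_s=0.0, pre_speed_mm_s=speed,
        pre_state=pre_state, post_state="freeze" if response == "freeze" else "walk",
        response=response, paused=False, pause_onset_s=None,
        orientation_pre_deg=float("nan"), orientation_post_deg=float("nan"),
    )


def wilson_interval(k, n, z=1.959963984540054):
    """Closed-form Wilson score interval (independent of statsmodels)."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


class TestFreezeProbBySpeed:
    def test_all_freeze_gives_p_one(self):
        trials = [make_trial(s, "freeze") for s in [1.0, 3.0, 5.0, 9.0, 9.5]]
        fbs = freeze_prob_by_speed(trials)
        assert np.all(fbs.p_freeze == 1.0)
        assert fbs.n_trials.sum() == 5

    def test_single_trial_wilson_interval(self):
        fbs = freeze_prob_by_speed([make_trial(1.0, "freeze")])
        lo, hi = wilson_interval(1, 1)
        assert fbs.ci_low[0] == pytest.approx(lo, abs=1e-9)
        assert fbs.ci_high[0] == pytest.approx(hi, abs=1e-9)

    def test_pre_freezing_trials_excluded(self):
        trials = [make_trial(1.0, "freeze"), make_trial(1.0, "freeze", "freeze")]
        fbs = freeze_prob_by_speed(trials)
        assert fbs.n_trials.sum() == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        trials = [
            make_trial(rng.uniform(0, 20), rng.choice(["freeze", "flee_no_pause"]))
            for _ in range(200)
        ]
        a = freeze_prob_by_speed(trials)
        b = freeze_prob_by_speed(trials[::-1])
        np.testing.assert_array_equal(a.p_freeze, b.p_freeze)
        np.testing.assert_array_equal(a.n_trials, b.n_trials)

    def test_merged_bins_pool_between_originals(self):
        rng = np.random.default_rng(1)
        trials = [
            make_trial(rng.uniform(0, 4), "freeze" if rng.random() < 0.5 else "none")
            for _ in range(400)
        ]
        fine = freeze_prob_by_speed(trials, bin_edges=[0, 2, 4])
        coarse = freeze_prob_by_speed(trials, bin_edges=[0, 4])
        lo, hi = sorted(fine.p_freeze)
        assert lo - 1e-12 <= coarse.p_freeze[0] <= hi + 1e-12

    def test_empty_bins_omitted(self):
        fbs = freeze_prob_by_speed(
            [make_trial(1.0, "freeze")], bin_edges=[0, 2, 4, 6]
        )
        assert len(fbs.p_freeze) == 1
        assert fbs.bin_low[0] == 0.0


class TestFitDeceleration:
    def test_noiseless_recovery(self):
        x = np.linspace(0, 1, 60)
        y = 2.0 ** (-8.0 * x - 3.0) + 1.0
        fit = fit_deceleration(x, y, base=2.0)
        assert fit.success
        assert abs(fit.b + 8.0) / 8.0 < 1e-3
        assert abs(fit.c - 3.0) / 3.0 < 1e-3
        assert abs(fit.d - 1.0) < 1e-3
        assert fit.residual < 1e-6

    def test_constant_trace_degenerate(self):
        x = np.linspace(0, 1, 50)
        fit = fit_deceleration(x, np.full(50, 5.0))
        assert fit.residual == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fit.predict(x), 5.0)

    def test_c_recovery_under_noise(self):
        x = np.linspace(0, 1, 60)
        y = 2.0 ** (-8.0 * x - 3.0) + 1.0
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(100):
            noisy = y + 0.05 * np.ptp(y) * rng.normal(size=60)
            fit = fit_deceleration(x, noisy, base=2.0)
            errs.append(abs(fit.c - 3.0))
        assert np.mean(errs) < 0.1

    def test_time_translation_shifts_c_predictably(self):
        x = np.linspace(0, 1, 60)
        y = np.exp(-5.0 * x + 1.0) + 2.0
        f0 = fit_deceleration(x, y)
        f1 = fit_deceleration(x + 0.4, y)
        # f(x + delta): b stays, c shifts by b * delta
        assert f1.b == pytest.approx(f0.b, rel=1e-6)
        assert f1.c == pytest.approx(f0.c + f0.b * 0.4, rel=1e-6)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fit_deceleration([0, 1, 2], [1, 2, 3])  # too short
        with pytest.raises(ValueError):
            fit_deceleration(np.arange(5.0), np.array([1, 2, np.nan, 4, 5]))


def decel_trace(c, n_trials, rng, n_t=40, noise=0.4):
    """Sigmoid-shaped deceleration traces with onset near time c."""
    x = np.linspace(0, 1, n_t)
    mean = 8.0 / (1.0 + np.exp(-(x - c) * 12.0)) + 2.0
    return x, mean[None, :] + noise * rng.normal(size=(n_trials, n_t))


class TestRandomizationTest:
    def test_identical_groups_p_one(self):
        x = np.linspace(0, 1, 40)
        y = np.exp(-6.0 * x + 1.0) + 2.0
        group = np.tile(y, (8, 1))
        res = randomization_test_c(group, group.copy(), x, n_shuffles=200, seed=0)
        assert res.observed == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == 1.0

    def test_seed_reproducible_and_in_unit_interval(self):
        rng = np.random.default_rng(3)
        x, a = decel_trace(0.35, 10, rng)
        _, b = decel_trace(0.40, 10, rng)
        r1 = randomization_test_c(a, b, x, n_shuffles=300, seed=42)
        r2 = randomization_test_c(a, b, x, n_shuffles=300, seed=42)
        assert r1.p_value == r2.p_value
        assert 0.0 < r1.p_value <= 1.0

    def test_group_order_invariance(self):
        rng = np.random.default_rng(4)
        x, a = decel_trace(0.3, 9, rng)
        _, b = decel_trace(0.5, 12, rng)
        r_ab = randomization_test_c(a, b, x, n_shuffles=300, seed=7)
        r_ba = randomization_test_c(b, a, x, n_shuffles=300, seed=7)
        assert r_ab.p_value == r_ba.p_value
        assert r_ab.observed == pytest.approx(r_ba.observed)

    def test_power_on_large_offset(self):
        rng = np.random.default_rng(5)
        x, a = decel_trace(0.25, 15, rng, noise=0.15)
        _, b = decel_trace(0.60, 15, rng, noise=0.15)
        res = randomization_test_c(a, b, x, n_shuffles=500, seed=1)
        assert res.p_value <= 0.01

    def test_empty_group_rejected(self):
        x = np.linspace(0, 1, 40)
        with pytest.raises(ValueError):
            randomization_test_c(np.empty((0, 40)), np.ones((3, 40)), x)


class TestWalkingSpeedDelta:
    def _etho_binned(self, labels, speeds):
        labels = np.asarray(labels, dtype="<U6")
        starts = np.arange(len(labels)) * 0.5
        etho = la.Ethogram(starts, labels, np.array([]), 0.5)
        from loomassay.ethogram import BinnedActivity

        binned = BinnedActivity(starts, np.asarray(speeds, float),
                                np.zeros(len(labels)), 0.5)
        return etho, binned

    def test_identical_windows_zero(self):
        etho, binned = self._etho_binned(["walk"] * 8, [8.0] * 8)
        assert walking_speed_delta(etho, binned, (0, 2), (2, 4)) == 0.0

    def test_simple_difference(self):
        etho, binned = self._etho_binned(
            ["walk", "walk", "groom", "walk", "walk", "freeze"],
            [8.0, 8.0, 1.0, 9.5, 9.5, 0.0],
        )
        delta = walking_speed_delta(etho, binned, (0.0, 1.5), (1.5, 3.0))
        assert delta == pytest.approx(1.5)

    def test_freezing_only_window_excluded(self):
        etho, binned = self._etho_binned(
            ["walk", "walk", "freeze", "freeze"], [8.0, 8.0, 0.0, 0.0]
        )
        assert walking_speed_delta(etho, binned, (0, 1), (1, 2)) is None


class TestResponseFractions:
    def test_fractions_sum_to_one_and_pinned_values(self):
        trials = (
            [make_trial(5.0, "freeze", index=2)] * 3
            + [make_trial(5.0, "jump", index=2)]
            + [make_trial(5.0, "flee_pause", index=1)] * 4
        )
        frac = response_fractions_timecourse(trials)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0)
        assert frac.loc[2, "freeze"] == pytest.approx(0.75)
        assert frac.loc[1, "flee_pause"] == 1.0

    def test_rising_freeze_hazard_trend(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(6)
        trials = []
        for idx in range(20):
            p = 0.05 + 0.04 * idx
            for _ in range(40):
                trials.append(
                    make_trial(
                        5.0,
                        "freeze" if rng.random() < p else "flee_no_pause",
                        index=idx,
                    )
                )
        frac = response_fractions_timecourse(trials)
        rho, _ = spearmanr(frac.index, frac["freeze"])
        assert rho > 0


class TestPdfHist:
    def test_integral_is_one(self):
        rng = np.random.default_rng(7)
        values = rng.normal(5, 2, size=500)
        edges = np.linspace(-2, 12, 15)
        dens = pdf_hist(values, edges)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_law_of_large_numbers(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 10, size=100_000)
        dens = pdf_hist(values, np.linspace(0, 10, 11))
        np.testing.assert_allclose(dens, 0.1, rtol=0.05)

    def test_single_value(self):
        dens = pdf_hist([3.0], [2.0, 4.0])
        assert dens[0] == pytest.approx(0.5)  # 1 / width

    def test_all_values_outside_range(self):
        with pytest.raises(ValueError):
            pdf_hist([100.0], [0.0, 1.0])


def test_delegated_tests_smoke():
    rng = np.random.default_rng(9)
    a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
    assert rank_sum_test(a, b).pvalue < 0.05
    res = chi2_proportions([40, 10], [50, 50])
    assert res.pvalue < 0.001
    assert kruskal_wallis(a, b, a + 3.0).pvalue < 0.001
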