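"""Delta-percent statistics, t-tests, CFU ratios, clearance and growth fits."""

import math

import numpy as np
import pytest

from barcodeq.competition import (
    CFUSeries,
    clearance_rate,
    competition_ratio,
    competition_table,
    delta_percent,
    growth_rate,
    ratio_fold_change,
    recovery_fold_change,
    relative_adhesion,
    summarize_replicates,
    unpaired_t_test,
)
from barcodeq.demux import SampleCounts
from barcodeq.simulate import SimConfig, gen_cfu_series


def _sample(counts, sid="s"):
    sc = SampleCounts(sample_id=sid)
    sc.counts = dict(counts)
    return sc


class TestDeltaPercent:
    def test_identical_samples_zero_delta(self):
        t0 = _sample({"a": 30, "b": 30, "c": 40})
        assert delta_percent(t0, t0)["delta_percent"].abs().max() == 0.0

    def test_simple_shift(self):
        t0 = _sample({"a": 30, "b": 30, "c": 40})
        tf = _sample({"a": 25, "b": 35, "c": 40})
        d = delta_percent(t0, tf).set_index("strain")["delta_percent"]
        assert d["a"] == pytest.approx(-5.0)
        assert d["b"] == pytest.approx(5.0)
        assert d["c"] == pytest.approx(0.0)

    def test_zero_sum_and_depth_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c0 = {f"s{i}": int(n) for i, n in enumerate(rng.integers(1, 500, 6))}
            cf = {f"s{i}": int(n) for i, n in enumerate(rng.integers(1, 500, 6))}
            d1 = delta_percent(_sample(c0), _sample(cf))
            assert d1["delta_percent"].sum() == pytest.approx(0.0, abs=1e-9)
            scaled = {k: v * 7 for k, v in cf.items()}
            d2 = delta_percent(_sample(c0), _sample(scaled))
            assert np.allclose(d1["delta_percent"], d2["delta_percent"])

    def test_disjoint_whitelists_rejected(self):
        with pytest.raises(ValueError):
            delta_percent(_sample({"a": 10}), _sample({"b": 10}))


class TestReplicateSummaries:
    def test_mean_and_sem(self):
        mean, sem = summarize_replicates([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(1.0 / math.sqrt(3))

    def test_constant_replicates(self):
        assert summarize_replicates([4.0, 4.0, 4.0])[1] == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            summarize_replicates([1.0])


def _welch_oracle(a, b):
    """Textbook Welch t-test, independent of the implementation path."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


class TestUnpairedTTest:
    def test_identical_groups(self):
        t, _, p = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        a = [0.0, 0.001, -0.001]
        b = [1.0, 1.001, 0.999]
        _, _, p = unpaired_t_test(a, b)
        assert p < 0.01

    def test_symmetry(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        ta, _, pa = unpaired_t_test(a, b)
        tb, _, pb = unpaired_t_test(b, a)
        assert ta == pytest.approx(-tb)
        assert pa == pytest.approx(pb)

    def test_matches_textbook_welch(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.normal(0, 1, int(rng.integers(3, 12)))
            b = rng.normal(0.5, 2, int(rng.integers(3, 12)))
            got = unpaired_t_test(a, b)
            want = _welch_oracle(a, b)
            assert got[0] == pytest.approx(want[0], abs=1e-10)
            assert got[1] == pytest.approx(want[1], abs=1e-10)
            assert got[2] == pytest.approx(want[2], abs=1e-10)

    def test_degenerate_equal_groups_convention(self):
        t, _, p = unpaired_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_test([1.0], [1.0, 2.0])


class TestCompetitionTable:
    def test_flags_only_negative_significant_strains(self):
        washed = {"hit": [-2.4, -2.6, -2.5], "null": [0.1, -0.1, 0.0]}
        unwashed = {"hit": [0.0, 0.1, -0.1], "null": [0.05, -0.05, 0.0]}
        tab = competition_table(washed, unwashed).set_index("strain")
        assert bool(tab.loc["hit", "reduced_adhesion"])
        assert not bool(tab.loc["null", "reduced_adhesion"])

    def test_bh_column_monotone(self):
        washed = {f"s{i}": list(np.random.default_rng(i).normal(0, 1, 4)) for i in range(5)}
        unwashed = {f"s{i}": list(np.random.default_rng(i + 99).normal(0, 1, 4)) for i in range(5)}
        tab = competition_table(washed, unwashed, adjust=True)
        assert (tab["p_bh"] >= tab["p_value"] - 1e-12).all()


class TestCFUArithmetic:
    def test_relative_adhesion(self):
        percent, rel = relative_adhesion(1e6, 2e4, control_percent=2.0)
        assert percent == pytest.approx(2.0)
        assert rel == pytest.approx(100.0)

    def test_relative_adhesion_half_of_control(self):
        _, rel = relative_adhesion(1e6, 1e4, control_percent=2.0)
        assert rel == pytest.approx(50.0)

    def test_over_recovery_warns(self):
        with pytest.warns(UserWarning):
            relative_adhesion(100, 150, control_percent=10.0)

    def test_competition_ratio(self):
        assert competition_ratio(1.2e5, 1.0e5) == pytest.approx(5.0)
        assert competition_ratio(100, 50) == pytest.approx(1.0)

    def test_marker_equals_total_is_infinite(self):
        with pytest.warns(UserWarning):
            assert competition_ratio(100, 100) == float("inf")

    def test_marker_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            competition_ratio(100, 101)

    def test_ratio_fold_change(self):
        assert ratio_fold_change(5.0, 1.0) == pytest.approx(5.0)

    def test_recovery_fold_change_published_inputs(self):
        # 6/100 patch-positive vs 1.25% direct efficiency -> ~5-fold
        fold, rounded = recovery_fold_change(0.06, 0.0125)
        assert fold == pytest.approx(4.8)
        assert rounded == 5

    def test_recovery_fold_change_equal_inputs(self):
        assert recovery_fold_change(0.01, 0.01)[0] == pytest.approx(1.0)

    def test_recovery_fold_change_zero_rejected(self):
        with pytest.raises(ValueError):
            recovery_fold_change(0.06, 0.0)


class TestClearanceRate:
    def test_noiseless_line_exact(self):
        days = np.arange(6.0)
        cfu = 10 ** (8.0 - 1.2 * days)
        fit = clearance_rate(days, cfu)
        assert fit.clearance_rate == pytest.approx(1.2)
        assert fit.slope == pytest.approx(-1.2)

    def test_flat_series_zero_rate(self):
        fit = clearance_rate(np.arange(6.0), np.full(6, 1e5))
        assert fit.clearance_rate == pytest.approx(0.0)

    def test_window_restricts_fit(self):
        days = np.arange(8.0)
        cfu = 10 ** (8.0 - 1.0 * days)
        cfu[6:] = 1e9  # garbage outside the 0-5 day window
        fit = clearance_rate(days, cfu, window=(0, 5))
        assert fit.clearance_rate == pytest.approx(1.0)
        assert fit.n_points == 6

    def test_trailing_censored_days_excluded(self):
        days = np.arange(6.0)
        cfu = 10 ** (5.0 - 1.0 * days)  # days 4 and 5 fall below LOD of 100
        fit = clearance_rate(days, cfu, detection_limit=100.0)
        assert fit.n_points == 4
        assert fit.clearance_rate == pytest.approx(1.0)

    def test_interior_censored_point_substituted(self):
        days = np.arange(5.0)
        cfu = np.array([1e6, 1e5, 50.0, 1e3, 1e2])
        fit = clearance_rate(days, cfu, detection_limit=100.0, lod_policy="half_lod")
        assert fit.n_points == 5  # interior censored day kept at LOD/2

    def test_recovers_generating_slope_on_noisy_series(self):
        cfg = SimConfig(seed=123, clearance_slope=0.8, clearance_noise_sd=0.2)
        series, _ = gen_cfu_series(cfg)
        rates = [s.fit_clearance().clearance_rate for s in series]
        assert abs(np.mean(rates) - 0.8) < 0.1

    def test_two_groups_distinguished(self):
        # fast- vs slow-clearing groups separate by Welch test on fitted rates
        fast, _ = gen_cfu_series(SimConfig(seed=5, clearance_slope=1.4))
        slow, _ = gen_cfu_series(SimConfig(seed=6, clearance_slope=0.8))
        _, _, p = unpaired_t_test(
            [s.fit_clearance().clearance_rate for s in fast],
            [s.fit_clearance().clearance_rate for s in slow],
        )
        assert p < 0.05

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            clearance_rate([0.0], [1e5])


class TestGrowthRate:
    def test_doubling_every_hour(self):
        t = np.arange(0, 6, 0.5)
        od = 0.05 * 2**t
        assert growth_rate(t, od).rate == pytest.approx(1.0)

    def test_doubling_every_30_min(self):
        t = np.arange(0, 3, 0.25)
        od = 0.05 * 2 ** (2 * t)
        assert growth_rate(t, od).rate == pytest.approx(2.0)

    def test_nonpositive_od_rejected(self):
        with pytest.raises(ValueError):
            growth_rate([0.0, 1.0, 2.0], [0.0, 0.1, 0.2])

    def test_logistic_curve_exponential_window(self):
        from barcodeq.simulate import gen_growth_curves

        cfg = SimConfig(seed=3, growth_rate=1.0)
        curves, _ = gen_growth_curves(cfg, n_curves=5)
        for c in curves:
            fit = c.fit_rate(window=(1.5, 4.0))
            assert fit.rate == pytest.approx(1.0, rel=0.05)
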