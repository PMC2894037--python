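import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tumorboost as tb
from tumorboost.evaluation import (
    InsufficientDataError,
    RegionSignal,
    UndefinedStatisticError,
    extract_flanking_signals,
    balanced_sample,
)


def _spec(margin=1000):
    return tb.ChangePointSpec(
        "X", "1", 1, 100_000, 50_000, margin, tb.PcnState(1, 1), tb.PcnState(0, 2)
    )


def _track(n=100, seed=0):
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(np.arange(1, 100_001), size=n, replace=False))
    values = rng.normal(size=n)
    calls = tb.GenotypeCallSet(np.full(n, 0.5), np.ones(n), (0.25, 0.75))
    return values, positions, calls


class TestFlankExtraction:
    def test_safety_region_excluded(self):
        values = np.zeros(100)
        positions = np.arange(1, 101) * 1000  # 1k..100k
        calls = tb.GenotypeCallSet(np.full(100, 0.5), np.ones(100), (0.25, 0.75))
        spec = _spec(margin=5000)  # covers positions 45k..55k inclusive -> 11 SNPs
        r1, r2, n_exc = extract_flanking_signals(values, positions, calls, spec)
        assert n_exc == 11
        assert len(r1) + len(r2) + n_exc == 100

    def test_zero_margin_excludes_nothing(self):
        values, positions, calls = _track()
        spec = _spec(margin=0)
        r1, r2, n_exc = extract_flanking_signals(values, positions, calls, spec)
        assert n_exc == int((positions == 50_000).sum())
        assert len(r1) + len(r2) == len(values) - n_exc

    def test_het_only_on_all_hom_region_raises(self):
        values, positions, _ = _track()
        calls = tb.GenotypeCallSet(np.zeros(len(values)), np.ones(len(values)), (0.25, 0.75))
        with pytest.raises(InsufficientDataError):
            extract_flanking_signals(values, positions, calls, _spec())


class TestBalancedSample:
    def test_sizes(self):
        r1 = RegionSignal(np.arange(300.0), np.arange(300), 1)
        r2 = RegionSignal(np.arange(500.0), np.arange(500), 2)
        x, y = balanced_sample(r1, r2, 250, rng=0)
        assert len(x) == len(y) == 250

    def test_same_seed_identical_different_seed_not(self):
        r1 = RegionSignal(np.arange(300.0), np.arange(300), 1)
        r2 = RegionSignal(np.arange(500.0), np.arange(500), 2)
        x1, y1 = balanced_sample(r1, r2, 250, rng=5)
        x2, y2 = balanced_sample(r1, r2, 250, rng=5)
        x3, _ = balanced_sample(r1, r2, 250, rng=6)
        assert np.array_equal(x1, x2) and np.array_equal(y1, y2)
        assert not np.array_equal(x1, x3)

    def test_oversampling_rejected(self):
        r1 = RegionSignal(np.arange(10.0), np.arange(10), 1)
        with pytest.raises(InsufficientDataError):
            balanced_sample(r1, r1, 11, rng=0)


class TestTStatistic:
    def test_equal_means_give_zero(self):
        x = np.array([0.0, 1.0] * 10)
        assert tb.t_statistic(x, x) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 50), rng.normal(1, 1, 50)
        assert tb.t_statistic(x, y) == pytest.approx(-tb.t_statistic(y, x))

    def test_matches_scipy_pooled_and_welch(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 40), rng.normal(0.5, 2, 60)
        assert tb.t_statistic(x, y) == pytest.approx(stats.ttest_ind(x, y).statistic)
        assert tb.t_statistic(x, y, welch=True) == pytest.approx(
            stats.ttest_ind(x, y, equal_var=False).statistic
        )

    def test_expected_magnitude_under_unit_shift(self):
        """For N(0,1) vs N(1,1) with n per group, |t| concentrates near
        sqrt(n/2)."""
        rng = np.random.default_rng(2)
        n = 250
        t = tb.t_statistic(rng.normal(0, 1, n), rng.normal(1, 1, n))
        assert abs(abs(t) - np.sqrt(n / 2)) < 3 * 1.1  # ~3 sd of a noncentral t

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            tb.t_statistic(np.ones(5), np.ones(5))


class TestBootstrapT:
    def _null_regions(self, n=400, seed=3):
        rng = np.random.default_rng(seed)
        return (
            RegionSignal(rng.normal(size=n), np.arange(n), 1),
            RegionSignal(rng.normal(size=n), np.arange(n), 2),
        )

    def test_null_level(self):
        """Two regions from one distribution give mean |t| near E|t| ~ 0.8."""
        r1, r2 = self._null_regions()
        mean_t, sd_t = tb.bootstrap_t(r1, r2, n_sampled=250, n_boot=100, rng=4)
        assert 0.3 < mean_t < 1.6
        assert sd_t < mean_t

    def test_single_repeat_sd_zero(self):
        r1, r2 = self._null_regions()
        _, sd_t = tb.bootstrap_t(r1, r2, n_sampled=100, n_boot=1, rng=0)
        assert sd_t == 0.0

    def test_deterministic_under_seed(self):
        r1, r2 = self._null_regions()
        a = tb.bootstrap_t(r1, r2, n_sampled=200, n_boot=50, rng=9)
        b = tb.bootstrap_t(r1, r2, n_sampled=200, n_boot=50, rng=9)
        assert a == b

    def test_oversized_draw_rejected(self):
        r1, r2 = self._null_regions(n=100)
        with pytest.raises(InsufficientDataError):
            tb.bootstrap_t(r1, r2, n_sampled=250, n_boot=10, rng=0)


class TestBinning:
    def test_pairwise_means(self):
        r = RegionSignal([1.0, 2.0, 3.0, 4.0], [10, 20, 30, 40], 1)
        b = tb.bin_signal(r, 2)
        np.testing.assert_array_equal(b.values, [1.5, 3.5])

    def test_identity_at_h1(self):
        r = RegionSignal([1.0, 2.0, 3.0], [1, 2, 3], 1)
        assert tb.bin_signal(r, 1) is r

    def test_trailing_incomplete_bin_dropped(self):
        r = RegionSignal(np.arange(5.0), np.arange(5), 1)
        assert len(tb.bin_signal(r, 2)) == 2


class TestRoc:
    def test_perfect_separation(self):
        roc = tb.roc_curve(np.zeros(50), np.ones(50))
        assert roc.auc == 1.0

    def test_null_is_half(self):
        rng = np.random.default_rng(5)
        roc = tb.roc_curve(rng.normal(size=5000), rng.normal(size=5000))
        assert roc.auc == pytest.approx(0.5, abs=0.03)

    def test_binormal_closed_form(self):
        """AUC for N(0,1) vs N(1,1) converges to Phi(1/sqrt(2)) ~ 0.760."""
        rng = np.random.default_rng(6)
        roc = tb.roc_curve(rng.normal(0, 1, 10_000), rng.normal(1, 1, 10_000))
        assert roc.auc == pytest.approx(stats.norm.cdf(1 / np.sqrt(2)), abs=0.01)

    def test_orientation_flip_recorded(self):
        rng = np.random.default_rng(7)
        roc = tb.roc_curve(rng.normal(1, 1, 500), rng.normal(0, 1, 500))
        assert roc.orientation == -1 and roc.auc > 0.5

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        neg, pos = rng.normal(0, 1, 500), rng.normal(1, 1, 500)
        a = tb.roc_curve(neg, pos).auc
        b = tb.roc_curve(np.exp(neg), np.exp(pos)).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_curve_endpoints(self):
        rng = np.random.default_rng(9)
        roc = tb.roc_curve(rng.normal(0, 1, 100), rng.normal(1, 1, 100))
        assert roc.fp_rate[0] == 0 and roc.tp_rate[0] == 0
        assert roc.fp_rate[-1] == 1 and roc.tp_rate[-1] == 1
        assert np.all(np.diff(roc.fp_rate) >= 0) and np.all(np.diff(roc.tp_rate) >= 0)


class TestEvaluateChangepoint:
    def test_null_control(self, scenario, scenario_calls, scenario_track):
        """On the no-change control every signal sits at chance level."""
        table, _, specs = scenario
        nn = next(s for s in specs if s.label == "N/N")
        tracks = {"dh_raw": tb.dh(table.beta_t), "dh_norm": tb.dh(scenario_track.beta_t_norm)}
        config = tb.EvalConfig(n_sampled=250, n_boot=50, bin_sizes=(1,), seed=13)
        report, _ = tb.evaluate_changepoint(
            tracks, table.position, scenario_calls, nn, config, chromosome=table.chromosome
        )
        assert (report["mean_t"] < 2).all()
        assert report["auc"].between(0.4, 0.6).all()

    def test_normalization_beats_raw_on_gain_loh(self, scenario, scenario_calls, scenario_track):
        table, _, specs = scenario
        gl = next(s for s in specs if s.label == "G/L")
        tracks = {"dh_raw": tb.dh(table.beta_t), "dh_norm": tb.dh(scenario_track.beta_t_norm)}
        config = tb.EvalConfig(n_sampled=250, n_boot=50, bin_sizes=(1, 2, 4), seed=13)
        report, _ = tb.evaluate_changepoint(
            tracks, table.position, scenario_calls, gl, config, chromosome=table.chromosome
        )
        piv = report.pivot(index="h", columns="signal", values="auc")
        assert (piv["dh_norm"] >= piv["dh_raw"]).all()

    def test_report_deterministic(self, scenario, scenario_calls, scenario_track):
        table, _, specs = scenario
        spec = next(s for s in specs if s.label == "N/G")
        tracks = {"dh_norm": tb.dh(scenario_track.beta_t_norm)}
        config = tb.EvalConfig(n_sampled=100, n_boot=20, bin_sizes=(1, 2), seed=99)
        r1, _ = tb.evaluate_changepoint(
            tracks, table.position, scenario_calls, spec, config, chromosome=table.chromosome
        )
        r2, _ = tb.evaluate_changepoint(
            tracks, table.position, scenario_calls, spec, config, chromosome=table.chromosome
        )
        pd.testing.assert_frame_equal(r1, r2)
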