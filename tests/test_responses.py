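"""Binning, baseline normalization, sliding-test classification, firing stats."""

import numpy as np
import pytest

from aonpop import responses as rs, simulate as sim, workflows as wk
from aonpop.errors import ParameterError


class TestBinning:
    def test_bin_grid_for_go_window(self):
        bc = rs.bin_centers_for_window((-0.3, 0.9))
        assert len(bc) == 51
        assert np.isclose(bc[0], -0.2) and np.isclose(bc[-1], 0.8)
        assert np.allclose(np.diff(bc), 0.02)

    def test_constant_poisson_rate_recovered(self, exe_trials,
                                             null_spike_maker):
        rate = 10.0
        spk = null_spike_maker(exe_trials, rate, seed=0)
        binned = rs.bin_activity(spk, exe_trials, "t_go_signal", (-0.3, 0.9))
        means = binned.rates.mean(axis=0)
        se = rate and np.sqrt(rate / (0.2 * binned.rates.shape[0]))
        assert np.all(np.abs(means - rate) < 3.5 * se)

    def test_single_spike_occupies_covering_bins(self, exe_trials):
        trial = exe_trials.iloc[0]
        spk = {trial["trial_id"]: np.array([trial["t_go_signal"]])}
        binned = rs.bin_activity(spk, exe_trials.iloc[[0]], "t_go_signal",
                                 (-0.3, 0.9))
        nonzero = binned.bin_centers[binned.counts[0] > 0]
        assert np.all(np.abs(nonzero) <= 0.1 + 1e-9)
        # ~10 covering bins (200-ms window, 20-ms steps); the bin whose edge
        # touches the spike may round either way
        assert nonzero.size in (10, 11)

    def test_empty_trials_rejected(self):
        with pytest.raises(ParameterError):
            rs.bin_activity({}, sim.generate_trials(1, seed=0).iloc[:0],
                            "t_go_signal", (-0.1, 0.1))


class TestBaseline:
    def test_spike_count_to_rate(self, exe_trials):
        trial = exe_trials.iloc[0]
        cue = trial["t_cue_onset"]
        spk = {trial["trial_id"]: cue - 0.5 + np.linspace(0.01, 0.49, 5)}
        rates, ids, mean = rs.compute_baseline(spk, exe_trials.iloc[[0]])
        assert rates[0] == pytest.approx(10.0)

    def test_silent_unit_zero(self, exe_trials):
        rates, _, mean = rs.compute_baseline({}, exe_trials)
        assert mean == 0.0

    def test_planted_baseline_recovered(self, exe_trials, null_spike_maker):
        rate = 12.0
        means = []
        for seed in range(20):
            spk = null_spike_maker(exe_trials, rate, seed=seed)
            _, _, m = rs.compute_baseline(spk, exe_trials)
            means.append(m)
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - rate) < 2 * se + 0.2


class TestSoftNormalization:
    def test_formula(self):
        out = rs.net_soft_normalize({"Go": np.array([25.0])}, baseline=10.0)
        # max |net| = 15 -> (25-10)/(15+5)
        assert out["Go"][0] == pytest.approx(0.75)

    def test_baseline_level_activity_is_zero(self):
        out = rs.net_soft_normalize({"Go": np.full(5, 7.0)}, baseline=7.0)
        assert np.all(out["Go"] == 0.0)

    def test_low_rate_damping(self):
        out = rs.net_soft_normalize({"Go": np.array([1.0])}, baseline=0.0)
        assert out["Go"][0] == pytest.approx(1.0 / 6.0)

    def test_outputs_strictly_inside_unit_interval(self, exe_trials,
                                                   null_spike_maker):
        spk = null_spike_maker(exe_trials, 30.0, seed=5)
        binned = rs.bin_activity(spk, exe_trials, "t_go_signal", (-0.3, 0.9))
        out = rs.net_soft_normalize({"all": binned.rates.mean(axis=0)},
                                    baseline=10.0)
        assert np.all(np.abs(out["all"]) < 1.0)


def _session_with_unit(gt, seed=0, n_per_condition=10):
    trials = sim.generate_trials(n_per_condition, "EXE", seed=seed)
    rng = np.random.default_rng(seed)
    spk = {}
    for _, row in trials.iterrows():
        t_stop = row["t_go_signal"] + 2.0
        spk[row["trial_id"]] = sim.generate_spike_train(
            gt, row, "EXE", t_stop, seed=rng.integers(2**31))
    return trials, spk


class TestClassification:
    def _classify(self, gt, seed):
        trials, spk = _session_with_unit(gt, seed=seed)
        base_r, base_ids, _ = rs.compute_baseline(spk, trials)
        binned = rs.bin_activity(spk, trials, "t_go_signal",
                                 rs.CLASSIFY_WINDOW)
        return rs.classify_response(binned, base_r, base_ids)

    @pytest.mark.parametrize("sign,expected", [
        (+1, rs.FACILITATED), (-1, rs.SUPPRESSED)])
    def test_planted_modulation_detected(self, sign, expected):
        hits = 0
        n_seeds = 12
        for seed in range(n_seeds):
            gt = sim.UnitGroundTruth(
                "u", "AIP", 1, 0.2, 0.05, 1, 20.0, sign, sign, 15.0, 0.0,
                onset_event="t_go_signal", duration=0.4)
            lab = self._classify(gt, seed)
            hits += lab.label == expected
        assert hits >= round(0.9 * n_seeds)

    def test_sign_symmetry_on_mirrored_rates(self):
        # noiseless rate inputs mirrored about baseline swap the labels
        centers = rs.bin_centers_for_window(rs.CLASSIFY_WINDOW)
        base = np.full(20, 10.0)
        bump = 6.0 * np.exp(-((centers - 0.3) / 0.15) ** 2)
        jitter = np.linspace(-0.5, 0.5, 20)[:, None]  # trial-to-trial spread
        up = 10.0 + bump[None, :] + jitter
        down = 2 * 10.0 - up
        mk = lambda r: rs.BinnedActivity(
            rates=r, counts=r * 0.2, bin_centers=centers,
            trial_ids=np.arange(20), alignment="t_go_signal")
        lab_up = rs.classify_response(mk(up), base)
        lab_down = rs.classify_response(mk(down), base)
        assert lab_up.label == rs.FACILITATED
        assert lab_down.label == rs.SUPPRESSED
        assert np.array_equal(lab_up.significant_bin_mask,
                              lab_down.significant_bin_mask)

    def test_zero_variance_bins_are_nonsignificant(self):
        centers = rs.bin_centers_for_window(rs.CLASSIFY_WINDOW)
        rates = np.full((5, centers.size), 10.0)
        binned = rs.BinnedActivity(rates=rates, counts=rates * 0.2,
                                   bin_centers=centers,
                                   trial_ids=np.arange(5),
                                   alignment="t_go_signal")
        lab = rs.classify_response(binned, np.full(5, 10.0))
        assert lab.label == rs.NONSIGNIFICANT


class TestPeakTime:
    def test_unimodal_bump(self):
        centers = rs.bin_centers_for_window((0.0, 0.6))
        trace = np.exp(-((centers - 0.25) / 0.1) ** 2)
        assert abs(rs.peak_time(trace, centers, "go") - 0.25) <= 0.02

    def test_monotone_trace_hits_window_edge(self):
        centers = rs.bin_centers_for_window((0.0, 0.6))
        t = rs.peak_time(centers.copy(), centers, "go")
        assert t == pytest.approx(centers[-1])

    def test_empty_window_rejected(self):
        with pytest.raises(ParameterError):
            rs.peak_time(np.array([1.0]), np.array([0.0]), (2.0, 3.0))

    def test_planted_population_latency_recovered(self):
        # median peak latency across simulated facilitated units ~ planted
        peaks = []
        for seed in range(15):
            gt = sim.UnitGroundTruth(
                "u", "F5", 2, 0.35, 0.16, 1, 15.0, 1, 1, 20.0, 0.3,
                onset_event="t_go_signal", duration=0.15, rise_sd=0.05)
            trials, spk = _session_with_unit(gt, seed=seed)
            _, _, base = rs.compute_baseline(spk, trials)
            binned = rs.bin_activity(spk, trials, "t_go_signal", (-0.1, 0.8))
            trace = binned.rates.mean(axis=0) - base
            peaks.append(rs.peak_time(trace, binned.bin_centers, "go"))
        assert abs(np.median(peaks) - (0.3 + 0.075)) <= 0.08

    def test_heatmap_ordering(self):
        centers = rs.bin_centers_for_window(rs.CLASSIFY_WINDOW)
        traces = np.vstack([np.full(centers.size, -0.2),
                            np.full(centers.size, 0.5),
                            np.full(centers.size, 0.5)])
        order = rs.order_heatmap(traces, centers)
        assert list(order) == [1, 2, 0]  # descending, ties keep input order


class TestFiringStatistics:
    def test_regular_train_zero_cv(self):
        stats_ = rs.firing_statistics({0: np.arange(0, 5, 0.1)})
        assert stats_["isi_cv"] == pytest.approx(0.0, abs=1e-12)

    def test_poisson_cv_near_one(self):
        rng = np.random.default_rng(3)
        spk = {i: np.sort(rng.uniform(0, 20.0, rng.poisson(200)))
               for i in range(10)}
        stats_ = rs.firing_statistics(spk)
        n = sum(max(len(s) - 1, 0) for s in spk.values())
        assert abs(stats_["isi_cv"] - 1.0) < 4 / np.sqrt(n)

    def test_doublets_raise_burst_fraction(self):
        base = np.arange(0, 5, 0.1)
        stats_plain = rs.firing_statistics({0: base})
        doublets = np.sort(np.concatenate([base, base + 0.005]))
        stats_burst = rs.firing_statistics({0: doublets})
        assert stats_burst["burst_fraction"] > stats_plain["burst_fraction"]

    def test_too_few_spikes(self):
        stats_ = rs.firing_statistics({0: np.array([1.0])})
        assert stats_["mean_isi"] is None


class TestTaskIndependence:
    def test_exe_and_obs_orderings_differ_when_modulation_differs(
            self, small_session):
        # units modulated in EXE only should not preserve ordering in OBS
        traces = {"EXE": [], "OBS": []}
        for u in small_session.units:
            for task in ("EXE", "OBS"):
                tr, _ = wk.normalized_task_trace(small_session, u.unit_id,
                                                 task)
                traces[task].append(tr)
        centers = rs.bin_centers_for_window(rs.CLASSIFY_WINDOW)
        o_exe = rs.order_heatmap(np.array(traces["EXE"]), centers)
        o_obs = rs.order_heatmap(np.array(traces["OBS"]), centers)
        assert not np.array_equal(o_exe, o_obs)
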