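"""Pseudo-population construction, Poisson NB decoding, MI and onset estimation."""

import itertools

import numpy as np
import pytest
from scipy import stats

from aonpop import decoding as dc
from aonpop.errors import ParameterError


def _units(rng, n_units, n_trials, B, rates):
    """rates: condition -> (B,) expected counts."""
    return [{c: rng.poisson(lam, size=(n_trials, B)).astype(float)
             for c, lam in rates.items()} for _ in range(n_units)]


class TestPseudoPopulation:
    def test_go_nogo_split_geometry(self):
        rng = np.random.default_rng(0)
        units = _units(rng, 5, 30, 4, {"Go": np.ones(4), "NoGo": np.ones(4)})
        pop = dc.make_pseudopopulation(units, np.arange(4), seed=1)
        assert pop.counts.shape == (30, 2, 5, 4)  # 30 splits x 2 = 60 points

    def test_object_split_geometry(self):
        rng = np.random.default_rng(0)
        rates = {o: np.ones(3) for o in ("ring", "small_cone", "big_cone")}
        units = _units(rng, 4, 10, 3, rates)
        pop = dc.make_pseudopopulation(units, np.arange(3), seed=1)
        assert pop.counts.shape == (10, 3, 4, 3)  # 10 splits x 3 = 30 points

    def test_single_trial_per_condition_rejected(self):
        rng = np.random.default_rng(0)
        units = _units(rng, 3, 1, 2, {"Go": np.ones(2), "NoGo": np.ones(2)})
        with pytest.raises(ParameterError):
            dc.make_pseudopopulation(units, np.arange(2), seed=0)

    def test_deficient_unit_named(self):
        rng = np.random.default_rng(0)
        units = _units(rng, 2, 10, 2, {"Go": np.ones(2), "NoGo": np.ones(2)})
        units.append({"Go": np.ones((3, 2)), "NoGo": np.ones((3, 2))})
        with pytest.raises(ParameterError, match="unit 2"):
            dc.make_pseudopopulation(units, np.arange(2), seed=0, n_splits=10)

    def test_number_matching_arithmetic(self):
        assert dc.number_matched_subsample_size([86, 106, 163]) == 65


class TestPreselection:
    def test_identical_condition_data_dropped(self):
        X = np.ones((10, 2, 3, 4))
        with pytest.raises(ParameterError):
            dc.preselect_features(X)  # every unit identical -> all dropped

    def test_selective_unit_retained_nonselective_mostly_dropped(self):
        rng = np.random.default_rng(1)
        n = 20
        X = rng.poisson(2.0, size=(n, 2, 2, 1)).astype(float)
        X[:, 1, 0, :] += 10.0  # unit 0 strongly selective
        mask = dc.preselect_features(X)
        assert mask[0, 0]

    def test_threshold_one_keeps_everything(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(2.0, size=(8, 2, 5, 3)).astype(float)
        mask = dc.preselect_features(X, p_threshold=1.0000001)
        assert mask.all()

    def test_null_unit_retention_matches_threshold(self):
        # under the null, P(p < 0.5) = 0.5: the F-test oracle
        rng = np.random.default_rng(3)
        kept = []
        for _ in range(300):
            X = rng.poisson(3.0, size=(12, 2, 1, 1)).astype(float)
            try:
                kept.append(dc.preselect_features(X)[0, 0])
            except ParameterError:
                kept.append(False)
        frac = np.mean(kept)
        assert abs(frac - 0.5) < 3.5 * np.sqrt(0.25 / 300) + 0.05


class TestPoissonNB:
    def test_single_point_parameters(self):
        X = np.array([[[[0.0, 3.0]], [[2.0, 0.0]]]])  # (1, 2, 1, 2)
        lam = dc.train_poisson_nb(X)
        assert np.allclose(lam[0, 0], [dc.RATE_FLOOR, 3.0])
        assert np.allclose(lam[1, 0], [2.0, dc.RATE_FLOOR])

    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        true = np.array([[2.0, 5.0]])
        X = rng.poisson(true, size=(400, 1, 2)).astype(float)[:, None]
        lam = dc.train_poisson_nb(X)
        se = np.sqrt(true / 400)
        assert np.all(np.abs(lam[0] - true) < 3 * se)

    def test_scores_match_brute_force_bayes(self):
        # enumeration oracle with explicit Poisson pmfs, exhaustive over
        # small instances
        rng = np.random.default_rng(5)
        for U, K, B in itertools.product([1, 2, 3], [2, 3], [1, 2]):
            lam = rng.uniform(0.2, 4.0, size=(K, U, B))
            for _ in range(10):
                x = rng.integers(0, 4, size=(U, B)).astype(float)
                scores = dc.poisson_nb_scores(x, lam)
                brute = np.array([
                    sum(stats.poisson.logpmf(x[u, b], lam[c, u, b])
                        for u in range(U) for b in range(B))
                    for c in range(K)])
                # scores omit the class-independent log(x!) term
                const = sum(-stats.poisson.logpmf(0, 1.0) * 0  # placeholder
                            for _ in range(1))
                logfact = np.sum([np.sum(np.log(np.arange(1, int(v) + 1)))
                                  for v in x.ravel()])
                assert np.allclose(scores.sum(axis=1), brute + logfact,
                                   atol=1e-8)

    def test_exhaustive_predictions_match_oracle(self):
        # all count configurations up to 3 spikes on a tiny instance
        lam = np.array([[[0.5]], [[2.5]]])  # K=2, U=1, B=1
        for x in range(4):
            xs = np.array([[float(x)]])
            pred = np.argmax(dc.poisson_nb_scores(xs, lam).sum(axis=1))
            brute = np.argmax([stats.poisson.logpmf(x, lam[c, 0, 0])
                               for c in range(2)])
            assert pred == brute


class TestMutualInformation:
    @pytest.mark.parametrize("conf,expected", [
        ([[10, 0], [0, 10]], 1.0),
        ([[5, 5], [5, 5]], 0.0),
        ([[9, 1], [1, 9]], 1 + 0.1 * np.log2(0.1) + 0.9 * np.log2(0.9)),
    ])
    def test_plugin_values(self, conf, expected):
        assert dc.mi_from_confusion(conf) == pytest.approx(expected,
                                                           abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            c = rng.integers(0, 10, size=(3, 3))
            if c.sum() == 0:
                continue
            mi = dc.mi_from_confusion(c)
            assert 0.0 <= mi <= np.log2(3) + 1e-12

    def test_diagonal_reaches_maximum(self):
        assert dc.mi_from_confusion(np.eye(3) * 7) == pytest.approx(np.log2(3))


class TestDecodeTimecourse:
    def test_normalization_constants(self):
        rng = np.random.default_rng(7)
        B = 6
        two = _units(rng, 6, 6, B, {"Go": np.ones(B), "NoGo": np.ones(B)})
        three = _units(rng, 6, 6, B,
                       {o: np.ones(B) for o in ("a", "b", "c")})
        r2 = dc.decode_timecourse(two, np.arange(B) * 0.02, n_subsample=6,
                                  n_iterations=2, n_runs=1, seed=0)
        r3 = dc.decode_timecourse(three, np.arange(B) * 0.02, n_subsample=6,
                                  n_iterations=2, n_runs=1, seed=0)
        assert r2.max_mi == 1.0
        assert round(r3.max_mi, 3) == 1.585

    def test_perfectly_separated_rates_decode_exactly(self):
        B = 4
        units = [{"Go": np.full((8, B), 12.0), "NoGo": np.zeros((8, B))}
                 for _ in range(4)]
        res = dc.decode_timecourse(units, np.arange(B) * 0.02, n_subsample=4,
                                   n_iterations=2, n_runs=1,
                                   smoothing_sd_s=1e-9, seed=1)
        assert np.allclose(res.mi_mean, 1.0)

    def test_shuffled_labels_mask_empty(self):
        rng = np.random.default_rng(8)
        empties = 0
        for seed in range(8):
            units = _units(rng, 20, 12, 10,
                           {"Go": np.full(10, 2.0), "NoGo": np.full(10, 2.0)})
            res = dc.decode_timecourse(units, np.arange(10) * 0.02,
                                       n_subsample=20, n_iterations=5,
                                       n_runs=2, seed=seed)
            empties += not res.significance_mask.any()
        assert empties >= 7

    def test_planted_changepoint_mask_onset(self):
        rng = np.random.default_rng(9)
        B = 41
        centers = 0.02 * np.arange(B)
        t_star = 0.4
        lam = np.full(B, 2.0)
        lam_go = lam.copy()
        lam_go[centers >= t_star] += 2.5
        units = _units(rng, 25, 12, B, {"Go": lam_go, "NoGo": lam})
        res = dc.decode_timecourse(units, centers, n_subsample=25,
                                   n_iterations=6, n_runs=3, seed=2)
        first = centers[np.argmax(res.significance_mask)]
        assert res.significance_mask.any()
        assert abs(first - t_star) <= 0.06

    def test_iteration_averaging_shrinks_spread(self):
        rng = np.random.default_rng(10)
        B = 8
        units = _units(rng, 15, 10, B,
                       {"Go": np.full(B, 2.4), "NoGo": np.full(B, 1.2)})
        few = dc.decode_timecourse(units, np.arange(B) * 0.02, n_subsample=15,
                                   n_iterations=5, n_runs=2, seed=3)
        many = dc.decode_timecourse(units, np.arange(B) * 0.02,
                                    n_subsample=15, n_iterations=20,
                                    n_runs=2, seed=3)
        sem_few = few.mi_sd.mean() / np.sqrt(few.mi_curves.shape[0])
        sem_many = many.mi_sd.mean() / np.sqrt(many.mi_curves.shape[0])
        assert sem_many < sem_few


def _result_from_curves(curves, centers, max_mi=1.0):
    return dc.DecodingResult(bin_centers=np.asarray(centers),
                             mi_curves=np.asarray(curves, dtype=float),
                             max_mi=max_mi, config={"n_subsample": 65})


class TestOnsets:
    def test_se_scaling_formula(self):
        centers = np.arange(0.0, 1.0, 0.02)
        rng = np.random.default_rng(11)
        onsets = rng.normal(0.4, 0.04, size=200)
        curves = [(centers >= o).astype(float) for o in onsets]
        res = _result_from_curves(curves, centers)
        est = dc.onset_time(res, n_area=106)
        grid_onsets = np.array([centers[np.argmax(c > 1 / 3)]
                                for c in curves])
        assert est.mean == pytest.approx(grid_onsets.mean())
        assert est.se == pytest.approx(grid_onsets.std(ddof=1) * 65 / 106)

    def test_curve_above_threshold_from_start(self):
        centers = np.arange(0.0, 0.2, 0.02)
        res = _result_from_curves([np.full(10, 0.9)], centers)
        est = dc.onset_time(res, n_area=65)
        assert est.mean == pytest.approx(centers[0])

    def test_never_crossing_reports_undefined(self):
        centers = np.arange(0.0, 0.2, 0.02)
        res = _result_from_curves([np.full(10, 0.1)] * 4, centers)
        est = dc.onset_time(res, n_area=65)
        assert not est.defined

    def test_compare_identical_results(self):
        est = dc.OnsetEstimate(defined=True, mean=0.3, se=0.02)
        out = dc.compare_onsets(est, est)
        assert out["z"] == 0.0 and out["p"] == pytest.approx(1.0)

    def test_compare_z_formula(self):
        a = dc.OnsetEstimate(defined=True, mean=0.10, se=0.05)
        b = dc.OnsetEstimate(defined=True, mean=0.30, se=0.05)
        out = dc.compare_onsets(a, b)
        assert out["z"] == pytest.approx(-2.828, abs=1e-3)
        assert out["p"] == pytest.approx(0.0047, abs=2e-4)

    def test_missing_onset_comparison_undefined(self):
        a = dc.OnsetEstimate(defined=True, mean=0.1, se=0.05)
        b = dc.OnsetEstimate(defined=False)
        assert not dc.compare_onsets(a, b)["defined"]


class TestClasswiseDecoding:
    def test_population_size_and_error_naming(self):
        rng = np.random.default_rng(12)
        B = 5
        units = _units(rng, 12, 8, B,
                       {"Go": np.full(B, 3.0), "NoGo": np.full(B, 1.0)})
        classes = np.array([1, 2] * 6)
        areas = np.array(["AIP", "F5", "F6"] * 4)
        res = dc.classwise_decode(units, classes, areas,
                                  np.arange(B) * 0.02,
                                  n_per_class_per_area=4, n_iterations=2,
                                  n_runs=1, seed=0)
        assert res[1].config["population_size"] == 12  # 4 x 3 areas
        lonely = np.ones(12, dtype=int)
        lonely[5] = 3  # class 3 exists only in F6
        with pytest.raises(ParameterError, match="class 3.*AIP"):
            dc.classwise_decode(units, lonely, areas,
                                np.arange(B) * 0.02, n_iterations=1,
                                n_runs=1)


class TestEpochAverage:
    def test_constant_curve(self):
        centers = np.arange(0.0, 1.0, 0.02)
        res = _result_from_curves([np.full(50, 0.4)] * 3, centers)
        vals = dc.epoch_average_mi(res, window=(0.2, 0.7))
        assert np.allclose(vals, 0.4)

    def test_window_outside_span_rejected(self):
        centers = np.arange(0.0, 0.3, 0.02)
        res = _result_from_curves([np.full(15, 0.4)], centers)
        with pytest.raises(ParameterError):
            dc.epoch_average_mi(res, window=(0.2, 0.7))
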