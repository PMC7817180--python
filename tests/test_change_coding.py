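import numpy as np
import pytest

import deviantcoding as dc
from deviantcoding.change_coding import shannon_entropy
from deviantcoding.datatypes import AnalysisConfig, DeflectionTrain
from deviantcoding.pipeline import run_change_coding
from deviantcoding.stimulus import deflection_sets, histogram_match_positions
from deviantcoding.units import CountTensor, analyzed_mask


def _toy_tensor(inc_counts, dec_counts):
    """One unit; one deflection per train; deviants with given counts."""
    trains = []
    counts = []
    tid = 0
    for sign, vals in ((1, inc_counts), (-1, dec_counts)):
        for v in vals:
            trains.append(dc.build_train(25.0, deviant_index=3,
                                         deviant_frac=0.1 * sign, train_id=tid))
            row = [0] * 7
            row[3] = v
            counts.append(row)
            tid += 1
    tensor = CountTensor(np.array([counts]), 100.0, [0],
                         [t.train_id for t in trains], analyzed_mask(trains))
    return tensor, trains


class TestChangeCoefficient:
    def test_arithmetic_example(self):
        tensor, trains = _toy_tensor([1, 2, 3], [1, 1, 1])
        cs = dc.change_coefficient(tensor, trains)
        assert cs.coeff[0] == pytest.approx(1.0)

    def test_missing_sign_marked_absent(self):
        tensor, trains = _toy_tensor([1, 2], [])
        cs = dc.change_coefficient(tensor, trains)
        assert np.isnan(cs.coeff[0])
        assert cs.absent_reason

    def test_brute_force_oracle(self, planted_session):
        cfg, trains, tensor, truth = planted_session
        sub = tensor.subset_units(np.arange(8))
        cs = dc.change_coefficient(sub, trains)
        # independent per-trial tabulation
        for ui in range(8):
            inc, dec = [], []
            for ti, t in enumerate(trains):
                if t.deviant_index is None:
                    continue
                c = sub.counts[ui, ti, t.deviant_index]
                (inc if t.deviant_sign > 0 else dec).append(c)
            assert cs.coeff[ui] == pytest.approx(np.mean(inc) - np.mean(dec))

    def test_sign_symmetry(self, planted_session):
        cfg, trains, tensor, truth = planted_session
        flipped = []
        for t in trains:
            if t.deviant_index is None:
                flipped.append(t)
            else:
                amps = t.amplitudes.copy()
                amps[t.deviant_index] = (2 * t.baseline_amplitude
                                         - amps[t.deviant_index])
                flipped.append(DeflectionTrain(
                    t.train_id, t.onsets, amps, t.baseline_amplitude,
                    t.deviant_index, -t.deviant_sign, t.opto_condition))
        cs = dc.change_coefficient(tensor, trains)
        cs_f = dc.change_coefficient(tensor, flipped)
        assert np.allclose(cs_f.coeff, -cs.coeff)
        acfg = AnalysisConfig(surrogate_draws=300, bootstrap_draws=500)
        r = run_change_coding(tensor, trains, np.ones(40, bool), acfg, seed=5)
        rf = run_change_coding(tensor, flipped, np.ones(40, bool), acfg, seed=5)
        assert rf.get("broadening").delta_iqr == pytest.approx(
            r["broadening"].delta_iqr)
        assert rf["broadening"].delta_H == pytest.approx(
            r["broadening"].delta_H, abs=0.15)


class TestSurrogate:
    def test_mean_near_zero_and_deterministic(self, planted_session):
        cfg, trains, tensor, truth = planted_session
        s1 = dc.surrogate_population(tensor, trains, n_draws=200, seed=3)
        s2 = dc.surrogate_population(tensor, trains, n_draws=200, seed=3)
        assert np.array_equal(s1.draws, s2.draws)
        assert abs(s1.draws.mean()) < 0.01

    def test_iqr_grows_with_count_variance(self):
        iqrs = []
        for base_rate in (0.5, 4.0):
            cfg = dc.SpikeSimConfig(n_units={"L4": 30}, driven_fraction={"L4": 1.0},
                                    base_rate=base_rate, amplitude_gain={"L4": 0.0})
            trains = dc.build_deviant_trains(150, 60, 60, seed=4)
            tensor, _ = dc.simulate_count_tensor(cfg, trains, seed=5)
            s = dc.surrogate_population(tensor, trains, n_draws=200, seed=6)
            iqrs.append(np.median(np.percentile(s.draws, 75, axis=1)
                                  - np.percentile(s.draws, 25, axis=1)))
        assert iqrs[1] > iqrs[0]

    def test_insufficient_pool_rejected(self):
        tensor, trains = _toy_tensor([1, 1, 1], [1, 1, 1])  # no baseline trains
        with pytest.raises(ValueError):
            dc.surrogate_population(tensor, trains, n_draws=10, seed=0)


class TestBroadening:
    def test_uniform_histogram_entropy_closed_form(self):
        vals = np.repeat(np.arange(8) + 0.5, 5)
        edges = np.arange(9.0)
        assert shannon_entropy(vals, edges) == pytest.approx(3.0)

    def test_planted_heterogeneity_detected(self, planted_session):
        cfg, trains, tensor, truth = planted_session
        res = run_change_coding(tensor, trains, truth.units.driven.to_numpy(),
                                AnalysisConfig(surrogate_draws=500,
                                               bootstrap_draws=1000), seed=7)
        b = res["broadening"]
        assert b.delta_iqr > 0
        assert b.p_iqr < 0.05 or b.p_entropy < 0.05

    def test_entropy_sign_stable_across_bin_counts(self, planted_session):
        cfg, trains, tensor, truth = planted_session
        signs = []
        for bins in (10, 15, 20, 30):
            acfg = AnalysisConfig(surrogate_draws=300, bootstrap_draws=500,
                                  entropy_bins=bins)
            res = run_change_coding(tensor, trains, truth.units.driven.to_numpy(),
                                    acfg, seed=8)
            signs.append(np.sign(res["broadening"].delta_H))
        assert len(set(signs)) == 1

    def test_too_few_units_rejected(self, planted_session):
        cfg, trains, tensor, truth = planted_session
        cs = dc.change_coefficient(tensor.subset_units(np.arange(5)), trains)
        surr = dc.surrogate_population(tensor.subset_units(np.arange(5)), trains,
                                       n_draws=50, seed=0)
        with pytest.raises(ValueError):
            dc.broadening_test(cs, surr)


class TestGroupedEffect:
    def test_symmetric_population_cancels(self, planted_session):
        cfg, trains, tensor, truth = planted_session
        diff, p, ci = dc.grouped_deviant_effect(
            tensor.subset_units(truth.units.driven.to_numpy()), trains,
            seed=1, n_boot=500)
        assert ci[0] <= 0 <= ci[2] or abs(np.median(diff)) < 0.02

    def test_uniform_shift_detected(self, planted_session):
        cfg, trains, tensor, truth = planted_session
        rng = np.random.default_rng(9)
        shifted = tensor.counts.copy()
        for ti, t in enumerate(trains):
            if t.deviant_index is not None:
                shifted[:, ti, t.deviant_index] += rng.poisson(
                    0.06, size=shifted.shape[0])
        tensor2 = CountTensor(shifted, tensor.window_ms, tensor.unit_ids,
                              tensor.train_ids, tensor.analyzed)
        diff, p, ci = dc.grouped_deviant_effect(tensor2, trains, seed=2, n_boot=500)
        assert np.median(diff) > 0
        assert p < 0.01


class TestPairedConditionTest:
    def test_identical_conditions_null(self):
        rng = np.random.default_rng(0)
        c = rng.normal(0, 0.05, 80)
        delta, p, ci = dc.paired_condition_test(c, c.copy(), n_boot=2000, seed=1)
        assert delta == pytest.approx(0.0)
        assert 0.2 < p < 0.8

    def test_sharpening_detected(self):
        rng = np.random.default_rng(1)
        c = np.concatenate([rng.normal(0.05, 0.02, 40),
                            rng.normal(-0.05, 0.02, 40)])
        laser = np.median(c) + 0.5 * (c - np.median(c))
        delta, p, ci = dc.paired_condition_test(c, laser, n_boot=2000, seed=2)
        assert delta > 0
        assert p < 0.05

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            dc.paired_condition_test(np.array([0.1]), np.array([0.2]))

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            dc.paired_condition_test(np.zeros(5), np.zeros(6))


def test_matched_sets_feed_surrogate(planted_session):
    cfg, trains, tensor, truth = planted_session
    dev, base = deflection_sets(trains)
    m = histogram_match_positions(dev, base, seed=0)
    s = dc.surrogate_population(tensor, trains, n_draws=50, seed=0, matched=m)
    assert s.draws.shape == (50, tensor.n_units)
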