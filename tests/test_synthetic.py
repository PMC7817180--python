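import numpy as np
import pytest

import deviantcoding as dc
from deviantcoding.calcium import compute_dff
from deviantcoding.change_coding import change_coefficient
from deviantcoding.synthetic import (CalciumSimConfig, gcamp_kernel,
                                     simulate_calcium, simulate_imaging_frames)
from deviantcoding.units import per_deflection_counts


def _single_unit_cfg(c, regime="shifted", gain=0.15):
    return dc.SpikeSimConfig(
        n_units={"L2/3": 1}, driven_fraction={"L2/3": 1.0},
        response_gain=gain, change_regime={"L2/3": (regime, c)},
        amplitude_gain={"L2/3": 0.0})


class TestSpikeSim:
    def test_planted_change_coefficient_recovered(self):
        # 2000 deviant trains (1000 per sign): empirical increase-decrease
        # difference within 3 SEM of the planted c
        c = 0.05
        trains = dc.build_deviant_trains(0, 1000, 1000, seed=1)
        tensor, truth = dc.simulate_count_tensor(_single_unit_cfg(c), trains, seed=2)
        est = change_coefficient(tensor, trains).coeff[0]
        lam = tensor.counts.mean()
        sem = np.sqrt(2 * lam / 1000)
        assert abs(est - c) < 3 * sem

    def test_null_c_gives_zero_difference(self):
        trains = dc.build_deviant_trains(0, 2000, 2000, seed=3)
        tensor, _ = dc.simulate_count_tensor(
            _single_unit_cfg(0.0, "null"), trains, seed=4)
        est = change_coefficient(tensor, trains).coeff[0]
        sem = np.sqrt(2 * tensor.counts.mean() / 2000)
        assert abs(est) < 3 * sem

    def test_spike_and_count_paths_agree_in_mean(self):
        cfg = _single_unit_cfg(0.0, "null")
        trains = dc.build_deviant_trains(300, 0, 0, seed=5)
        bundle, _ = dc.simulate_population_spikes(cfg, trains, seed=6)
        ct_spikes = per_deflection_counts(bundle)
        ct_direct, _ = dc.simulate_count_tensor(cfg, trains, seed=7)
        m1, m2 = ct_spikes.counts.mean(), ct_direct.counts.mean()
        pooled_sem = np.sqrt((m1 + m2) / ct_spikes.counts.size)
        assert abs(m1 - m2) < 4 * pooled_sem

    def test_seed_determinism(self):
        cfg = dc.SpikeSimConfig()
        trains = dc.build_deviant_trains(20, 10, 10, seed=8)
        b1, g1 = dc.simulate_population_spikes(cfg, trains, seed=9)
        b2, g2 = dc.simulate_population_spikes(cfg, trains, seed=9)
        assert g1.units.equals(g2.units)
        for u1, u2 in zip(b1.units, b2.units):
            assert set(u1.spike_times) == set(u2.spike_times)
            for tid in u1.spike_times:
                assert np.array_equal(u1.spike_times[tid], u2.spike_times[tid])

    def test_opto_shuffle_preserves_l6_rate_but_swaps_identity(self):
        cfg = dc.SpikeSimConfig(
            n_units={"L6": 100}, driven_fraction={"L6": 0.5},
            opto_shuffle_fraction=0.5, amplitude_gain={"L6": 0.0},
            change_regime={"L6": ("null", 0.0)})
        ctrl = dc.build_deviant_trains(400, 0, 0, seed=10)
        laser = dc.build_deviant_trains(400, 0, 0, seed=11,
                                        opto_condition="weak_laser", id_offset=400)
        tensor, truth = dc.simulate_count_tensor(cfg, ctrl + laser, seed=12)
        is_laser = np.array([t.opto_condition == "weak_laser" for t in ctrl + laser])
        mean_ctrl = tensor.counts[:, ~is_laser].mean()
        mean_laser = tensor.counts[:, is_laser].mean()
        assert abs(mean_laser - mean_ctrl) / mean_ctrl < 0.02
        n_swapped = (truth.units.opto_role != "none").sum()
        assert n_swapped >= 40

    def test_negative_rates_clipped_and_counted(self):
        cfg = _single_unit_cfg(2.0, "heterogeneous", gain=0.05)
        trains = dc.build_deviant_trains(0, 50, 50, seed=13)
        tensor, _ = dc.simulate_count_tensor(cfg, trains, seed=14)
        assert tensor.meta["clipped_rates"] > 0
        assert (tensor.counts >= 0).all()


class TestCalciumSim:
    def test_noiseless_quiet_roi_recovers_zero_dff(self):
        cfg = CalciumSimConfig(n_rois=3, driven_fraction=0.0, noise_sd_dff=0.0,
                               spont_event_rate_hz=0.0, n_trials_per_condition=20,
                               f0_drift_frac=0.0)
        traces, _ = simulate_calcium(cfg, seed=1)
        f0, dff = compute_dff(traces.F, traces.frame_rate)
        assert np.abs(dff).max() < 1e-9

    def test_planted_transient_peak_recovered(self):
        fr = 5.0
        n = 3000
        F = np.full(n, 100.0)
        k = gcamp_kernel(fr)
        F[1000:1000 + k.size] += 1.5 * 100.0 * k
        _, dff = compute_dff(F, fr)
        assert dff[0, 1000:1000 + k.size].max() == pytest.approx(1.5, rel=0.05)

    def test_artifact_touches_only_flagged_lines(self):
        frames, clean, labels, flagged, led_on, _ = simulate_imaging_frames(
            seed=2, global_artifact=0.0)
        delta = frames - clean
        unflagged = np.setdiff1d(np.arange(frames.shape[1]), flagged)
        assert np.abs(delta[:, unflagged, :]).max() == 0
        assert np.abs(delta[np.ix_(led_on, flagged)]).max() > 0
        assert np.abs(delta[np.ix_(~led_on, flagged)]).max() == 0


class TestBehaviorSim:
    def test_hit_probability_at_threshold(self):
        psych = dc.PsychObserver(mu=15, sigma=3, guess=0.0, lapse=0.0,
                                 deviant_benefit=0.0)
        assert psych.hit_probability(15.0) == pytest.approx(0.5)

    def test_null_benefit_converges_to_zero(self):
        psych = dc.PsychObserver(deviant_benefit=0.0)
        trials = dc.simulate_detection_behavior(psych, 20000, seed=3)
        sub = trials[(trials.amplitude > 0) & (trials.amplitude < 0.6 * psych.mu)]
        h_dev = (sub[sub.deviant_present].response == "hit").mean()
        h_base = (sub[~sub.deviant_present].response == "hit").mean()
        assert abs(h_dev - h_base) < 0.03

    def test_exclusion_rules_are_exercised(self):
        psych = dc.PsychObserver()
        trials = dc.simulate_detection_behavior(psych, 5000, seed=4)
        rt = trials.reaction_time_ms
        assert ((rt < 50) & rt.notna()).any()
        assert (trials.deviant_time_ms > 400).any()

    def test_invalid_observer_rejected(self):
        with pytest.raises(Exception):
            dc.PsychObserver(mu=-1.0)
        with pytest.raises(Exception):
            dc.PsychObserver(guess=0.8, lapse=0.4)
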