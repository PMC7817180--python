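import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import deviantcoding as dc
from deviantcoding.calcium import (annulus_masks_from_labels, classify_responsive,
                                   compute_dff, evoked_encoding_stats,
                                   evoked_responses, extract_traces,
                                   interpolate_flagged_lines, neuropil_annulus,
                                   subtract_brightening_profile)
from deviantcoding.synthetic import (CalciumSimConfig, gcamp_kernel,
                                     simulate_calcium, simulate_imaging_frames)


class TestDff:
    def test_constant_trace_identity(self):
        F = np.full((2, 500), 100.0)
        f0, dff = compute_dff(F, frame_rate=5.0)
        assert np.allclose(f0, 100.0)
        assert np.allclose(dff, 0.0)

    def test_step_baseline_tracked_within_2pct(self):
        rng = np.random.default_rng(0)
        fr = 5.0
        F = np.full(4000, 100.0)
        F[2000:] = 200.0
        k = gcamp_kernel(fr)
        for i0 in rng.integers(0, 3900, 12):  # sparse transients
            seg = slice(i0, min(i0 + k.size, 4000))
            F[seg] += 0.8 * F[i0] * k[:seg.stop - seg.start]
        f0, _ = compute_dff(F, fr)
        away1 = slice(700, 1300)
        away2 = slice(2700, 3300)
        assert np.abs(f0[0, away1] / 100.0 - 1).max() < 0.02
        assert np.abs(f0[0, away2] / 200.0 - 1).max() < 0.02

    @given(k=st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_global_gain_invariance(self, k):
        rng = np.random.default_rng(1)
        F = 100.0 + 10.0 * rng.random(400)
        _, d1 = compute_dff(F, 5.0)
        _, d2 = compute_dff(k * F, 5.0)
        assert np.allclose(d1, d2, atol=1e-10)

    def test_nonpositive_baseline_rejected(self):
        F = np.zeros((1, 300))
        with pytest.raises(ValueError):
            compute_dff(F, 5.0)


class TestAnnulus:
    def test_lone_roi_extends_only_in_x(self):
        grid = np.zeros((40, 80), dtype=bool)
        grid[20, 30:40] = True  # 10 px wide, 1 px tall
        ann = neuropil_annulus(grid, grid, erode_x_px=20)
        ys, xs = np.nonzero(ann)
        assert set(ys) == {20}                      # no y extension
        assert xs.min() == 10 and xs.max() == 59    # 20 px each side
        assert not (ann & grid).any()

    def test_abutting_rois_exclude_each_other(self):
        labels = np.zeros((30, 60), dtype=np.int32)
        labels[15, 10:20] = 1
        labels[15, 20:30] = 2
        anns = annulus_masks_from_labels(labels, erode_x_px=20)
        somata = labels > 0
        for ann in anns.values():
            assert not (ann & somata).any()

    def test_set_algebra_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        labels = np.zeros((50, 50), dtype=np.int32)
        for lab in (1, 2, 3):
            cy, cx = rng.integers(5, 45, 2)
            yy, xx = np.mgrid[0:50, 0:50]
            labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= 9] = lab
        anns = annulus_masks_from_labels(labels, erode_x_px=6)
        somata = labels > 0
        for lab, ann in anns.items():
            roi = labels == lab
            brute = np.zeros_like(roi)
            ys, xs = np.nonzero(roi)
            for y, x in zip(ys, xs):
                lo, hi = max(0, x - 6), min(50, x + 7)
                brute[y, lo:hi] = True
            brute &= ~somata
            assert np.array_equal(ann, brute)


class TestArtifact:
    def test_clean_constant_field_unchanged(self):
        frames = np.full((5, 16, 16), 50.0)
        out = interpolate_flagged_lines(frames, np.arange(0, 16, 4))
        assert np.allclose(out, frames)

    def test_null_session_profile_near_zero(self):
        rng = np.random.default_rng(3)
        np_traces = 30.0 + rng.normal(0, 0.1, (6, 400))
        _, profile = subtract_brightening_profile(np_traces.copy(), np_traces)
        assert np.abs(profile).max() < 0.02

    def test_two_stage_residual_below_half_percent(self):
        frames, clean, labels, flagged, led_on, _ = simulate_imaging_frames(seed=4)
        from deviantcoding.calcium import correct_light_artifact
        corr, _ = correct_light_artifact(frames, flagged, labels)
        ref, _ = correct_light_artifact(clean, flagged, labels)
        assert (np.abs(corr - ref) / ref).max() < 0.005

    def test_edge_lines_one_sided(self):
        frames = np.tile(np.arange(8.0)[None, :, None], (2, 1, 8)) + 1.0
        out = interpolate_flagged_lines(frames, [0, 7])
        assert np.allclose(out[:, 0], frames[:, 1])
        assert np.allclose(out[:, 7], frames[:, 6])


class TestResponsiveness:
    def _traces(self, seed, driven_fraction, n_rois=60):
        cfg = CalciumSimConfig(n_rois=n_rois, driven_fraction=driven_fraction,
                               n_trials_per_condition=40)
        traces, gt = simulate_calcium(cfg, seed=seed)
        traces.F0, traces.dff = compute_dff(traces.F, traces.frame_rate)
        return traces, gt

    def test_driven_rois_recovered(self):
        traces, gt = self._traces(5, 0.2)
        flags = classify_responsive(traces, "control")
        truth = gt.rois.driven_control.to_numpy()
        assert (flags == truth).mean() >= 0.95

    def test_null_false_positive_rate(self):
        traces, _ = self._traces(6, 0.0, n_rois=150)
        flags = classify_responsive(traces, None)
        assert flags.mean() <= 0.05

    def test_equal_windows_not_responsive(self):
        traces, _ = self._traces(7, 0.3)
        flags = classify_responsive(traces, None, pre_window=(0.5, 1.5),
                                    stim_window=(0.5, 1.5))
        assert not flags.any()


class TestEncodingStats:
    def test_amplitude_encoding_detected(self):
        cfg = CalciumSimConfig(n_rois=120, driven_fraction=0.3,
                               n_trials_per_condition=50)
        traces, gt = simulate_calcium(cfg, seed=8)
        traces.F0, traces.dff = compute_dff(traces.F, traces.frame_rate)
        flags = classify_responsive(traces, None)
        resp = evoked_responses(traces)
        stats = evoked_encoding_stats(resp, traces.trials, "baseline_amp",
                                      roi_subset=flags, seed=9, n_boot=2000)
        assert stats["ci_median"][0] > 0
        assert stats["p_signed_rank"] < 0.01

    def test_shuffled_contrast_covers_zero(self):
        cfg = CalciumSimConfig(n_rois=80, driven_fraction=0.3,
                               n_trials_per_condition=50)
        traces, _ = simulate_calcium(cfg, seed=10)
        traces.F0, traces.dff = compute_dff(traces.F, traces.frame_rate)
        resp = evoked_responses(traces)
        rng = np.random.default_rng(11)
        trials = traces.trials.copy()
        trials["amplitude"] = rng.permutation(trials.amplitude.to_numpy())
        stats = evoked_encoding_stats(resp, trials, "baseline_amp", seed=12,
                                      n_boot=2000)
        lo, _, hi = stats["ci_median"]
        assert lo <= 0 <= hi

    def test_cross_validation_controls_regression_to_mean(self):
        # pure-noise ROIs: selecting the most responsive on the same trials
        # that are evaluated inflates "encoding"; a held-out split does not
        cfg = CalciumSimConfig(n_rois=200, driven_fraction=0.0,
                               n_trials_per_condition=40)
        traces, _ = simulate_calcium(cfg, seed=13)
        traces.F0, traces.dff = compute_dff(traces.F, traces.frame_rate)
        resp = evoked_responses(traces)
        n_trials = resp.shape[1]
        train = np.arange(n_trials) % 2 == 0
        sel = np.argsort(resp[:, train].mean(axis=1))[-20:]   # top "responders"
        # spurious "encoding" = selected ROIs' excess over the population
        naive_excess = resp[sel][:, train].mean() - resp[:, train].mean()
        cv_excess = resp[sel][:, ~train].mean() - resp[:, ~train].mean()
        assert naive_excess > 0.01
        assert abs(cv_excess) < naive_excess / 2
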