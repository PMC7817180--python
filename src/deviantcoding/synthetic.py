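"""Synthetic spike, calcium, and behavioral data with known ground truth.

Every downstream stage of the pipeline is testable against data generated
here: spike trains are drawn from an inhomogeneous Poisson process with a
phasic deflection-response kernel, repetition adaptation, and a planted
per-unit "change coefficient" c defined so that the expected spike-count
difference between amplitude-increase and amplitude-decrease deviants is
exactly c; calcium traces convolve sparse event trains with a GCaMP6s-like
kernel on top of a drifting baseline with neuropil contamination; the
behavioral observer is a cumulative-Gaussian psychometric subject with a
detection benefit for sub-threshold deviant-containing stimuli.

The generator emulates the qualitative layer structure of barrel-cortex
deviance encoding: positively shifted change coefficients in L4,
heterogeneous two-signed coefficients in L2/3, sparse responsiveness and
amplitude coding in L6, and a weak-laser "ensemble shuffle" that swaps
which L6 units are sensory driven while preserving mean rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ConfigError, DeflectionTrain, SessionBundle, UnitRecord
from .stimulus import EPHYS_DEVIANT_POSITIONS, build_train
from .units import CountTensor, analyzed_mask, assign_layer, classify_waveform

REFERENCE_AMPLITUDE = 25.0  # mm/s, the nominal baseline deflection velocity

# depth ranges (um) used when placing synthetic units into layers
_LAYER_DEPTHS = {"L2/3": (120.0, 340.0), "L4": (360.0, 440.0),
                 "L5": (460.0, 640.0), "L6": (660.0, 800.0)}


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# spike simulation
# ---------------------------------------------------------------------------

@dataclass
class SpikeSimConfig:
    """Parameters of the population spike simulator.

    ``change_regime`` maps layer -> (mode, c) where mode is ``"shifted"``
    (all driven units get +c), ``"heterogeneous"`` (driven units get +c or
    -c with equal probability), or ``"null"`` (c = 0); c is in spikes per
    deflection and satisfies E[count | increase] - E[count | decrease] = c
    in the response window for every driven unit.
    """

    n_units: Mapping[str, int] = field(
        default_factory=lambda: {"L2/3": 30, "L4": 15, "L5": 20, "L6": 25})
    driven_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"L2/3": 0.26, "L4": 0.5, "L5": 0.3, "L6": 0.13})
    base_rate: float = 0.5                 # Hz, spontaneous (sparse awake RS)
    response_gain: float = 0.15            # expected spikes per deflection (pos 0)
    adaptation_decay: float = 0.9          # geometric per-position multiplier
    amplitude_gain: Mapping[str, float] = field(
        default_factory=lambda: {"L2/3": 0.0, "L4": 0.0, "L5": 0.0, "L6": 0.004})
    change_regime: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: {"L2/3": ("heterogeneous", 0.05),
                                 "L4": ("shifted", 0.015),
                                 "L5": ("null", 0.0),
                                 "L6": ("null", 0.0)})
    fs_fraction: float = 0.3
    opto_shuffle_fraction: float = 0.5     # of driven L6 units swapped under laser
    kernel_latency_s: float = 0.010
    kernel_duration_s: float = 0.025
    trial_span_s: tuple[float, float] = (-0.2, 0.9)

    def __post_init__(self) -> None:
        if self.base_rate < 0 or self.response_gain < 0:
            raise ConfigError("rates must be non-negative")
        for frac in list(self.driven_fraction.values()) + [self.fs_fraction,
                                                           self.opto_shuffle_fraction]:
            if not 0 <= frac <= 1:
                raise ConfigError("fractions must lie in [0, 1]")

    def adaptation_profile(self, n_deflections: int) -> np.ndarray:
        return self.adaptation_decay ** np.arange(n_deflections)


@dataclass
class GroundTruth:
    """Planted parameters, aligned 1:1 with generated units or ROIs."""

    units: pd.DataFrame | None = None
    rois: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)


def build_deviant_trains(
    n_baseline: int,
    n_increase: int,
    n_decrease: int,
    seed=0,
    baseline_amp: float = REFERENCE_AMPLITUDE,
    amp_jitter: float = 0.10,
    deviant_frac_range: tuple[float, float] = (0.05, 0.15),
    positions: Sequence[int] = EPHYS_DEVIANT_POSITIONS,
    n_deflections: int = 7,
    rate_hz: float = 10.0,
    opto_condition: str = "control",
    id_offset: int = 0,
) -> list[DeflectionTrain]:
    """Build a session's stimulus trains with randomized deviants.

    Baseline amplitudes are jittered trial-to-trial by up to ``amp_jitter``
    (a narrow randomized range around ~25 mm/s); deviant fractions are drawn
    uniformly from ``deviant_frac_range`` and deviant positions uniformly
    from ``positions`` (a deviant follows at least two baseline deflections).
    """
    rng = _as_rng(seed)
    trains = []
    signs = [0] * n_baseline + [+1] * n_increase + [-1] * n_decrease
    for i, sign in enumerate(signs):
        amp = baseline_amp * (1.0 + rng.uniform(-amp_jitter, amp_jitter))
        if sign == 0:
            trains.append(build_train(amp, n=n_deflections, rate=rate_hz,
                                      train_id=id_offset + i,
                                      opto_condition=opto_condition))
        else:
            frac = sign * rng.uniform(*deviant_frac_range)
            pos = int(rng.choice(positions))
            trains.append(build_train(amp, n=n_deflections, rate=rate_hz,
                                      deviant_index=pos, deviant_frac=frac,
                                      train_id=id_offset + i,
                                      opto_condition=opto_condition))
    return trains


def make_unit_table(cfg: SpikeSimConfig, seed=0) -> pd.DataFrame:
    """Draw per-unit ground-truth parameters (layer, depth, class, c, gains)."""
    rng = _as_rng(seed)
    rows = []
    uid = 0
    for layer, n in cfg.n_units.items():
        lo, hi = _LAYER_DEPTHS[layer]
        mode, c = cfg.change_regime.get(layer, ("null", 0.0))
        again = cfg.amplitude_gain.get(layer, 0.0)
        for _ in range(n):
            depth = rng.uniform(lo, hi)
            is_fs = rng.random() < cfg.fs_fraction
            width = rng.uniform(0.15, 0.35) if is_fs else rng.uniform(0.45, 0.9)
            driven = rng.random() < cfg.driven_fraction.get(layer, 0.0)
            if not driven or mode == "null":
                c_u = 0.0
            elif mode == "shifted":
                c_u = c
            elif mode == "heterogeneous":
                c_u = c if rng.random() < 0.5 else -c
            else:
                raise ConfigError(f"unknown change regime {mode!r}")
            rows.append(dict(unit_id=uid, layer=layer, depth_um=depth,
                             width_ms=width, driven=driven, c=c_u,
                             amplitude_gain=again if driven else 0.0,
                             opto_role="none", partner_id=-1))
            uid += 1
    table = pd.DataFrame(rows)
    # weak-laser ensemble shuffle: pair driven and non-driven L6 units that
    # will exchange their evoked responses on laser trials
    l6 = table[table.layer == "L6"]
    driven_ids = l6.index[l6.driven].to_numpy()
    silent_ids = l6.index[~l6.driven].to_numpy()
    k = min(int(round(cfg.opto_shuffle_fraction * driven_ids.size)), silent_ids.size)
    if k > 0:
        sup = rng.choice(driven_ids, size=k, replace=False)
        fac = rng.choice(silent_ids, size=k, replace=False)
        table.loc[sup, "opto_role"] = "laser_suppressed"
        table.loc[fac, "opto_role"] = "laser_facilitated"
        table.loc[sup, "partner_id"] = table.loc[fac, "unit_id"].to_numpy()
        table.loc[fac, "partner_id"] = table.loc[sup, "unit_id"].to_numpy()
    return table


def expected_evoked_counts(
    cfg: SpikeSimConfig, unit_table: pd.DataFrame, trains: Sequence[DeflectionTrain]
) -> np.ndarray:
    """Expected evoked spikes per (unit, trial, deflection), before clipping.

    The deviant deflection adds ``(c/2) * deviant_sign`` expected spikes on
    top of the adapted baseline response, so the increase-minus-decrease
    expectation equals the planted c exactly.  Trial-to-trial baseline
    amplitude variation enters through ``amplitude_gain``.
    """
    n_defl = trains[0].n_deflections
    adapt = cfg.adaptation_profile(n_defl)
    base_amp = np.array([t.baseline_amplitude for t in trains])
    dev_idx = np.array([-1 if t.deviant_index is None else t.deviant_index
                        for t in trains])
    dev_sign = np.array([t.deviant_sign for t in trains])
    laser = np.array([t.opto_condition == "weak_laser" for t in trains])

    driven = unit_table.driven.to_numpy().copy()[:, None]
    gain = np.where(unit_table.driven, cfg.response_gain, 0.0)[:, None]
    agn = unit_table.amplitude_gain.to_numpy()[:, None]
    c = unit_table.c.to_numpy()[:, None]

    # swap evoked parameters for opto-paired units on weak-laser trials
    if laser.any() and (unit_table.opto_role != "none").any():
        idx = unit_table.set_index("unit_id")
        gain_l, agn_l, c_l = gain.copy(), agn.copy(), c.copy()
        for i, row in unit_table.iterrows():
            if row.opto_role == "none":
                continue
            p = idx.loc[row.partner_id]
            gain_l[i] = cfg.response_gain if p.driven else 0.0
            agn_l[i] = p.amplitude_gain
            c_l[i] = p.c
    else:
        gain_l, agn_l, c_l = gain, agn, c

    per_defl = gain + agn * (base_amp[None, :] - REFERENCE_AMPLITUDE)
    per_defl_l = gain_l + agn_l * (base_amp[None, :] - REFERENCE_AMPLITUDE)
    per_defl = np.where(laser[None, :], per_defl_l, per_defl)
    lam = np.clip(per_defl, 0.0, None)[:, :, None] * adapt[None, None, :]
    c_eff = np.where(laser[None, :], c_l, c)
    dev_term = 0.5 * c_eff * dev_sign[None, :]
    cols = np.arange(n_defl)
    at_dev = cols[None, None, :] == dev_idx[None, :, None]
    lam = lam + at_dev * dev_term[:, :, None]
    return lam


def simulate_count_tensor(
    cfg: SpikeSimConfig,
    trains: Sequence[DeflectionTrain],
    seed=0,
    window_ms: float = 100.0,
    unit_table: pd.DataFrame | None = None,
) -> tuple[CountTensor, GroundTruth]:
    """Draw per-deflection spike counts directly (fast path).

    Marginally equivalent to running :func:`simulate_population_spikes`
    followed by window counting: the evoked kernel lies entirely inside the
    100 ms response window, so counts are Poisson with mean
    ``base_rate * window + lambda_evoked``.
    """
    rng = _as_rng(seed)
    if unit_table is None:
        unit_table = make_unit_table(cfg, rng)
    lam = expected_evoked_counts(cfg, unit_table, trains)
    n_clip = int(np.sum(lam < 0))
    lam = np.clip(lam, 0.0, None) + cfg.base_rate * window_ms / 1000.0
    counts = rng.poisson(lam)
    tensor = CountTensor(
        counts=counts, window_ms=window_ms,
        unit_ids=unit_table.unit_id.tolist(),
        train_ids=[t.train_id for t in trains],
        analyzed=analyzed_mask(trains),
        meta={"clipped_rates": n_clip},
    )
    return tensor, GroundTruth(units=unit_table)


def _sample_kernel_times(rng, n, latency, duration):
    # phasic half-cosine bump: density ~ sin(pi x / d) on [0, d]
    u = rng.random(n)
    return latency + duration / np.pi * np.arccos(1.0 - 2.0 * u)


def simulate_population_spikes(
    cfg: SpikeSimConfig,
    trains: Sequence[DeflectionTrain],
    seed=0,
) -> tuple[SessionBundle, GroundTruth]:
    """Simulate spike times for a population across a session's trains.

    Spikes are an inhomogeneous Poisson process: homogeneous spontaneous
    rate over the trial span plus, for driven units, a phasic kernel after
    each deflection whose expected count follows
    :func:`expected_evoked_counts`.  Negative instantaneous rates (possible
    for strong negative deviant terms) are clipped at zero and counted in
    the bundle metadata.
    """
    rng = _as_rng(seed)
    unit_table = make_unit_table(cfg, rng)
    lam = expected_evoked_counts(cfg, unit_table, trains)
    n_clip = int(np.sum(lam < 0))
    lam = np.clip(lam, 0.0, None)
    t0, t1 = cfg.trial_span_s
    span = t1 - t0
    onsets = np.stack([t.onsets for t in trains])  # (T, D)

    units = []
    for ui in range(len(unit_table)):
        evoked_counts = rng.poisson(lam[ui])                    # (T, D)
        base_counts = rng.poisson(cfg.base_rate * span, size=len(trains))
        spike_times: dict[int, np.ndarray] = {}
        for ti, train in enumerate(trains):
            ev_n = evoked_counts[ti]
            total_ev = int(ev_n.sum())
            ev = np.repeat(onsets[ti], ev_n)
            ev = ev + _sample_kernel_times(rng, total_ev, cfg.kernel_latency_s,
                                           cfg.kernel_duration_s)
            sp = np.concatenate([ev, t0 + span * rng.random(base_counts[ti])])
            if sp.size:
                spike_times[train.train_id] = np.sort(sp)
        row = unit_table.iloc[ui]
        units.append(UnitRecord(
            unit_id=int(row.unit_id), spike_times=spike_times,
            depth_um=float(row.depth_um), waveform_width_ms=float(row.width_ms),
            layer=assign_layer(float(row.depth_um)),
            cell_class=classify_waveform(float(row.width_ms)),
        ))
    bundle = SessionBundle(trains=list(trains), units=units,
                           metadata={"clipped_rates": n_clip})
    return bundle, GroundTruth(units=unit_table)


def simulate_drift_binned(
    n_trials: int,
    rate_start_hz: float,
    rate_end_hz: float,
    seed=0,
    n_deflections: int = 7,
    n_bins: int = 6,
    period_s: float = 0.1,
) -> np.ndarray:
    """Binned counts of a unit with a slow rate drift and no stimulus locking.

    The rate ramps linearly from ``rate_start_hz`` (pre-stimulus epoch) to
    ``rate_end_hz`` (end of the train); output shape matches the driven
    classifier's ``(n_trials, 1 + n_deflections, n_bins)`` layout.
    """
    rng = _as_rng(seed)
    n_periods = n_deflections + 1
    t = (np.arange(n_periods * n_bins) + 0.5) * (period_s / n_bins)
    total = n_periods * period_s
    rate = rate_start_hz + (rate_end_hz - rate_start_hz) * t / total
    lam = rate * (period_s / n_bins)
    return rng.poisson(lam, size=(n_trials, n_periods * n_bins)).reshape(
        n_trials, n_periods, n_bins)


# ---------------------------------------------------------------------------
# calcium simulation
# ---------------------------------------------------------------------------

def gcamp_kernel(frame_rate: float, rise_s: float = 0.18, decay_s: float = 1.5,
                 length_s: float = 8.0) -> np.ndarray:
    """Double-exponential GCaMP6s-like impulse response, normalized to peak 1."""
    t = np.arange(0, length_s, 1.0 / frame_rate)
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k / k.max()


@dataclass
class CalciumSimConfig:
    """Parameters of the L6 two-photon trace simulator."""

    n_rois: int = 300
    driven_fraction: float = 0.13
    frame_rate: float = 5.0
    n_trials_per_condition: int = 60
    conditions: tuple[str, ...] = ("control",)
    trial_period_s: float = 6.0
    stim_onset_in_trial_s: float = 2.0
    stim_duration_s: float = 0.7
    baseline_amps: tuple[float, float] = (20.0, 30.0)
    deviant_fracs: tuple[float, float] = (-0.2, 0.2)
    response_peak_dff: float = 1.2         # evoked dF/F peak at reference amp
    amplitude_exponent: float = 1.0        # response ~ (amp / ref) ** exponent
    noise_sd_dff: float = 0.05
    f0_range: tuple[float, float] = (80.0, 120.0)
    f0_drift_frac: float = 0.05
    f0_drift_period_s: float = 300.0
    neuropil_contamination: float = 0.3
    spont_event_rate_hz: float = 0.02      # sparse spontaneous transients
    opto_shuffle_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.frame_rate < 5.0:
            raise ConfigError("frame rate must be >= 5 Hz")
        if not 0 <= self.driven_fraction <= 1:
            raise ConfigError("driven_fraction must lie in [0, 1]")


def simulate_calcium(cfg: CalciumSimConfig, seed=0):
    """Simulate ROI fluorescence traces with known evoked structure.

    Returns ``(RoiTraceSet, GroundTruth)``.  Driven ROIs respond to each
    stimulus with a GCaMP-kernel transient whose amplitude scales with
    stimulus amplitude; under the ``weak_laser`` condition a fraction of the
    driven ensemble is swapped with previously silent ROIs (suppressed /
    facilitated), preserving the mean population response.
    """
    from .calcium import RoiTraceSet  # local import to avoid a cycle

    rng = _as_rng(seed)
    n_trials = cfg.n_trials_per_condition * len(cfg.conditions)
    dur = n_trials * cfg.trial_period_s
    times = np.arange(0, dur, 1.0 / cfg.frame_rate)
    n_frames = times.size

    # trial table: interleave conditions, randomize stimulus type
    rows = []
    for k in range(n_trials):
        cond = cfg.conditions[k % len(cfg.conditions)]
        onset = k * cfg.trial_period_s + cfg.stim_onset_in_trial_s
        kind = rng.integers(4)  # 0: small, 1: large, 2: dev-, 3: dev+
        amp = cfg.baseline_amps[kind] if kind < 2 else float(np.mean(cfg.baseline_amps))
        sign = 0 if kind < 2 else (-1 if kind == 2 else +1)
        eff_amp = amp * (1.0 + (cfg.deviant_fracs[1] if sign > 0 else
                                cfg.deviant_fracs[0] if sign < 0 else 0.0))
        rows.append(dict(trial=k, condition=cond, onset_s=onset,
                         offset_s=onset + cfg.stim_duration_s,
                         amplitude=amp, effective_amplitude=eff_amp,
                         deviant_sign=sign))
    trials = pd.DataFrame(rows)

    driven_ctrl = rng.random(cfg.n_rois) < cfg.driven_fraction
    driven_laser = driven_ctrl.copy()
    roles = np.array(["none"] * cfg.n_rois, dtype=object)
    if "weak_laser" in cfg.conditions:
        d_idx = np.flatnonzero(driven_ctrl)
        s_idx = np.flatnonzero(~driven_ctrl)
        k = min(int(round(cfg.opto_shuffle_fraction * d_idx.size)), s_idx.size)
        sup = rng.choice(d_idx, size=k, replace=False)
        fac = rng.choice(s_idx, size=k, replace=False)
        driven_laser[sup] = False
        driven_laser[fac] = True
        roles[sup] = "laser_suppressed"
        roles[fac] = "laser_facilitated"

    gain = np.where(driven_ctrl | driven_laser,
                    cfg.response_peak_dff * rng.uniform(0.7, 1.3, cfg.n_rois), 0.0)
    kern = gcamp_kernel(cfg.frame_rate)
    ref = float(np.mean(cfg.baseline_amps))

    dff_true = np.zeros((cfg.n_rois, n_frames))
    onset_idx = np.searchsorted(times, trials.onset_s.to_numpy())
    is_laser = (trials.condition == "weak_laser").to_numpy()
    amp_scale = (trials.effective_amplitude.to_numpy() / ref) ** cfg.amplitude_exponent
    for ti in range(n_trials):
        act = driven_laser if is_laser[ti] else driven_ctrl
        i0 = onset_idx[ti]
        seg = slice(i0, min(i0 + kern.size, n_frames))
        npts = seg.stop - seg.start
        dff_true[act, seg] += np.outer(gain[act], kern[:npts])[:, :npts] * amp_scale[ti]
    # sparse spontaneous transients in all ROIs
    n_spont = rng.poisson(cfg.spont_event_rate_hz * dur, size=cfg.n_rois)
    for r in range(cfg.n_rois):
        for t_ev in rng.uniform(0, dur, size=n_spont[r]):
            i0 = int(t_ev * cfg.frame_rate)
            seg = slice(i0, min(i0 + kern.size, n_frames))
            dff_true[r, seg] += 0.5 * kern[:seg.stop - seg.start]

    f0_base = rng.uniform(*cfg.f0_range, size=cfg.n_rois)
    phase = rng.uniform(0, 2 * np.pi, size=cfg.n_rois)
    drift = 1.0 + cfg.f0_drift_frac * np.sin(
        2 * np.pi * times[None, :] / cfg.f0_drift_period_s + phase[:, None])
    f0 = f0_base[:, None] * drift
    noise = rng.normal(0, cfg.noise_sd_dff, size=(cfg.n_rois, n_frames))
    f = f0 * (1.0 + dff_true + noise)
    np.clip(f, 1e-3, None, out=f)

    np_base = 0.5 * f0_base
    np_noise = rng.normal(0, cfg.noise_sd_dff, size=(cfg.n_rois, n_frames))
    f_np = np_base[:, None] * drift * (
        1.0 + cfg.neuropil_contamination * dff_true + np_noise)
    np.clip(f_np, 1e-3, None, out=f_np)

    traces = RoiTraceSet(F=f, F_neuropil=f_np, frame_times=times, trials=trials)
    rois = pd.DataFrame(dict(
        roi_id=np.arange(cfg.n_rois), driven_control=driven_ctrl,
        driven_laser=driven_laser, gain=gain, f0_base=f0_base,
        opto_role=roles))
    gt = GroundTruth(rois=rois, extra={"dff_true": dff_true})
    return traces, gt


def simulate_imaging_frames(
    seed=0,
    shape: tuple[int, int] = (64, 64),
    n_frames: int = 300,
    n_rois: int = 8,
    roi_radius: int = 3,
    flagged_line_step: int = 4,
    line_artifact: float = 0.05,
    global_artifact: float = 0.01,
    led_block_frames: int = 20,
    frame_rate: float = 5.0,
):
    """Simulate a small two-photon frame stack with a flyback light artifact.

    Returns ``(frames, clean_frames, label_masks, flagged_lines, led_on,
    frame_times)``.  The optogenetic LED is pulsed in alternating blocks of
    ``led_block_frames`` frames; on LED-on frames the flyback pulses
    brighten every ``flagged_line_step``-th scan line by ``line_artifact``
    (fractional) and the whole frame by ``global_artifact`` (residual
    scattered light, the component that line interpolation cannot remove
    and the neuropil brightening profile does).
    """
    rng = _as_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    background = 20.0 + 5.0 * np.sin(xx / w * np.pi) * np.sin(yy / h * np.pi)

    labels = np.zeros(shape, dtype=np.int32)
    centers = []
    while len(centers) < n_rois:
        cy, cx = rng.integers(8, h - 8), rng.integers(8, w - 8)
        if all((cy - y) ** 2 + (cx - x) ** 2 > (4 * roi_radius) ** 2 for y, x in centers):
            centers.append((cy, cx))
    for i, (cy, cx) in enumerate(centers):
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= roi_radius ** 2
        labels[mask] = i + 1

    kern = gcamp_kernel(frame_rate)
    activity = np.zeros((n_rois, n_frames))
    for r in range(n_rois):
        for t_ev in rng.uniform(0, n_frames / frame_rate, size=rng.poisson(3)):
            i0 = int(t_ev * frame_rate)
            seg = slice(i0, min(i0 + kern.size, n_frames))
            activity[r, seg] += kern[:seg.stop - seg.start]

    clean = np.empty((n_frames, h, w))
    clean[:] = background[None, :, :]
    for i in range(n_rois):
        m = labels == i + 1
        clean[:, m] += (60.0 * (1.0 + activity[i]))[:, None]
    clean += rng.normal(0, 0.5, size=clean.shape)

    flagged = np.arange(0, h, flagged_line_step)
    led_on = (np.arange(n_frames) // led_block_frames) % 2 == 1
    frames = clean.copy()
    frames[led_on] *= 1.0 + global_artifact
    on_idx = np.flatnonzero(led_on)
    frames[np.ix_(on_idx, flagged)] *= 1.0 + line_artifact
    frame_times = np.arange(n_frames) / frame_rate
    return frames, clean, labels, flagged, led_on, frame_times


# ---------------------------------------------------------------------------
# behavioral simulation
# ---------------------------------------------------------------------------

@dataclass
class PsychObserver:
    """Cumulative-Gaussian observer with a deviant detection benefit.

    P(hit | amp, no deviant) = guess + (1 - guess - lapse) * Phi((amp - mu) / sigma);
    deviant-containing trials get an additive benefit ``deviant_benefit`` on
    sub-threshold amplitudes (below ``benefit_band`` * mu).
    """

    mu: float = 15.0            # mm/s threshold
    sigma: float = 3.0          # psychometric slope
    guess: float = 0.1
    lapse: float = 0.02
    deviant_benefit: float = 0.15
    benefit_band: float = 0.6   # deviants help below this fraction of mu

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.sigma <= 0:
            raise ConfigError("mu and sigma must be positive")
        if self.guess < 0 or self.lapse < 0 or self.guess + self.lapse >= 1:
            raise ConfigError("guess/lapse rates must be non-negative and sum below 1")

    def hit_probability(self, amp, deviant_present=False) -> np.ndarray:
        from scipy.stats import norm
        amp = np.asarray(amp, dtype=float)
        p = self.guess + (1 - self.guess - self.lapse) * norm.cdf(
            (amp - self.mu) / self.sigma)
        if np.ndim(deviant_present) == 0:
            benefit = self.deviant_benefit if deviant_present else 0.0
        else:
            benefit = self.deviant_benefit * np.asarray(deviant_present)
        p = p + benefit * (amp < self.benefit_band * self.mu) * (amp > 0)
        return np.clip(p, 0.0, 1.0 - self.lapse)


def simulate_detection_behavior(
    psych: PsychObserver,
    n_trials: int,
    seed=0,
    max_amp: float = 30.0,
    catch_fraction: float = 0.1,
    max_amp_fraction: float = 0.1,
    deviant_fraction: float = 0.5,
    laser_fraction: float = 0.0,
    laser_removes_benefit: bool = True,
    deviant_positions: Sequence[int] = (2, 3, 4),
    late_deviant_fraction: float = 0.1,
    early_lick_rate: float = 0.02,
    session_id: int = 0,
) -> pd.DataFrame:
    """Simulate a go/no-go detection session as a behavior trial table.

    Amplitudes are uniform on (0, ``max_amp``) with a fraction of
    maximum-amplitude and catch (zero-amplitude) trials; half of the
    stimulus trials contain a direction deviant at positions 2-4 (0-based,
    onsets 200-400 ms), with a small fraction of late deviants (position 5,
    500 ms) and early spontaneous licks so downstream exclusion rules are
    exercised.
    """
    rng = _as_rng(seed)
    amp = rng.uniform(0, max_amp, size=n_trials)
    u = rng.random(n_trials)
    amp[u < catch_fraction] = 0.0
    amp[u > 1 - max_amp_fraction] = max_amp
    deviant = (rng.random(n_trials) < deviant_fraction) & (amp > 0)
    laser = rng.random(n_trials) < laser_fraction

    pos = rng.choice(deviant_positions, size=n_trials)
    late = rng.random(n_trials) < late_deviant_fraction
    pos[late] = 5
    dev_time_ms = np.where(deviant, pos * 100.0, np.nan)

    benefit_on = deviant & ~(laser & laser_removes_benefit)
    p_hit = psych.hit_probability(amp, benefit_on)
    responded = rng.random(n_trials) < p_hit

    rt = np.full(n_trials, np.nan)
    n_resp = int(responded.sum())
    rt[responded] = rng.lognormal(np.log(300.0), 0.3, size=n_resp)
    early = responded & (rng.random(n_trials) < early_lick_rate)
    rt[early] = rng.uniform(5.0, 45.0, size=int(early.sum()))

    response = np.where(amp > 0,
                        np.where(responded, "hit", "miss"),
                        np.where(responded, "false_alarm", "correct_reject"))
    return pd.DataFrame(dict(
        amplitude=amp, deviant_present=deviant, deviant_time_ms=dev_time_ms,
        response=response, reaction_time_ms=rt, laser=laser,
        session_id=session_id))
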