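"""dF/F extraction, light-artifact correction, and encoding statistics for
two-photon ROI traces.

The baseline F0 is a sliding 30th percentile over a 200 s centered window
(shrinking at trace edges), dF/F = (F - F0) / F0.  Neuropil annuli are
built by dilating each somatic ROI 20 px along the scan (x) direction and
excluding all somata; their traces estimate the residual image-brightening
profile of interleaved optogenetic flyback pulses, which is removed in two
stages (scan-line interpolation, then session-mean profile subtraction).
Stimulus-driven ROIs are those whose 10% quantile of stimulus-period dF/F
exceeds the 90% quantile of the pre-stimulus period.  Evoked responses are
integrated over a 0-2 s window after stimulus offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import wilcoxon

from .change_coding import bootstrap_median_ci

PRE_WINDOW_S = (-1.5, 0.0)     # relative to stimulus onset
STIM_WINDOW_S = (0.5, 1.5)     # relative to stimulus onset
EVOKED_WINDOW_S = (0.0, 2.0)   # relative to stimulus offset


@dataclass
class RoiTraceSet:
    """Fluorescence traces for a session's ROIs.

    ``trials`` is a DataFrame with at least ``onset_s``, ``offset_s``,
    ``amplitude``, ``deviant_sign`` and (optionally) ``condition`` columns.
    """

    F: np.ndarray                      # (n_rois, n_frames)
    F_neuropil: np.ndarray | None
    frame_times: np.ndarray
    trials: pd.DataFrame | None = None
    F0: np.ndarray | None = None
    dff: np.ndarray | None = None
    masks: np.ndarray | None = None    # label image
    responsive: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.frame_times)))

    @property
    def n_rois(self) -> int:
        return self.F.shape[0]


def compute_dff(
    F: np.ndarray,
    frame_rate: float,
    window_s: float = 200.0,
    percentile: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-percentile baseline and fractional fluorescence change.

    ``F0[t]`` is the ``percentile``-th percentile of F over a centered
    ``window_s`` window (shrinking at the trace edges);
    ``dff = (F - F0) / F0``.  Raises on non-positive baselines, which
    indicate pathological input.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n = F.shape[1]
    win = int(round(window_s * frame_rate))
    if win >= n:
        warnings.warn("percentile window longer than trace; using full trace")
        win = n
    win = max(win, 1)
    f0 = (pd.DataFrame(F.T)
          .rolling(win, center=True, min_periods=1)
          .quantile(percentile / 100.0)
          .to_numpy().T)
    if np.any(f0 <= 0):
        raise ValueError("non-positive F0 baseline (data pathology)")
    dff = (F - f0) / f0
    return f0, dff


def neuropil_annulus(
    roi_mask: np.ndarray,
    all_roi_masks: np.ndarray,
    erode_x_px: int = 20,
) -> np.ndarray:
    """Annulus mask around a somatic ROI, extended along x only.

    The ROI is dilated ``erode_x_px`` pixels in each x direction; the ROI
    itself and every other somatic ROI are excluded.  An empty annulus is
    returned as an all-False mask (flag the ROI upstream).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    struct = np.ones((1, 2 * erode_x_px + 1), dtype=bool)
    dilated = ndimage.binary_dilation(roi_mask, structure=struct)
    return dilated & ~np.asarray(all_roi_masks, dtype=bool)


def annulus_masks_from_labels(labels: np.ndarray, erode_x_px: int = 20):
    """Per-ROI annulus masks from a label image (labels 1..n)."""
    somata = labels > 0
    out = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        out[int(lab)] = neuropil_annulus(labels == lab, somata, erode_x_px)
    return out


def extract_traces(frames: np.ndarray, masks: dict[int, np.ndarray] | np.ndarray):
    """Mean-pixel traces per ROI from a frame stack.

    ``masks`` may be a label image or a dict of boolean masks.
    """
    if isinstance(masks, np.ndarray):
        masks = {int(l): masks == l for l in np.unique(masks) if l != 0}
    traces = np.empty((len(masks), frames.shape[0]))
    for i, (lab, m) in enumerate(sorted(masks.items())):
        if not m.any():
            traces[i] = np.nan
            continue
        traces[i] = frames[:, m].mean(axis=1)
    return traces


def interpolate_flagged_lines(frames: np.ndarray, flagged_lines: np.ndarray) -> np.ndarray:
    """Stage 1: replace artifact-affected scan lines by neighbor means.

    Every flagged line is replaced by the mean of the nearest preceding and
    following unflagged lines, unconditionally (whether the LED was on or
    off); first/last lines fall back to one-sided interpolation.
    """
    frames = np.asarray(frames, dtype=float).copy()
    h = frames.shape[1]
    flagged = np.zeros(h, dtype=bool)
    flagged[np.asarray(flagged_lines, dtype=int)] = True
    clean_idx = np.flatnonzero(~flagged)
    if clean_idx.size == 0:
        raise ValueError("all scan lines flagged")
    for line in np.flatnonzero(flagged):
        prev = clean_idx[clean_idx < line]
        nxt = clean_idx[clean_idx > line]
        if prev.size and nxt.size:
            frames[:, line, :] = 0.5 * (frames[:, prev[-1], :] + frames[:, nxt[0], :])
        elif prev.size:
            frames[:, line, :] = frames[:, prev[-1], :]
        else:
            frames[:, line, :] = frames[:, nxt[0], :]
    return frames


def subtract_brightening_profile(
    roi_traces: np.ndarray,
    neuropil_traces: np.ndarray,
    baseline_percentile: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stage 2: remove the session-mean image-brightening profile.

    The fractional brightening profile is the across-neuropil-ROI mean of
    each neuropil trace relative to its own session baseline (a low
    percentile, anchoring the profile to LED-off frames); ROI traces are
    divided by (1 + profile).  Returns ``(corrected_traces, profile)``.
    """
    np_traces = np.atleast_2d(np.asarray(neuropil_traces, dtype=float))
    med = np.percentile(np_traces, baseline_percentile, axis=1, keepdims=True)
    profile = np.mean(np_traces / med - 1.0, axis=0)
    corrected = np.asarray(roi_traces, dtype=float) / (1.0 + profile)[None, :]
    return corrected, profile


def correct_light_artifact(
    frames: np.ndarray,
    flagged_lines: np.ndarray,
    masks,
    erode_x_px: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Full two-stage artifact correction from a frame stack.

    Stage 1 interpolates flagged scan lines; stage 2 subtracts the mean
    neuropil brightening profile from the somatic ROI traces.  Returns
    ``(corrected_roi_traces, profile)``.
    """
    fixed = interpolate_flagged_lines(frames, flagged_lines)
    if isinstance(masks, np.ndarray):
        label_img = masks
    else:
        raise TypeError("masks must be a label image")
    roi_traces = extract_traces(fixed, label_img)
    annuli = annulus_masks_from_labels(label_img, erode_x_px)
    np_traces = extract_traces(fixed, annuli)
    return subtract_brightening_profile(roi_traces, np_traces)


def _window_frames(times, anchors, window):
    """Boolean (n_anchors, n_frames) membership of each window."""
    lo = anchors[:, None] + window[0]
    hi = anchors[:, None] + window[1]
    return (times[None, :] >= lo) & (times[None, :] < hi)


def classify_responsive(
    traces: RoiTraceSet,
    condition: str | None = None,
    pre_window: tuple[float, float] = PRE_WINDOW_S,
    stim_window: tuple[float, float] = STIM_WINDOW_S,
) -> np.ndarray:
    """Non-overlapping-quantile responsiveness classification per ROI.

    An ROI is stimulus-driven when the 10% quantile of its stimulus-period
    dF/F (0.5-1.5 s after onset, pooled over trials of the selected
    condition) exceeds the 90% quantile of its pre-stimulus period
    (-1.5-0 s).
    """
    if traces.dff is None:
        raise ValueError("run compute_dff first")
    trials = traces.trials
    if condition is not None and "condition" in trials.columns:
        trials = trials[trials.condition == condition]
    onsets = trials.onset_s.to_numpy()
    pre = _window_frames(traces.frame_times, onsets, pre_window).any(axis=0)
    stim = _window_frames(traces.frame_times, onsets, stim_window).any(axis=0)
    if pre.sum() < 3 or stim.sum() < 3:
        raise ValueError("fewer than 3 frames in a classification window")
    q90_pre = np.quantile(traces.dff[:, pre], 0.90, axis=1)
    q10_stim = np.quantile(traces.dff[:, stim], 0.10, axis=1)
    flags = q10_stim > q90_pre
    key = condition or "all"
    traces.responsive[key] = flags
    return flags


def evoked_responses(
    traces: RoiTraceSet,
    window: tuple[float, float] = EVOKED_WINDOW_S,
) -> np.ndarray:
    """Per-ROI, per-trial mean dF/F over the post-stimulus-offset window.

    Returns an array of shape ``(n_rois, n_trials)``.
    """
    if traces.dff is None:
        raise ValueError("run compute_dff first")
    offsets = traces.trials.offset_s.to_numpy()
    out = np.empty((traces.n_rois, offsets.size))
    for ti, off in enumerate(offsets):
        sel = (traces.frame_times >= off + window[0]) & (traces.frame_times < off + window[1])
        out[:, ti] = traces.dff[:, sel].mean(axis=1)
    return out


def value_at_timepoint(
    traces: RoiTraceSet,
    t_after_onset: float = 1.0,
) -> np.ndarray:
    """dF/F at a fixed post-onset time point (nearest frame), per trial."""
    onsets = traces.trials.onset_s.to_numpy()
    idx = np.searchsorted(traces.frame_times, onsets + t_after_onset)
    idx = np.clip(idx, 0, traces.frame_times.size - 1)
    return traces.dff[:, idx]


def per_roi_laser_effect(
    values: np.ndarray,
    is_laser: np.ndarray,
    n_boot: int = 10000,
    seed=0,
    alpha: float = 0.0025,
):
    """Per-ROI significance of the laser effect via trial bootstrap.

    ``values`` is (n_rois, n_trials); for each ROI the difference of
    laser-trial and control-trial means is bootstrapped (two-sided,
    add-one); returns ``(diff, p, significant)`` arrays.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = values[:, is_laser]
    b = values[:, ~is_laser]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 trials per condition")
    diff = a.mean(axis=1) - b.mean(axis=1)
    ia = rng.integers(0, a.shape[1], size=(n_boot, a.shape[1]))
    ib = rng.integers(0, b.shape[1], size=(n_boot, b.shape[1]))
    n_rois = values.shape[0]
    p = np.empty(n_rois)
    for r in range(n_rois):
        d = a[r][ia].mean(axis=1) - b[r][ib].mean(axis=1)
        p_pos = (1 + np.sum(d <= 0)) / (1 + n_boot)
        p_neg = (1 + np.sum(d >= 0)) / (1 + n_boot)
        p[r] = min(1.0, 2 * min(p_pos, p_neg))
    return diff, p, p < alpha


def evoked_encoding_stats(
    responses: np.ndarray,
    trials: pd.DataFrame,
    contrast: str,
    roi_subset: np.ndarray | None = None,
    condition: str | None = None,
    min_trials: int = 5,
    n_boot: int = 10000,
    seed=0,
    train_split: np.ndarray | None = None,
) -> dict:
    """Per-ROI evoked differences across a stimulus contrast + population stats.

    ``contrast`` is one of ``baseline_amp`` (large vs small baseline
    stimuli), ``deviant_sign`` (amplitude-increase vs -decrease deviants),
    or ``laser`` (laser vs control trials).  Returns per-ROI mean evoked
    differences with the population signed-rank p-value and a bootstrapped
    median CI.  ROIs with fewer than ``min_trials`` trials in either
    condition are dropped with a reason.

    ``train_split`` (boolean per trial) supports the cross-validated
    variant: responsiveness is decided on the training trials upstream and
    only held-out (``~train_split``) trials enter the contrast here, which
    controls for regression to the mean when the same data would otherwise
    select and evaluate ROIs.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = trials.reset_index(drop=True)
    use = np.ones(len(t), dtype=bool)
    if condition is not None and "condition" in t.columns:
        use &= (t.condition == condition).to_numpy()
    if train_split is not None:
        use &= ~np.asarray(train_split)
    if contrast == "baseline_amp":
        no_dev = (t.deviant_sign == 0).to_numpy()
        amps = t.amplitude[no_dev & use]
        thresh = 0.5 * (amps.min() + amps.max())   # midrange split: large vs small
        cond_a = use & no_dev & (t.amplitude >= thresh).to_numpy()
        cond_b = use & no_dev & (t.amplitude < thresh).to_numpy()
    elif contrast == "deviant_sign":
        cond_a = use & (t.deviant_sign == 1).to_numpy()
        cond_b = use & (t.deviant_sign == -1).to_numpy()
    elif contrast == "laser":
        lz = (t.condition == "weak_laser").to_numpy()
        cond_a = use & lz
        cond_b = use & ~lz
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    if cond_a.sum() < min_trials or cond_b.sum() < min_trials:
        raise ValueError("degenerate condition counts for the contrast")

    resp = responses if roi_subset is None else responses[roi_subset]
    diff = resp[:, cond_a].mean(axis=1) - resp[:, cond_b].mean(axis=1)
    finite = np.isfinite(diff)
    dropped = int(np.sum(~finite))
    d = diff[finite]
    p = float(wilcoxon(d).pvalue) if np.any(d != 0) else 1.0
    ci = bootstrap_median_ci(d, n_boot, rng)
    return {"per_roi_diff": diff, "p_signed_rank": p, "ci_median": ci,
            "n_rois": int(d.size), "n_dropped": dropped,
            "n_trials": (int(cond_a.sum()), int(cond_b.sum()))}
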