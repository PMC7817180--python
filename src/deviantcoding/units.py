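"""Spike-count extraction, layer mapping, and RS/FS classification."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ConfigError, SessionBundle

# Depth-to-layer mapping (um below pia); boundaries go to the deeper layer.
LAYER_BOUNDS = ((100.0, 350.0, "L2/3"), (350.0, 450.0, "L4"), (450.0, 650.0, "L5"))
L6_FLOOR = 650.0


@dataclass
class CountTensor:
    """Spike counts per (unit, trial, deflection) in the response window.

    ``analyzed[t, d]`` is False for deflections after a deviant (those are
    excluded from all downstream analyses) -- the deviant deflection itself
    is analyzed.
    """

    counts: np.ndarray  # (n_units, n_trials, n_deflections) int
    window_ms: float
    unit_ids: list[int]
    train_ids: list[int]
    analyzed: np.ndarray  # (n_trials, n_deflections) bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape[1:] != self.analyzed.shape:
            raise ValueError("analyzed mask shape mismatch")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    def unit_index(self, unit_id: int) -> int:
        return self.unit_ids.index(unit_id)

    def train_index(self, train_id: int) -> int:
        return self.train_ids.index(train_id)

    def subset_units(self, indices) -> "CountTensor":
        """Restrict to a subset of units (e.g. the driven population)."""
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return CountTensor(
            counts=self.counts[indices],
            window_ms=self.window_ms,
            unit_ids=[self.unit_ids[i] for i in indices],
            train_ids=list(self.train_ids),
            analyzed=self.analyzed,
            meta=dict(self.meta),
        )


def analyzed_mask(trains) -> np.ndarray:
    """Boolean (n_trials, n_deflections) mask excluding post-deviant stimuli."""
    n_defl = trains[0].n_deflections
    mask = np.ones((len(trains), n_defl), dtype=bool)
    for i, t in enumerate(trains):
        if t.deviant_index is not None:
            mask[i, t.deviant_index + 1:] = False
    return mask


def per_deflection_counts(bundle: SessionBundle, window_ms: float = 100.0) -> CountTensor:
    """Count spikes in ``[onset, onset + window)`` for every deflection.

    The window must not exceed the inter-deflection interval, so windows are
    non-overlapping.
    """
    trains = bundle.trains
    w = window_ms / 1000.0
    for t in trains:
        iv = np.diff(t.onsets)
        if iv.size and w > iv.min() + 1e-12:
            raise ConfigError(
                f"window {window_ms} ms exceeds inter-deflection interval of "
                f"train {t.train_id}"
            )
    n_defl = trains[0].n_deflections
    counts = np.zeros((len(bundle.units), len(trains), n_defl), dtype=np.int64)
    for ui, unit in enumerate(bundle.units):
        for ti, train in enumerate(trains):
            spikes = unit.spikes_for(train.train_id)
            if spikes.size == 0:
                continue
            lo = np.searchsorted(spikes, train.onsets, side="left")
            hi = np.searchsorted(spikes, train.onsets + w, side="left")
            counts[ui, ti] = hi - lo
    return CountTensor(
        counts=counts,
        window_ms=window_ms,
        unit_ids=[u.unit_id for u in bundle.units],
        train_ids=[t.train_id for t in trains],
        analyzed=analyzed_mask(trains),
    )


def assign_layer(depth_um: float) -> str:
    """Map recording depth (um) to a cortical layer.

    L2/3: 100-350, L4: 350-450, L5: 450-650, L6: >650; exact boundaries are
    assigned to the deeper layer; depths above 100 um are unassigned (L1).
    """
    if depth_um < 0:
        raise ValueError("depth must be non-negative")
    if depth_um >= L6_FLOOR:
        return "L6"
    for lo, hi, layer in LAYER_BOUNDS:
        if lo <= depth_um < hi:
            return layer
    return "unassigned"


def classify_waveform(width_ms: float, threshold_ms: float = 0.4) -> str:
    """RS/FS split by spike trough-to-peak width: FS below the threshold."""
    if width_ms <= 0:
        raise ValueError("waveform width must be positive")
    return "FS" if width_ms < threshold_ms else "RS"


def annotate_units(bundle: SessionBundle, fs_threshold_ms: float = 0.4) -> SessionBundle:
    """Fill derived ``layer`` and ``cell_class`` fields in place."""
    for u in bundle.units:
        u.layer = assign_layer(u.depth_um)
        u.cell_class = classify_waveform(u.waveform_width_ms, fs_threshold_ms)
    return bundle


def psth(unit, train_ids, window: tuple[float, float], bin_ms: float) -> np.ndarray:
    """Trial-averaged firing rate (Hz) in ``bin_ms`` bins over ``window``.

    ``bin_ms`` must divide the window length.
    """
    t0, t1 = window
    span_ms = (t1 - t0) * 1000.0
    n_bins = span_ms / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ConfigError("bin_ms must divide the window length")
    n_bins = int(round(n_bins))
    if len(train_ids) == 0:
        raise ValueError("psth requires at least one trial")
    edges = t0 + np.arange(n_bins + 1) * (bin_ms / 1000.0)
    acc = np.zeros(n_bins)
    for tid in train_ids:
        spikes = unit.spikes_for(tid)
        acc += np.histogram(spikes, bins=edges)[0]
    return acc / len(train_ids) / (bin_ms / 1000.0)


def classifier_binned_counts(
    bundle: SessionBundle,
    n_bins: int = 6,
    period_ms: float = 100.0,
    include_pre: bool = True,
) -> np.ndarray:
    """Per-trial binned counts for the driven classifier.

    Returns an array of shape ``(n_units, n_trials, n_periods, n_bins)``
    where period 0 is the 100 ms pre-stimulus epoch (if ``include_pre``)
    and subsequent periods are the successive deflection epochs, each
    divided into ``n_bins`` equal bins.
    """
    trains = bundle.trains
    n_defl = trains[0].n_deflections
    p = period_ms / 1000.0
    n_periods = n_defl + (1 if include_pre else 0)
    out = np.zeros((len(bundle.units), len(trains), n_periods, n_bins), dtype=np.int64)
    rel_edges = np.arange(n_bins + 1) / n_bins * p
    for ti, train in enumerate(trains):
        starts = list(train.onsets)
        if include_pre:
            starts = [train.onsets[0] - p] + starts
        edges = np.asarray(starts)[:, None] + rel_edges[None, :]
        for ui, unit in enumerate(bundle.units):
            spikes = unit.spikes_for(train.train_id)
            if spikes.size == 0:
                continue
            idx = np.searchsorted(spikes, edges.ravel(), side="left")
            out[ui, ti] = np.diff(idx.reshape(len(starts), n_bins + 1), axis=1)
    return out
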