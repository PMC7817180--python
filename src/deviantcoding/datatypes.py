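"""Core domain types for deviant-encoding analysis sessions.

A recording session is modelled as a set of stimulus trains (each train is
one trial: seven vibrissa deflections at 10 Hz, optionally containing one
amplitude deviant) and a set of sorted units with per-trial spike times.
Times are in seconds and train-relative; deflection indices are 0-based;
count windows are half-open ``[onset, onset + w)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import numpy as np
import yaml

OPTO_CONDITIONS = ("control", "weak_laser", "strong_laser")
LAYERS = ("L2/3", "L4", "L5", "L6")


class SchemaError(ValueError):
    """A table is missing columns or contains malformed rows."""


class IntegrityError(ValueError):
    """Cross-references between tables do not resolve."""


class ConfigError(ValueError):
    """Invalid analysis or simulation configuration."""


@dataclass
class DeflectionTrain:
    """One deflection train (= one trial).

    Parameters
    ----------
    onsets
        Deflection onset times in seconds, train-relative, strictly increasing.
    amplitudes
        Per-deflection velocity amplitudes (mm/s); equal to
        ``baseline_amplitude`` before the deviant position.
    deviant_index
        0-based position of the amplitude deviant, or ``None``.
    deviant_sign
        +1 for an amplitude increase, -1 for a decrease, 0 if no deviant.
    """

    train_id: int
    onsets: np.ndarray
    amplitudes: np.ndarray
    baseline_amplitude: float
    deviant_index: int | None = None
    deviant_sign: int = 0
    opto_condition: str = "control"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.onsets.ndim != 1 or self.onsets.size != self.amplitudes.size:
            raise SchemaError("onsets and amplitudes must be 1-D and equal length")
        if np.any(np.diff(self.onsets) <= 0):
            raise SchemaError(f"train {self.train_id}: onsets must be strictly increasing")
        if np.any(self.amplitudes <= 0):
            raise SchemaError(f"train {self.train_id}: amplitudes must be positive")
        if self.opto_condition not in OPTO_CONDITIONS:
            raise SchemaError(
                f"train {self.train_id}: unknown opto_condition {self.opto_condition!r}"
            )
        has_dev = self.deviant_index is not None
        if has_dev != (self.deviant_sign != 0):
            raise SchemaError(
                f"train {self.train_id}: deviant_sign must be nonzero iff "
                "deviant_index is present"
            )
        if has_dev:
            di = int(self.deviant_index)
            if not (0 < di < self.n_deflections):
                raise SchemaError(
                    f"train {self.train_id}: a deviant requires preceding baseline "
                    f"deflections (got index {di})"
                )
            pre = self.amplitudes[:di]
            if not np.allclose(pre, self.baseline_amplitude):
                raise SchemaError(
                    f"train {self.train_id}: amplitudes before the deviant must equal "
                    "baseline_amplitude"
                )

    @property
    def n_deflections(self) -> int:
        return int(self.onsets.size)


@dataclass
class UnitRecord:
    """A sorted single unit with per-trial spike times.

    ``spike_times`` maps train_id -> sorted array of spike times (s,
    train-relative; may be negative for pre-stimulus spikes). ``layer`` and
    ``cell_class`` are derived from depth / waveform width by
    :mod:`deviantcoding.units` when absent.
    """

    unit_id: int
    spike_times: dict[int, np.ndarray]
    depth_um: float
    waveform_width_ms: float
    layer: str | None = None
    cell_class: str | None = None
    driven: bool | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth_um < 0:
            raise SchemaError(f"unit {self.unit_id}: negative depth")
        if self.waveform_width_ms <= 0:
            raise SchemaError(f"unit {self.unit_id}: waveform width must be positive")
        for tid, t in self.spike_times.items():
            t = np.asarray(t, dtype=float)
            if np.any(np.diff(t) < 0):
                t = np.sort(t)
            self.spike_times[tid] = t

    def spikes_for(self, train_id: int) -> np.ndarray:
        return self.spike_times.get(train_id, np.empty(0))


@dataclass
class SessionBundle:
    """A validated session: trains, units, and metadata."""

    trains: list[DeflectionTrain]
    units: list[UnitRecord]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        tids = [t.train_id for t in self.trains]
        if len(set(tids)) != len(tids):
            raise IntegrityError("duplicate train_id in session")
        uids = [u.unit_id for u in self.units]
        if len(set(uids)) != len(uids):
            raise IntegrityError("duplicate unit_id in session")
        known = set(tids)
        for u in self.units:
            for tid in u.spike_times:
                if tid not in known:
                    raise IntegrityError(
                        f"unit {u.unit_id} references unknown train_id {tid}"
                    )

    @property
    def train_ids(self) -> list[int]:
        return [t.train_id for t in self.trains]

    def train_by_id(self, train_id: int) -> DeflectionTrain:
        for t in self.trains:
            if t.train_id == train_id:
                return t
        raise IntegrityError(f"unknown train_id {train_id}")


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters shared across pipeline stages.

    All stochastic stages take an explicit seed (``rng_seed``); identical
    config + seed yields bit-identical outputs.
    """

    response_window_ms: float = 100.0
    surrogate_draws: int = 1000
    bootstrap_draws: int = 10000
    entropy_bins: int = 15
    rng_seed: int = 0
    alpha: float = 0.05
    min_units: int = 20
    driven_p_level: float = 0.03
    driven_se_bound: float = 0.002
    classifier_bins: int = 6
    fs_width_threshold_ms: float = 0.4

    def __post_init__(self) -> None:
        for name in ("surrogate_draws", "bootstrap_draws", "entropy_bins",
                     "min_units", "classifier_bins"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0 < self.alpha < 1) or not (0 < self.driven_p_level < 1):
            raise ConfigError("significance levels must lie in (0, 1)")
        if self.response_window_ms <= 0:
            raise ConfigError("response_window_ms must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw: Mapping[str, Any] = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
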