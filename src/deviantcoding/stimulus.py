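"""Deviant-containing deflection trains and trial-matching procedures.

The stimulus paradigm is a train of repeated vibrissa deflections (default
seven at 10 Hz) at a fixed baseline amplitude, with at most one amplitude
deviant (+/- 5-15% of baseline) inserted after at least two baseline
deflections.  Because deviant positions are randomized, baseline deflections
outnumber deviant deflections and occur earlier in the train on average;
the histogram-matching procedures here subsample deflection sets so that
comparisons are not biased by position-in-train (adaptation) or by the
amplitude distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ConfigError, DeflectionTrain

#: default allowed 0-based deviant positions: a deviant follows 2-6 repeated
#: baseline deflections in a 7-deflection train
EPHYS_DEVIANT_POSITIONS = (2, 3, 4, 5, 6)
#: head-fixed behavior uses earlier deviants (onsets 200-400 ms)
BEHAVIOR_DEVIANT_POSITIONS = (2, 3, 4)


@dataclass
class MatchedSets:
    """Two deflection sets with identical histograms of the matching key.

    ``deviant_set`` and ``baseline_set`` are DataFrames of deflection
    references; for position matching the columns are ``(train_id,
    deflection)``, for amplitude matching ``(train_id, deflection,
    amplitude)``.
    """

    deviant_set: pd.DataFrame
    baseline_set: pd.DataFrame
    matched_on: str

    def __post_init__(self) -> None:
        if len(self.deviant_set) != len(self.baseline_set):
            raise ValueError("matched sets must have equal cardinality")


def build_train(
    baseline_amp: float,
    n: int = 7,
    rate: float = 10.0,
    deviant_index: int | None = None,
    deviant_frac: float = 0.0,
    train_id: int = 0,
    opto_condition: str = "control",
) -> DeflectionTrain:
    """Construct a deflection train with an optional amplitude deviant.

    Onsets are at ``k / rate`` seconds; the deflection at ``deviant_index``
    has amplitude ``baseline_amp * (1 + deviant_frac)``; all others are at
    baseline.
    """
    if baseline_amp <= 0:
        raise ConfigError("baseline amplitude must be positive")
    if not (-0.15 - 1e-12 <= deviant_frac <= 0.15 + 1e-12):
        raise ConfigError("deviant_frac must lie in [-0.15, +0.15]")
    if (deviant_index is None) != (deviant_frac == 0):
        raise ConfigError("deviant_index and a nonzero deviant_frac go together")
    onsets = np.arange(n) / rate
    amplitudes = np.full(n, float(baseline_amp))
    sign = 0
    if deviant_index is not None:
        if deviant_index == 0:
            raise ConfigError("a deviant requires preceding baseline deflections")
        amplitudes[deviant_index] = baseline_amp * (1.0 + deviant_frac)
        sign = int(np.sign(deviant_frac))
    return DeflectionTrain(
        train_id=train_id,
        onsets=onsets,
        amplitudes=amplitudes,
        baseline_amplitude=float(baseline_amp),
        deviant_index=deviant_index,
        deviant_sign=sign,
        opto_condition=opto_condition,
    )


def histogram_match_positions(
    deviant_deflections: pd.DataFrame,
    baseline_deflections: pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> MatchedSets:
    """Subsample baseline deflections to match the deviant position histogram.

    Both inputs are DataFrames with columns ``train_id`` and ``deflection``
    (0-based position in train).  The returned baseline subset has exactly
    the deviant set's position histogram, drawn uniformly at random without
    replacement.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for df, name in ((deviant_deflections, "deviant"), (baseline_deflections, "baseline")):
        missing = {"train_id", "deflection"} - set(df.columns)
        if missing:
            raise ConfigError(f"{name} deflection table missing columns {sorted(missing)}")
    if len(deviant_deflections) == 0:
        empty = baseline_deflections.iloc[:0].reset_index(drop=True)
        return MatchedSets(deviant_deflections.reset_index(drop=True), empty, "position")

    need = deviant_deflections["deflection"].value_counts()
    pieces = []
    for pos, k in sorted(need.items()):
        pool = baseline_deflections[baseline_deflections["deflection"] == pos]
        if len(pool) < k:
            raise ValueError(
                f"insufficient baseline pool at position {pos}: need {k}, have {len(pool)}"
            )
        take = rng.choice(len(pool), size=int(k), replace=False)
        pieces.append(pool.iloc[np.sort(take)])
    matched = pd.concat(pieces, ignore_index=True)
    return MatchedSets(deviant_deflections.reset_index(drop=True), matched, "position")


def match_amplitude_distributions(
    trials_a: pd.DataFrame,
    trials_b: pd.DataFrame,
    bin_width: float,
    seed: int | np.random.Generator = 0,
) -> MatchedSets:
    """Subsample both trial sets so their amplitude histograms are equal.

    Used to isolate stimulus-history effects: after matching, the deviant
    amplitude distributions of the two sets are identical per bin, so any
    remaining response difference reflects the preceding baseline amplitudes
    only.  Inputs carry an ``amplitude`` column; within each amplitude bin
    ``min(n_a, n_b)`` rows are retained from each set (subsampling only the
    larger set within a bin), uniformly at random.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")
    for df, name in ((trials_a, "A"), (trials_b, "B")):
        if "amplitude" not in df.columns:
            raise ConfigError(f"trial set {name} lacks an 'amplitude' column")
    lo = min(trials_a["amplitude"].min(), trials_b["amplitude"].min())
    hi = max(trials_a["amplitude"].max(), trials_b["amplitude"].max())
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    bins_a = np.digitize(trials_a["amplitude"].to_numpy(), edges)
    bins_b = np.digitize(trials_b["amplitude"].to_numpy(), edges)

    keep_a, keep_b = [], []
    for b in np.union1d(bins_a, bins_b):
        ia = np.flatnonzero(bins_a == b)
        ib = np.flatnonzero(bins_b == b)
        k = min(ia.size, ib.size)
        if k == 0:
            continue
        keep_a.append(ia if ia.size == k else np.sort(rng.choice(ia, size=k, replace=False)))
        keep_b.append(ib if ib.size == k else np.sort(rng.choice(ib, size=k, replace=False)))
    if not keep_a:
        raise ValueError("no overlapping amplitude support between trial sets")
    sub_a = trials_a.iloc[np.concatenate(keep_a)].reset_index(drop=True)
    sub_b = trials_b.iloc[np.concatenate(keep_b)].reset_index(drop=True)
    return MatchedSets(sub_a, sub_b, "amplitude_distribution")


def deflection_sets(trains) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a session's deflections into deviant and baseline reference sets.

    Only the (first) deviant deflection of each deviant train enters the
    deviant set; deflections after a deviant are excluded from the baseline
    pool (stimuli after the deviant are not analyzed), as are deflections
    at position 0 of deviant trains' corresponding positions -- the baseline
    pool is drawn from non-deviant trains only, at all positions.
    """
    dev_rows, base_rows = [], []
    for t in trains:
        if t.deviant_index is not None:
            dev_rows.append((t.train_id, int(t.deviant_index), int(t.deviant_sign)))
        else:
            for d in range(t.n_deflections):
                base_rows.append((t.train_id, d))
    dev = pd.DataFrame(dev_rows, columns=["train_id", "deflection", "sign"])
    base = pd.DataFrame(base_rows, columns=["train_id", "deflection"])
    return dev, base
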