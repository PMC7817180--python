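"""Delimited-text session readers/writers and JSON result serialization.

On-disk schema (inspectable, language-neutral):

* ``trials.csv`` -- train_id, opto_condition, baseline_amplitude,
  deviant_index (empty if absent), deviant_sign, onset_0..onset_{n-1},
  amp_0..amp_{n-1}
* ``spikes.csv``  -- unit_id, train_id, t_s
* ``units.csv``   -- unit_id, depth_um, width_ms

Results of any stage are JSON (full-precision floats, sorted keys, so
identical inputs yield byte-identical files).
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (DeflectionTrain, IntegrityError, SchemaError,
                        SessionBundle, UnitRecord)
from .units import annotate_units

TRIALS_FILE = "trials.csv"
SPIKES_FILE = "spikes.csv"
UNITS_FILE = "units.csv"


def write_session(bundle: SessionBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = bundle.trains[0].n_deflections
    rows = []
    for t in bundle.trains:
        row = {"train_id": t.train_id, "opto_condition": t.opto_condition,
               "baseline_amplitude": t.baseline_amplitude,
               "deviant_index": "" if t.deviant_index is None else t.deviant_index,
               "deviant_sign": t.deviant_sign}
        row.update({f"onset_{i}": t.onsets[i] for i in range(n)})
        row.update({f"amp_{i}": repr(float(t.amplitudes[i])) for i in range(n)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / TRIALS_FILE, index=False)

    srows = []
    for u in bundle.units:
        for tid in sorted(u.spike_times):
            for s in u.spike_times[tid]:
                srows.append((u.unit_id, tid, repr(float(s))))
    pd.DataFrame(srows, columns=["unit_id", "train_id", "t_s"]).to_csv(
        out / SPIKES_FILE, index=False)

    urows = [(u.unit_id, u.depth_um, u.waveform_width_ms) for u in bundle.units]
    pd.DataFrame(urows, columns=["unit_id", "depth_um", "width_ms"]).to_csv(
        out / UNITS_FILE, index=False)


def _require_columns(df: pd.DataFrame, cols, fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing columns {missing}")


def read_session(in_dir) -> SessionBundle:
    """Read and validate a session from its delimited-text tables.

    Malformed rows are reported with 1-based data line numbers; spike rows
    referencing unknown trains raise an integrity error naming the id.
    """
    ind = Path(in_dir)
    for fname in (TRIALS_FILE, SPIKES_FILE, UNITS_FILE):
        if not (ind / fname).exists():
            raise SchemaError(f"missing session file {fname} in {ind}")
    trials = pd.read_csv(ind / TRIALS_FILE)
    _require_columns(trials, ["train_id", "opto_condition", "baseline_amplitude",
                              "deviant_index", "deviant_sign", "onset_0", "amp_0"],
                     TRIALS_FILE)
    onset_cols = sorted([c for c in trials.columns if c.startswith("onset_")],
                        key=lambda c: int(c.split("_")[1]))
    amp_cols = sorted([c for c in trials.columns if c.startswith("amp_")],
                      key=lambda c: int(c.split("_")[1]))
    trains = []
    for i, row in trials.iterrows():
        try:
            di = row["deviant_index"]
            di = None if pd.isna(di) or di == "" else int(di)
            trains.append(DeflectionTrain(
                train_id=int(row["train_id"]),
                onsets=row[onset_cols].to_numpy(dtype=float),
                amplitudes=row[amp_cols].to_numpy(dtype=float),
                baseline_amplitude=float(row["baseline_amplitude"]),
                deviant_index=di,
                deviant_sign=int(row["deviant_sign"]),
                opto_condition=str(row["opto_condition"])))
        except (ValueError, TypeError) as err:
            raise SchemaError(f"{TRIALS_FILE} line {i + 1}: {err}") from err

    units_df = pd.read_csv(ind / UNITS_FILE)
    _require_columns(units_df, ["unit_id", "depth_um", "width_ms"], UNITS_FILE)
    spikes = pd.read_csv(ind / SPIKES_FILE)
    _require_columns(spikes, ["unit_id", "train_id", "t_s"], SPIKES_FILE)

    known_trains = {t.train_id for t in trains}
    bad = set(spikes.train_id.unique()) - known_trains
    if bad:
        raise IntegrityError(
            f"{SPIKES_FILE}: spikes reference unknown train_id(s) {sorted(bad)}")
    known_units = set(units_df.unit_id)
    bad_u = set(spikes.unit_id.unique()) - known_units
    if bad_u:
        raise IntegrityError(
            f"{SPIKES_FILE}: spikes reference unknown unit_id(s) {sorted(bad_u)}")

    grouped = {k: g for k, g in spikes.groupby(["unit_id", "train_id"])}
    units = []
    for i, row in units_df.iterrows():
        uid = int(row["unit_id"])
        st = {}
        for tid in known_trains:
            g = grouped.get((uid, tid))
            if g is not None:
                st[tid] = np.sort(g.t_s.to_numpy(dtype=float))
        try:
            units.append(UnitRecord(unit_id=uid, spike_times=st,
                                    depth_um=float(row["depth_um"]),
                                    waveform_width_ms=float(row["width_ms"])))
        except (ValueError, TypeError) as err:
            raise SchemaError(f"{UNITS_FILE} line {i + 1}: {err}") from err
    bundle = SessionBundle(trains=trains, units=units,
                           metadata={"source": str(ind)})
    return annotate_units(bundle)


# ---------------------------------------------------------------------------
# JSON results
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_results(results, path) -> None:
    """Serialize a stage result (dataclass / dict / list) to JSON.

    Floats keep full precision; keys are sorted so re-runs are
    byte-identical.  NaN/inf become null.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = _jsonable(results)
    try:
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1, allow_nan=False)
            fh.write("\n")
    except OSError as err:
        raise OSError(f"cannot write results to {path}: {err}") from err


def read_results(path):
    with open(path) as fh:
        return json.load(fh)


def results_equal(a, b, rtol=0.0) -> bool:
    """Structural equality of parsed result payloads."""
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(results_equal(a[k], b[k], rtol) for k in a)
    if isinstance(a, list) and isinstance(b, list):
        return len(a) == len(b) and all(results_equal(x, y, rtol) for x, y in zip(a, b))
    if isinstance(a, float) and isinstance(b, float):
        return a == b or abs(a - b) <= rtol * max(abs(a), abs(b))
    return a == b
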