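import numpy as np
import pytest

import deviantcoding as dc


@pytest.fixture
def small_bundle():
    """Two units, four trains, hand-placed spikes."""
    trains = [
        dc.build_train(25.0, train_id=0),
        dc.build_train(25.0, train_id=1, deviant_index=3, deviant_frac=0.10),
        dc.build_train(25.0, train_id=2, deviant_index=4, deviant_frac=-0.10),
        dc.build_train(25.0, train_id=3),
    ]
    units = [
        dc.UnitRecord(0, {0: np.array([0.01, 0.11, 0.31]),
                          1: np.array([0.305, 0.32]),
                          2: np.array([0.41])},
                      depth_um=400.0, waveform_width_ms=0.6),
        dc.UnitRecord(1, {0: np.array([0.05]),
                          3: np.array([0.61, 0.65])},
                      depth_um=700.0, waveform_width_ms=0.25),
    ]
    return dc.SessionBundle(trains=trains, units=units, metadata={"session": "fix"})


@pytest.fixture
def planted_session():
    """Counts-level session with a heterogeneous planted population."""
    cfg = dc.SpikeSimConfig(
        n_units={"L2/3": 40}, driven_fraction={"L2/3": 1.0},
        change_regime={"L2/3": ("heterogeneous", 0.05)},
        amplitude_gain={"L2/3": 0.0})
    trains = dc.build_deviant_trains(200, 80, 80, seed=11)
    tensor, truth = dc.simulate_count_tensor(cfg, trains, seed=12)
    return cfg, trains, tensor, truth
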