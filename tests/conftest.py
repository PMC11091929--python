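import numpy as np
import pandas as pd
import pytest

from oscistate.containers import SensorRecording, make_channel_meta
from oscistate.synthetic import (
    SyntheticTruth,
    make_topographies,
    simulate_recording,
    simulate_state_sequence,
)


@pytest.fixture(scope="session")
def alpha_truth() -> SyntheticTruth:
    """Small 4-state alpha-band ground truth shared across tests."""
    topo = make_topographies(24, 4, max_abs_corr=0.3, seed=7)
    segs = simulate_state_sequence(20.0, 4, mean_dur_s=0.08, min_dur_s=0.02, seed=3)
    return SyntheticTruth(topo, segs, band="alpha", snr=3.0, seed=3)


@pytest.fixture(scope="session")
def alpha_recording(alpha_truth):
    """Noisy recording + planted per-sample labels for the shared truth."""
    rec, labels = simulate_recording(alpha_truth, fs=250.0, noise_sigma=0.1, seed=5)
    return rec, labels


@pytest.fixture()
def grad_recording() -> SensorRecording:
    """A recording with 2 MAG channels and 2 complete planar pairs."""
    rng = np.random.default_rng(0)
    data = rng.standard_normal((6, 100))
    meta = make_channel_meta(
        names=["M0", "M1", "G0a", "G0b", "G1a", "G1b"],
        kinds=["MAG", "MAG", "GRAD", "GRAD", "GRAD", "GRAD"],
        pairs=[None, None, "p0", "p0", "p1", "p1"],
    )
    return SensorRecording(data, fs=250.0, band="broadband-raw", channels=meta)


def make_manifest(groups: dict[str, int], age_by_group=None) -> pd.DataFrame:
    """Tiny subject manifest builder used by workflow tests."""
    defaults = {"YA": 25, "EMA": 37, "LMA": 52, "YS": 67, "EA": 80}
    age_by_group = age_by_group or defaults
    rows = []
    i = 0
    for group, n in groups.items():
        for _ in range(n):
            rows.append(
                {
                    "subject": f"s{i:02d}",
                    "path": "",
                    "age": age_by_group[group] + (i % 5),
                    "group": group,
                    "sex": "F" if i % 2 else "M",
                    "handedness": "R",
                }
            )
            i += 1
    return pd.DataFrame(rows)
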