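import numpy as np
import pandas as pd
import pytest

from pupilkit.preprocess import PupilRun
from pupilkit.synthcohort import SyntheticCohortConfig


def make_run(
    diameter,
    sampling_rate=500.0,
    loss=None,
    standardized=False,
    participant_id="sub-01",
):
    diameter = np.asarray(diameter, dtype=float)
    if loss is None:
        loss = np.zeros(diameter.size, dtype=bool)
    return PupilRun(
        participant_id=participant_id,
        sampling_rate=sampling_rate,
        diameter=diameter,
        loss_flags=np.asarray(loss, dtype=bool),
        standardized=standardized,
        units_label="z" if standardized else "device",
    )


def make_events(onsets_ms, block_types=None, sampling_rate=500.0):
    """Minimal valid event table with stimulus onsets in ms."""
    from pupilkit.preprocess import BLOCK_DECODE

    n = len(onsets_ms)
    if block_types is None:
        cycle = ["ReappraisePositive", "ReappraiseNegative", "ViewPositive", "ViewNegative"]
        block_types = [cycle[i % 4] for i in range(n)]
    rows = []
    for i, (t0, bt) in enumerate(zip(onsets_ms, block_types)):
        cond, val = BLOCK_DECODE[bt]
        rows.append(
            {
                "trial_id": i + 1,
                "block_type": bt,
                "condition": cond,
                "valence": val,
                "adaptation_onset_ms": t0 - 1000.0,
                "stimulus_onset_ms": float(t0),
                "rating": 5,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_config():
    """Small, fast cohort config for smoke tests."""
    return SyntheticCohortConfig(
        seed=11,
        n_participants=6,
        sampling_rate=100.0,
        n_trials_per_block=4,
        rating_duration=1.0,
        block_break=2.0,
        iti_range=(0.5, 1.0),
        blink_rate_per_min=4.0,
    )


@pytest.fixture
def noiseless_config():
    """Deterministic traces: no noise, no drift, no blinks."""
    return SyntheticCohortConfig(
        seed=7,
        n_participants=5,
        sampling_rate=100.0,
        n_trials_per_block=3,
        rating_duration=1.0,
        block_break=2.0,
        iti_range=(0.5, 1.0),
        noise_sd=0.0,
        drift_sd=0.0,
        blink_rate_per_min=0.0,
    )
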