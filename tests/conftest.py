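import numpy as np
import pytest
from hypothesis import settings

from dqiselect import (
    ChannelSpec,
    CohortSpec,
    NoiseSpec,
    Recording,
    SubjectSpec,
    accuracy_all_combos,
    generate_cohort,
    generate_recording,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """Two-channel (sEMG + pFMG) recording with 3 gestures x 2 repetitions."""
    fs = 1000.0
    blocks = []
    labels = []
    reps = []
    for rep in (1, 2):
        for g in (1, 2, 3):
            blocks.append(np.zeros(300))
            labels += [0] * 300
            reps += [0] * 300
            blocks.append(rng.normal(0.0, 1.0 + 0.5 * g, 400))
            labels += [g] * 400
            reps += [rep] * 400
    blocks.append(np.zeros(300))
    labels += [0] * 300
    reps += [0] * 300
    x = np.concatenate(blocks)
    data = np.column_stack([x, 0.5 * x + rng.normal(0, 0.1, len(x))])
    return Recording(
        data=data,
        fs=fs,
        modality=("sEMG", "pFMG"),
        labels=np.array(labels),
        repetitions=np.array(reps),
        subject_id="tiny",
    )


MINI_COHORT = CohortSpec(
    n_subjects=4,
    n_channels=5,
    n_gestures=4,
    n_repetitions=4,
    active_s=0.6,
    rest_s=0.4,
    good_channels=(1, 3),
    master_seed=7,
)


@pytest.fixture(scope="session")
def mini_cohort():
    """Small synthetic cohort reused across selection/model tests."""
    recordings, truth = generate_cohort(MINI_COHORT)
    return recordings, truth


@pytest.fixture(scope="session")
def mini_tables(mini_cohort):
    recordings, _ = mini_cohort
    return [
        accuracy_all_combos(rec, (1, 2, 3), (4,), seed=0, k=3) for rec in recordings
    ]


def make_subject_spec(
    n_channels=2,
    n_gestures=3,
    n_repetitions=2,
    target_snr_db=15.0,
    fs=1000.0,
    active_s=0.8,
    rest_s=0.4,
    separation=0.6,
    modality="sEMG",
):
    """Hand-rolled subject spec for targeted generator tests."""
    channels = []
    for c in range(n_channels):
        gains = tuple(1.0 + separation * (g / max(n_gestures - 1, 1) - 0.5) for g in range(n_gestures))
        channels.append(
            ChannelSpec(
                gesture_gain=gains,
                noise_specs=(NoiseSpec("white_gaussian", 1.0),),
                target_snr_db=target_snr_db,
                modality=modality,
            )
        )
    return SubjectSpec(
        channels=tuple(channels),
        fs=fs,
        n_gestures=n_gestures,
        n_repetitions=n_repetitions,
        active_s=active_s,
        rest_s=rest_s,
        subject_id="spec-test",
    )
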