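"""Shared fixtures: synthetic epoch sets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from miadapt import (
    CHANNELS_60,
    Erd,
    SynthSpec,
    bandpass_fir,
    extract_epochs,
    generate_paradigm,
    rereference_average,
    simulate_recording,
)


@pytest.fixture(scope="session")
def epochs_70():
    """Two-class, 35+35-epoch set on the full 60-channel montage at 250 Hz.

    Left- and right-hand imagery with contralateral ERD, the standard
    3-s window (750 samples) after 1 s of reaction time.
    """
    sched = generate_paradigm(
        1, 70, tasks=("left_hand", "right_hand"), imagery_s=4.5, rest_s=1.0, seed=5
    )
    spec = SynthSpec(
        montage=CHANNELS_60,
        fs=250.0,
        erd=(
            Erd("left_hand", ("C4", "C6", "CP4"), (8.0, 30.0), 0.5),
            Erd("right_hand", ("C3", "C5", "CP3"), (8.0, 30.0), 0.5),
        ),
        snr=0.5,
        seed=6,
    )
    rec = simulate_recording(sched, spec)
    rec = bandpass_fir(rereference_average(rec), 1.0, 40.0)
    return extract_epochs(rec, window=(1.0, 3.0), per_task_keep=35)


@pytest.fixture(scope="session")
def small_epochs():
    """Fast fixture: 8+8 epochs, 8 channels, 2-s windows."""
    montage = ("FC3", "FC4", "C3", "C4", "Cz", "CP3", "CP4", "Pz")
    sched = generate_paradigm(
        1, 16, tasks=("left_hand", "right_hand"), imagery_s=2.5, rest_s=1.0, seed=1
    )
    spec = SynthSpec(
        montage=montage,
        fs=250.0,
        erd=(
            Erd("left_hand", ("C4", "CP4"), (8.0, 30.0), 0.6),
            Erd("right_hand", ("C3", "CP3"), (8.0, 30.0), 0.6),
        ),
        snr=1.0,
        seed=2,
    )
    rec = simulate_recording(sched, spec)
    return extract_epochs(rec, window=(0.25, 2.0), per_task_keep=8)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
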