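"""Canonical electrode sets for the 60-channel 10-20 montage.

The study montage keeps 60 scalp electrodes of the extended 10-20 layout.
Hemispheric summaries use 15 key electrodes per hemisphere over
frontal-central-parietal cortex; spectral features use a 21-channel
sensorimotor strip (FC, C and CP rows).
"""

from __future__ import annotations

import functools

import numpy as np

#: The 60 retained scalp electrodes, in canonical order.
CHANNELS_60: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

#: Key electrodes of the left hemisphere (frontal-central-parietal).
LEFT_KEY_15: tuple[str, ...] = (
    "F5", "F3", "F1", "FC5", "FC3", "FC1",
    "C5", "C3", "C1", "CP5", "CP3", "CP1",
    "P5", "P3", "P1",
)

#: Key electrodes of the right hemisphere.
RIGHT_KEY_15: tuple[str, ...] = (
    "F6", "F4", "F2", "FC6", "FC4", "FC2",
    "C6", "C4", "C2", "CP6", "CP4", "CP2",
    "P6", "P4", "P2",
)

#: Union of both hemispheric key sets (30 electrodes).
KEY_30: tuple[str, ...] = LEFT_KEY_15 + RIGHT_KEY_15

#: 21-channel sensorimotor strip used for spectral / covariance features
#: (FC5..FC6, C5..C6 and CP5..CP6 rows, 3 x 7 electrodes).
SENSORIMOTOR_21: tuple[str, ...] = (
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
)


@functools.lru_cache(maxsize=1)
def _standard_positions() -> dict:
    """3-D positions of the standard 10-05 layout (metres), via mne."""
    import mne

    montage = mne.channels.make_standard_montage("standard_1005")
    return montage.get_positions()["ch_pos"]


def channel_positions_2d(names=CHANNELS_60) -> dict[str, np.ndarray]:
    """Top-view 2-D projected coordinates (x, y) for ``names``.

    Coordinates come from the standard 10-05 template; the z axis is
    dropped, which is adequate for nearest-neighbour lookups on the scalp.
    """
    pos = _standard_positions()
    missing = [n for n in names if n not in pos]
    if missing:
        raise KeyError(f"channels without template positions: {missing}")
    return {n: np.asarray(pos[n][:2], dtype=float) for n in names}


def nearest_neighbors(name: str, candidates, k: int = 4) -> list[tuple[str, float]]:
    """``k`` nearest candidate electrodes to ``name`` with their distances."""
    pos = channel_positions_2d(tuple(sorted(set(candidates) | {name})))
    ref = pos[name]
    dists = sorted(
        (float(np.linalg.norm(pos[c] - ref)), c)
        for c in candidates
        if c != name
    )
    return [(c, d) for d, c in dists[:k]]
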