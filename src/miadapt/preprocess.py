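"""Preprocessing: re-reference, FIR filtering, downsampling, channel
selection/interpolation and epoch extraction.

The canonical order, applied by :func:`run_preprocess` and logged, is

    select/interpolate -> average re-reference -> downsample -> band-pass
    -> epoch extraction

FIR filters follow an explicit order rule — three times the ratio of the
sampling rate to the transition bandwidth, rounded to the nearest even
integer (linear-phase type I) — with a Hanning window, and are applied
zero-phase (symmetric kernel, delay-compensated single pass on a
reflection-padded signal) so epoch timing is never shifted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ._montage import CHANNELS_60, nearest_neighbors
from .synthgen import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet",
    "rereference_average",
    "bandpass_fir",
    "downsample",
    "select_and_interpolate",
    "extract_epochs",
    "denoise_hook",
    "run_preprocess",
    "fir_order",
    "design_bandpass",
    "filter_zero_phase",
]


@dataclass
class EpochSet:
    """Task-labelled epochs: ``data`` is epochs x channels x samples."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    window: tuple[float, float]  # (offset_s, length_s) from imagery onset

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal epoch count")
        expected = int(round(self.window[1] * self.fs))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != window length "
                f"{self.window[1]} s x {self.fs} Hz = {expected} samples"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def task_subset(self, *tasks: str) -> "EpochSet":
        """Epochs whose label is in ``tasks`` (order preserved)."""
        mask = np.isin(self.labels, tasks)
        return EpochSet(
            self.data[mask], self.labels[mask], self.fs, self.channel_names, self.window
        )

    def channel_indices(self, names) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.channel_names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"channels not in epoch set: {missing}")
        return np.asarray([lookup[n] for n in names], dtype=int)


# --------------------------------------------------------------------------
# FIR design and application
# --------------------------------------------------------------------------

def fir_order(fs: float, transition_bw: float, max_order: int | None = None) -> int:
    """Filter order: ``3 * fs / transition_bw`` rounded to the nearest even
    integer, optionally capped (short epochs cannot support the full rule)."""
    if transition_bw <= 0:
        raise ValueError("transition bandwidth must be positive")
    order = int(round(3.0 * fs / transition_bw / 2.0)) * 2
    order = max(order, 2)
    if max_order is not None:
        cap = max(2, (int(max_order) // 2) * 2)
        order = min(order, cap)
    return order


def design_bandpass(
    fs: float,
    f_lo: float,
    f_hi: float,
    transition_bw: float = 1.0,
    max_order: int | None = None,
) -> np.ndarray:
    """Hanning-windowed linear-phase band-pass FIR taps."""
    if not 0 < f_lo < f_hi < fs / 2:
        raise ValueError(
            f"band edges must satisfy 0 < f_lo < f_hi < Nyquist; "
            f"got ({f_lo}, {f_hi}) at fs={fs}"
        )
    order = fir_order(fs, transition_bw, max_order)
    return sps.firwin(order + 1, [f_lo, f_hi], pass_zero=False, window="hann", fs=fs)


def design_lowpass(
    fs: float, cutoff: float, transition_bw: float, max_order: int | None = None
) -> np.ndarray:
    order = fir_order(fs, transition_bw, max_order)
    return sps.firwin(order + 1, cutoff, pass_zero=True, window="hann", fs=fs)


def filter_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR along the last axis with zero net phase.

    The kernel is linear phase, so centring the convolution ("same" mode)
    compensates the group delay exactly; reflection padding suppresses
    edge transients.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    pad = min(len(taps) // 2, n - 1)
    padded = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    out = sps.fftconvolve(padded, taps[(None,) * (x.ndim - 1) + (slice(None),)], mode="same", axes=-1)
    return out[..., pad : pad + n]


# --------------------------------------------------------------------------
# recording-level operations
# --------------------------------------------------------------------------

def rereference_average(rec: Recording) -> Recording:
    """Common average reference: subtract the instantaneous channel mean."""
    if rec.n_channels < 2:
        raise ValueError("average reference is degenerate with a single channel")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data)


def bandpass_fir(
    rec: Recording, f_lo: float = 1.0, f_hi: float = 40.0, transition_bw: float = 1.0
) -> Recording:
    """Zero-phase Hanning-window FIR band-pass of the whole recording."""
    taps = design_bandpass(rec.fs, f_lo, f_hi, transition_bw)
    return rec.copy_with(data=filter_zero_phase(rec.data, taps))


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Integer-ratio decimation with an internal anti-alias low-pass.

    Event sample indices are rescaled by the same ratio.
    """
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"sampling rate {rec.fs} is not an integer multiple of target {target_fs}"
        )
    ratio = int(round(ratio))
    if ratio == 1:
        return rec.copy_with()
    # anti-alias: cut at 80% of the target Nyquist, modest transition
    taps = design_lowpass(rec.fs, 0.8 * target_fs / 2, transition_bw=0.1 * target_fs)
    data = filter_zero_phase(rec.data, taps)[:, ::ratio]
    events = [(idx // ratio, task) for idx, task in rec.events]
    return Recording(data=data, channel_names=rec.channel_names, fs=target_fs, events=events)


def select_and_interpolate(
    rec: Recording, keep=CHANNELS_60, bad=(), n_neighbors: int = 4
) -> Recording:
    """Reduce to the canonical channel set and repair bad channels.

    Output channels are exactly ``keep`` in the given order.  Each bad
    channel is replaced by an inverse-distance-weighted average of its
    ``n_neighbors`` nearest good kept channels (standard 10-20 template
    positions, top-view 2-D projection).
    """
    keep = tuple(keep)
    missing = [c for c in keep if c not in rec.channel_names]
    if missing:
        raise ValueError(f"keep channels absent from recording: {missing}")
    bad_eff = []
    for b in bad:
        if b in keep:
            bad_eff.append(b)
        else:
            warnings.warn(f"bad channel {b!r} not in keep list; skipped", stacklevel=2)
    lookup = {n: i for i, n in enumerate(rec.channel_names)}
    data = rec.data[[lookup[c] for c in keep]].copy()
    good = [c for c in keep if c not in bad_eff]
    keep_index = {n: i for i, n in enumerate(keep)}
    for b in bad_eff:
        neigh = nearest_neighbors(b, good, k=n_neighbors)
        weights = np.array([1.0 / max(d, 1e-12) for _, d in neigh])
        weights /= weights.sum()
        rows = [keep_index[c] for c, _ in neigh]
        data[keep_index[b]] = weights @ data[rows]
        logger.info("interpolated %s from %s", b, [c for c, _ in neigh])
    return Recording(data=data, channel_names=keep, fs=rec.fs, events=list(rec.events))


def extract_epochs(
    rec: Recording,
    window: tuple[float, float] = (1.0, 3.0),
    per_task_keep: int | None = None,
    seed: int = 0,
) -> EpochSet:
    """Cut imagery epochs and keep the cleanest ``per_task_keep`` per task.

    ``window = (offset_s, length_s)`` is relative to each imagery onset
    (the default skips 1 s of reaction time and takes 3 s of imagery).
    Retention is an automated proxy for manual artifact screening: per
    task, the ``per_task_keep`` epochs with the smallest peak-to-peak
    amplitude (max over channels) are kept, ties broken by trial order.
    The procedure is deterministic; ``seed`` is reserved for alternative
    retention rules.
    """
    offset_s, length_s = window
    n_len = int(round(length_s * rec.fs))
    per_task: dict[str, list[tuple[float, int, np.ndarray]]] = {}
    for order, (onset, task) in enumerate(rec.events):
        start = onset + int(round(offset_s * rec.fs))
        stop = start + n_len
        if start < 0 or stop > rec.n_samples:
            raise ValueError(
                f"epoch window [{start}, {stop}) outside recording of "
                f"{rec.n_samples} samples (event at {onset})"
            )
        epoch = rec.data[:, start:stop]
        ptp = float(np.max(epoch.max(axis=1) - epoch.min(axis=1)))
        per_task.setdefault(task, []).append((ptp, order, epoch))

    epochs, labels = [], []
    for task in sorted(per_task):
        trials = per_task[task]
        if per_task_keep is not None:
            if len(trials) < per_task_keep:
                raise ValueError(
                    f"task {task!r} has only {len(trials)} trials, "
                    f"cannot keep {per_task_keep}"
                )
            kept = sorted(trials, key=lambda t: (t[0], t[1]))[:per_task_keep]
            kept.sort(key=lambda t: t[1])  # restore chronological order
        else:
            kept = trials
        for _, _, epoch in kept:
            epochs.append(epoch)
            labels.append(task)
    return EpochSet(
        data=np.stack(epochs),
        labels=np.asarray(labels),
        fs=rec.fs,
        channel_names=rec.channel_names,
        window=window,
    )


def denoise_hook(rec: Recording, hook=None) -> Recording:
    """Pass-through slot for component-based denoising (e.g. ICA cleanup).

    Manual component inspection is outside this package; supply ``hook``
    (Recording -> Recording) to plug an external cleaning step into the
    pipeline, otherwise the recording passes unchanged.
    """
    return rec if hook is None else hook(rec)


def run_preprocess(
    rec: Recording,
    keep=CHANNELS_60,
    bad=(),
    target_fs: float = 250.0,
    band: tuple[float, float] = (1.0, 40.0),
    transition_bw: float = 1.0,
    window: tuple[float, float] = (1.0, 3.0),
    per_task_keep: int | None = 35,
    seed: int = 0,
    hook=None,
) -> EpochSet:
    """Full preprocessing chain in the canonical, logged order."""
    logger.info("preprocess: select/interpolate (%d channels, %d bad)", len(keep), len(bad))
    rec = select_and_interpolate(rec, keep=keep, bad=bad)
    logger.info("preprocess: average re-reference")
    rec = rereference_average(rec)
    if target_fs != rec.fs:
        logger.info("preprocess: downsample %g -> %g Hz", rec.fs, target_fs)
        rec = downsample(rec, target_fs)
    logger.info("preprocess: band-pass %g-%g Hz (transition %g Hz)", *band, transition_bw)
    rec = bandpass_fir(rec, band[0], band[1], transition_bw)
    rec = denoise_hook(rec, hook)
    logger.info("preprocess: epochs window=%s keep=%s", window, per_task_keep)
    return extract_epochs(rec, window=window, per_task_keep=per_task_keep, seed=seed)
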