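"""Synthetic motor-imagery EEG with known ground truth.

Real recordings for this kind of study are rarely shareable, so the
package ships a generator that emulates the acquisition: a 4-class
motor-imagery paradigm (balanced randomized trial schedule), band-limited
oscillatory activity over a pink-noise background, task-dependent
amplitude attenuation (ERD), and phase-lagged coupling between chosen
channel pairs.  Every downstream stage — filtering, CSP, WPLI networks,
graph metrics, correlation screening — can therefore be tested against a
known answer.

Model
-----
Each channel is ``amplitude * (pink_noise + sqrt(snr) * oscillations)``.
Oscillators are constant-amplitude phase-diffusion sinusoids: the
instantaneous phase advances at the band's centre frequency plus a random
walk whose step variance sets the linewidth.  This produces a narrow-band
analytic signal directly, so imposing an exact phase lag between two
channels is a complex rotation — precisely the structure a phase-lag
estimator is sensitive to.  Volume conduction, eye/muscle artifacts and
realistic forward-model topographies are deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._montage import CHANNELS_60

__all__ = [
    "TASKS",
    "Trial",
    "ParadigmSchedule",
    "Coupling",
    "Erd",
    "Oscillation",
    "SynthSpec",
    "Recording",
    "generate_paradigm",
    "simulate_recording",
    "simulate_cohort",
]

#: The four imagery tasks in canonical order.
TASKS: tuple[str, ...] = ("left_hand", "right_hand", "foot", "tongue")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    """One imagery prompt followed by one rest period."""

    task: str
    imagery_s: float
    rest_s: float


@dataclass
class ParadigmSchedule:
    """A balanced, randomized trial schedule.

    Invariants: ``len(trials) == sets * trials_per_set`` and within each
    set every task appears exactly ``trials_per_set / n_tasks`` times.
    """

    trials: list[Trial]
    sets: int
    trials_per_set: int
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def task_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trials:
            counts[t.task] = counts.get(t.task, 0) + 1
        return counts

    def duration_s(self) -> float:
        return float(sum(t.imagery_s + t.rest_s for t in self.trials))


@dataclass(frozen=True)
class Coupling:
    """Ground-truth phase-lagged coupling between two channels.

    ``chan_b``'s band component is ``chan_a``'s rotated by ``phase_lag``
    radians, mixed with ``chan_b``'s own independent oscillator at the
    stated ``strength`` (1 = fully coupled).  If ``task`` is set the
    coupling is only active inside that task's imagery windows, which
    creates class-discriminable network structure.
    """

    chan_a: str
    chan_b: str
    band: tuple[float, float] = (8.0, 12.0)
    phase_lag: float = math.pi / 2
    strength: float = 1.0
    task: str | None = None


@dataclass(frozen=True)
class Erd:
    """Event-related desynchronization: band-amplitude attenuation.

    During imagery windows of ``task``, the band oscillation on each
    listed channel is multiplied by ``1 - attenuation`` (0 = no effect,
    1 = full suppression).
    """

    task: str
    channels: tuple[str, ...]
    band: tuple[float, float] = (8.0, 30.0)
    attenuation: float = 0.5


@dataclass(frozen=True)
class Oscillation:
    """A background band oscillator; ``channels=None`` means all channels."""

    band: tuple[float, float] = (8.0, 30.0)
    channels: tuple[str, ...] | None = None


@dataclass
class SynthSpec:
    """Everything needed to synthesize one subject's recording."""

    montage: tuple[str, ...] = CHANNELS_60
    fs: float = 1000.0
    coupling: tuple[Coupling, ...] = ()
    erd: tuple[Erd, ...] = ()
    background: tuple[Oscillation, ...] = (Oscillation(),)
    noise_exponent: float = 1.0
    snr: float = 1.0
    amplitude_uv: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        names = set(self.montage)
        if len(names) != len(self.montage):
            raise ValueError("montage contains duplicate channel names")
        for c in self.coupling:
            for ch in (c.chan_a, c.chan_b):
                if ch not in names:
                    raise ValueError(f"coupling channel {ch!r} not in montage")
            if not 0.0 <= c.strength <= 1.0:
                raise ValueError(f"coupling strength {c.strength} outside [0, 1]")
            if c.band[1] >= self.fs / 2:
                raise ValueError(
                    f"coupling band {c.band} at or above Nyquist ({self.fs / 2} Hz)"
                )
        for e in self.erd:
            if not set(e.channels) <= names:
                raise ValueError(f"ERD channels {set(e.channels) - names} not in montage")
            if not 0.0 <= e.attenuation <= 1.0:
                raise ValueError(f"ERD attenuation {e.attenuation} outside [0, 1]")
        for b in self.background:
            if b.band[1] >= self.fs / 2:
                raise ValueError(f"background band {b.band} at or above Nyquist")


@dataclass
class Recording:
    """A continuous multi-channel recording with event markers.

    ``data`` is channels x samples in nominal microvolts; ``events`` is a
    list of ``(sample_index, task_label)`` imagery onsets with strictly
    increasing sample indices.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    fs: float
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        last = -1
        for idx, _task in self.events:
            if not 0 <= idx < self.data.shape[1]:
                raise ValueError(f"event sample {idx} outside recording")
            if idx <= last:
                raise ValueError("event sample indices must be strictly increasing")
            last = idx

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kwargs) -> "Recording":
        out = {
            "data": self.data,
            "channel_names": self.channel_names,
            "fs": self.fs,
            "events": list(self.events),
        }
        out.update(kwargs)
        return Recording(**out)

    def to_frame(self):
        """Tabular export: one row per sample, one column per channel."""
        import pandas as pd

        return pd.DataFrame(self.data.T, columns=list(self.channel_names))


# --------------------------------------------------------------------------
# paradigm
# --------------------------------------------------------------------------

def generate_paradigm(
    sets: int = 5,
    trials_per_set: int = 40,
    tasks=TASKS,
    imagery_s: float = 7.0,
    rest_s: float = 5.0,
    seed: int = 0,
) -> ParadigmSchedule:
    """Balanced randomized schedule: each set contains each task equally often.

    With the defaults (5 sets of 40 trials, 4 tasks) a subject performs
    200 trials, 50 per task.
    """
    tasks = tuple(tasks)
    if sets < 1 or trials_per_set < 1:
        raise ValueError("sets and trials_per_set must be positive")
    if trials_per_set % len(tasks) != 0:
        raise ValueError(
            f"trials_per_set ({trials_per_set}) must be divisible by the "
            f"number of tasks ({len(tasks)}) for a balanced schedule"
        )
    rng = np.random.default_rng(seed)
    per_task = trials_per_set // len(tasks)
    trials: list[Trial] = []
    for _ in range(sets):
        block = [task for task in tasks for _ in range(per_task)]
        order = rng.permutation(len(block))
        trials.extend(Trial(block[i], imagery_s, rest_s) for i in order)
    return ParadigmSchedule(trials, sets, trials_per_set, seed)


# --------------------------------------------------------------------------
# signal synthesis
# --------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], exponent: float) -> np.ndarray:
    """1/f^exponent noise, one independent realisation per row, unit RMS."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    out = np.fft.irfft(spec * scale, n=n, axis=1)
    rms = np.sqrt(np.mean(out**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return out / rms


def _phase_walk_oscillator(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Complex analytic narrow-band oscillator, |z| = 1.

    Centre frequency is the band midpoint; the per-sample phase-step
    standard deviation is chosen so the Lorentzian linewidth is about
    half the band width, keeping the component inside the band.
    """
    f_lo, f_hi = band
    f_c = 0.5 * (f_lo + f_hi)
    bw = max(f_hi - f_lo, 0.5)
    sigma = math.sqrt(math.pi * bw / fs)  # FWHM ~ sigma^2 fs / (2 pi) = bw/2
    steps = 2.0 * math.pi * f_c / fs + sigma * rng.standard_normal(n)
    phase = np.cumsum(steps) + rng.uniform(0.0, 2.0 * math.pi)
    return np.exp(1j * phase)


def _imagery_windows(schedule: ParadigmSchedule, fs: float) -> dict[str, list[tuple[int, int]]]:
    """Per task, imagery windows as (start, stop) sample index pairs."""
    windows: dict[str, list[tuple[int, int]]] = {}
    t = 0.0
    for trial in schedule.trials:
        start = int(round(t * fs))
        stop = int(round((t + trial.imagery_s) * fs))
        windows.setdefault(trial.task, []).append((start, stop))
        t += trial.imagery_s + trial.rest_s
    return windows


def _window_mask(windows: list[tuple[int, int]], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=float)
    for start, stop in windows:
        mask[start : min(stop, n)] = 1.0
    return mask


def _erd_gain(
    spec: SynthSpec,
    channel: str,
    band: tuple[float, float],
    task_windows: dict[str, list[tuple[int, int]]],
    n: int,
) -> np.ndarray:
    """Multiplicative amplitude envelope from all ERD entries matching
    ``channel`` and overlapping ``band``."""
    gain = np.ones(n, dtype=float)
    for e in spec.erd:
        overlaps = min(band[1], e.band[1]) > max(band[0], e.band[0])
        if channel in e.channels and overlaps and e.task in task_windows:
            mask = _window_mask(task_windows[e.task], n)
            gain *= 1.0 - e.attenuation * mask
    return gain


def simulate_recording(schedule: ParadigmSchedule, spec: SynthSpec) -> Recording:
    """Synthesize a continuous recording covering the full schedule.

    Per channel: pink noise plus band oscillators (background entries and
    any coupling entry the channel takes part in).  Coupled channel pairs
    share a phase-rotated oscillator; ERD entries attenuate band
    amplitude inside matching imagery windows.  Events mark each imagery
    onset.
    """
    spec.validate()
    fs = spec.fs
    n = int(round(schedule.duration_s() * fs))
    if n <= 0:
        raise ValueError("schedule has zero duration")
    channels = tuple(spec.montage)
    index = {name: i for i, name in enumerate(channels)}
    task_windows = _imagery_windows(schedule, fs)

    ss = np.random.SeedSequence(spec.seed)
    noise_rng, bg_rng, cpl_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    osc = np.zeros((len(channels), n), dtype=float)
    n_osc = np.zeros(len(channels), dtype=int)

    for bg in spec.background:
        targets = channels if bg.channels is None else bg.channels
        for name in targets:
            z = _phase_walk_oscillator(bg_rng, n, fs, bg.band)
            gain = _erd_gain(spec, name, bg.band, task_windows, n)
            osc[index[name]] += math.sqrt(2.0) * gain * np.real(z)
            n_osc[index[name]] += 1

    for c in spec.coupling:
        z_a = _phase_walk_oscillator(cpl_rng, n, fs, c.band)
        z_b_own = _phase_walk_oscillator(cpl_rng, n, fs, c.band)
        if c.task is None:
            active = np.ones(n, dtype=float)
        else:
            active = _window_mask(task_windows.get(c.task, []), n)
        mix = c.strength * active
        z_b = mix * z_a * np.exp(-1j * c.phase_lag) + (1.0 - mix) * z_b_own
        for name, z in ((c.chan_a, z_a), (c.chan_b, z_b)):
            gain = _erd_gain(spec, name, c.band, task_windows, n)
            osc[index[name]] += math.sqrt(2.0) * gain * np.real(z)
            n_osc[index[name]] += 1

    # each oscillator has unit RMS; keep total oscillatory power at snr
    # relative to unit-RMS noise regardless of how many entries a channel has
    scale = np.where(n_osc > 0, np.sqrt(np.maximum(n_osc, 1)), 1.0)
    osc /= scale[:, None]

    noise = _pink_noise(noise_rng, (len(channels), n), spec.noise_exponent)
    data = spec.amplitude_uv * (noise + math.sqrt(spec.snr) * osc)

    events: list[tuple[int, str]] = []
    t = 0.0
    for trial in schedule.trials:
        events.append((int(round(t * fs)), trial.task))
        t += trial.imagery_s + trial.rest_s
    return Recording(data=data, channel_names=channels, fs=fs, events=events)


def subject_seeds(master_seed: int, n_subjects: int) -> list[int]:
    """Derive one independent substream seed per subject.

    Uses numpy's SeedSequence spawning (child ``i`` of the master seed),
    folded to a 31-bit integer so seeds stay portable.
    """
    children = np.random.SeedSequence(master_seed).spawn(n_subjects)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def simulate_cohort(
    n_subjects: int,
    spec_generator,
    seed: int = 0,
    schedule: ParadigmSchedule | None = None,
    **paradigm_kwargs,
) -> list[Recording]:
    """Simulate ``n_subjects`` independent recordings.

    ``spec_generator`` maps a subject index to a :class:`SynthSpec`
    (typically varying coupling strength / ERD depth across subjects to
    create a ground-truth adaptability gradient).  Each subject's spec
    seed is overridden with a substream derived from ``seed``; if no
    ``schedule`` is given, each subject gets their own randomized
    balanced schedule from a second substream.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    seeds = subject_seeds(seed, 2 * n_subjects)
    recordings = []
    for i in range(n_subjects):
        spec = replace(spec_generator(i), seed=seeds[2 * i])
        sched = schedule
        if sched is None:
            sched = generate_paradigm(seed=seeds[2 * i + 1], **paradigm_kwargs)
        recordings.append(simulate_recording(sched, spec))
    return recordings
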