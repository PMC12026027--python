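"""Functional connectivity: the weighted phase lag index (WPLI).

For two channels x and y with cross-power spectrum S_xy, the WPLI is

    WPLI_xy = | mean_n  im(S_xy^n) |  /  mean_n | im(S_xy^n) |

where n runs over cross-spectral observations.  Here an observation is
one time sample of the band-limited analytic signals, pooled over all
retained epochs: S^n = z_x(t) conj(z_y(t)).  The estimator weights each
observation's phase-lag sign by the magnitude of the imaginary part,
which makes it insensitive to volume-conducted (zero-lag) components and
to per-channel amplitude scaling.  The 0/0 case (no imaginary part at
all, e.g. identical signals) is defined as 0.

Networks are binarized by proportional thresholding: the top fraction of
the strongest off-diagonal connections is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import EpochSet, design_bandpass, filter_zero_phase

__all__ = [
    "BANDS",
    "ConnectivityMatrix",
    "BinaryNetwork",
    "wpli_matrix",
    "wpli_pairwise",
    "threshold_top_fraction",
    "plot_connectivity",
]

#: Analysis bands (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "alpha": (8.0, 12.0),
    "beta1": (13.0, 20.0),
    "beta2": (20.0, 30.0),
}


@dataclass
class ConnectivityMatrix:
    """Symmetric channels x channels WPLI weights in [0, 1], zero diagonal."""

    W: np.ndarray
    channel_names: tuple[str, ...]
    band: tuple[float, float]
    task: str = ""
    n_epochs: int = 0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have a zero diagonal")
        if self.W.min() < -1e-12 or self.W.max() > 1 + 1e-12:
            raise ValueError("WPLI weights must lie in [0, 1]")

    def to_frame(self):
        import pandas as pd

        names = list(self.channel_names)
        return pd.DataFrame(self.W, index=names, columns=names)


@dataclass
class BinaryNetwork:
    """Thresholded adjacency matrix (0/1, symmetric, zero diagonal)."""

    A: np.ndarray
    channel_names: tuple[str, ...]
    fraction: float
    band: tuple[float, float] = (0.0, 0.0)
    task: str = ""

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if not np.array_equal(self.A, self.A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.A = self.A.astype(int)

    @property
    def n_edges(self) -> int:
        return int(self.A.sum() // 2)

    def edge_list(self) -> list[tuple[str, str]]:
        iu = np.triu_indices_from(self.A, k=1)
        return [
            (self.channel_names[i], self.channel_names[j])
            for i, j in zip(*iu)
            if self.A[i, j]
        ]


def _analytic_band(
    X: np.ndarray, fs: float, band, transition_bw: float = 1.0, edge_frac: float = 0.05
) -> np.ndarray:
    """Band-limited analytic signal per epoch/channel; a fraction of
    samples at each epoch edge is dropped to suppress filter/Hilbert
    transients."""
    n = X.shape[-1]
    taps = design_bandpass(fs, band[0], band[1], transition_bw, max_order=(n - 1) // 3 * 2)
    Xb = filter_zero_phase(X, taps)
    Z = hilbert(Xb, axis=-1)
    trim = int(edge_frac * n)
    return Z[..., trim : n - trim] if trim else Z


def wpli_matrix(
    epochs: EpochSet,
    band: tuple[float, float],
    task: str | None = None,
    transition_bw: float = 1.0,
    edge_frac: float = 0.05,
) -> ConnectivityMatrix:
    """WPLI between every channel pair, pooled over epochs.

    If ``task`` is given only that task's epochs enter the estimate (the
    default of per-task networks from each task's own epochs).
    """
    if band[1] >= epochs.fs / 2:
        raise ValueError(f"band {band} at or above Nyquist ({epochs.fs / 2} Hz)")
    eps = epochs if task is None else epochs.task_subset(task)
    if eps.n_epochs < 2:
        raise ValueError("WPLI needs at least 2 epochs")
    if not np.any(eps.data):
        warnings.warn("all-zero signals; WPLI defined as 0", stacklevel=2)

    C = eps.n_channels
    num = np.zeros((C, C))
    den = np.zeros((C, C))
    Z = _analytic_band(eps.data, eps.fs, band, transition_bw, edge_frac)
    for z in Z:  # epoch-wise to bound memory; observations pool across epochs
        re, im_part = np.real(z), np.imag(z)
        # im(S_ab) = im(z_a conj(z_b)) = im_a re_b - re_a im_b, written in
        # real arithmetic so identical channels give an exact zero (the
        # 0/0 convention must fire for zero-lag pairs)
        im = im_part[:, None, :] * re[None, :, :] - re[:, None, :] * im_part[None, :, :]
        num += im.sum(axis=-1)
        den += np.abs(im).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.abs(num) / den
    W[den == 0] = 0.0  # 0/0 convention: no phase asymmetry -> 0
    np.fill_diagonal(W, 0.0)
    W = 0.5 * (W + W.T)
    return ConnectivityMatrix(
        W=np.clip(W, 0.0, 1.0),
        channel_names=eps.channel_names,
        band=tuple(band),
        task=task or "",
        n_epochs=eps.n_epochs,
    )


def wpli_pairwise(x: np.ndarray, y: np.ndarray) -> float:
    """WPLI of two already-analytic (complex) signal arrays, any shape.

    Convenience for tests and small analyses; observations are all
    elements."""
    x = np.asarray(x)
    y = np.asarray(y)
    im = (np.imag(x) * np.real(y) - np.real(x) * np.imag(y)).ravel()
    den = np.abs(im).sum()
    if den == 0:
        return 0.0
    return float(abs(im.sum()) / den)


def threshold_top_fraction(cm: ConnectivityMatrix, fraction: float = 0.10) -> BinaryNetwork:
    """Proportional threshold: keep the strongest ``fraction`` of pairs.

    Retains ``round(fraction * P)`` of the P = C(C-1)/2 off-diagonal
    pairs with the largest weights (never pairs of zero weight), breaking
    ties at the cut by (row, column) lexicographic order, then
    symmetrizes and binarizes.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    W = cm.W
    C = W.shape[0]
    iu, ju = np.triu_indices(C, k=1)
    weights = W[iu, ju]
    k = int(np.floor(fraction * len(weights) + 0.5))
    order = sorted(range(len(weights)), key=lambda m: (-weights[m], iu[m], ju[m]))
    A = np.zeros((C, C), dtype=int)
    kept = 0
    for m in order:
        if kept >= k or weights[m] <= 0:
            break
        A[iu[m], ju[m]] = A[ju[m], iu[m]] = 1
        kept += 1
    return BinaryNetwork(
        A=A, channel_names=cm.channel_names, fraction=fraction,
        band=cm.band, task=cm.task,
    )


def plot_connectivity(cm: ConnectivityMatrix, ax=None):
    """Basic connectivity heat map (channels x channels)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.W, vmin=0, vmax=max(cm.W.max(), 1e-12), cmap="viridis")
    ax.set_title(f"WPLI {cm.band[0]:g}-{cm.band[1]:g} Hz {cm.task}".strip())
    step = max(1, len(cm.channel_names) // 15)
    ticks = range(0, len(cm.channel_names), step)
    ax.set_xticks(list(ticks))
    ax.set_xticklabels([cm.channel_names[i] for i in ticks], rotation=90, fontsize=6)
    ax.set_yticks(list(ticks))
    ax.set_yticklabels([cm.channel_names[i] for i in ticks], fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="WPLI")
    return ax
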