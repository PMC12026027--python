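"""MI-BCI adaptability: mean cross-validated pairwise accuracy.

A subject's adaptability is the arithmetic mean of six pairwise
classification accuracies (left hand-right hand, left hand-foot,
left hand-tongue, right hand-foot, right hand-tongue, foot-tongue),
each estimated by stratified 10-fold cross-validation of a linear
maximum-margin classifier (SVM, C=1) on one of the four feature sets.
Trainable transforms (CSP filters, Riemannian class means, feature
standardization) are always fitted inside the training folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._montage import SENSORIMOTOR_21
from .features import (
    FBCSPFeatures,
    FeatureMatrix,
    PSDFeatures,
    RiemannFeatures,
    WaveletFeatures,
    psd_features,
    wavelet_features,
)
from .preprocess import EpochSet

__all__ = [
    "PAIR_ORDER",
    "METHODS",
    "AdaptabilityScore",
    "pairwise_accuracy",
    "adaptability_score",
    "compute_adaptability",
    "method_consistency",
    "method_pipeline",
]

#: Canonical order of the six task pairs.
PAIR_ORDER: tuple[tuple[str, str], ...] = (
    ("left_hand", "right_hand"),
    ("left_hand", "foot"),
    ("left_hand", "tongue"),
    ("right_hand", "foot"),
    ("right_hand", "tongue"),
    ("foot", "tongue"),
)

#: Pairs of the 3-pair variant (tongue excluded).
PAIR_ORDER_3: tuple[tuple[str, str], ...] = (
    ("left_hand", "right_hand"),
    ("left_hand", "foot"),
    ("right_hand", "foot"),
)

METHODS: tuple[str, ...] = ("psd", "wavelet", "riemann", "fbcsp")


@dataclass
class AdaptabilityScore:
    """Six pairwise accuracies, their mean, and the 3-pair variant."""

    subject: str | int
    method: str
    pairwise: dict[tuple[str, str], float]
    mean: float = field(init=False)
    variant3: float = field(init=False)

    def __post_init__(self) -> None:
        if tuple(self.pairwise) != PAIR_ORDER:
            raise ValueError(
                f"pairwise accuracies must be given for the canonical six "
                f"pairs in order; got {tuple(self.pairwise)}"
            )
        vals = np.asarray(list(self.pairwise.values()), dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
        self.mean = float(vals.mean())
        self.variant3 = float(np.mean([self.pairwise[p] for p in PAIR_ORDER_3]))


def adaptability_score(
    per_pair_accuracies, subject="", method=""
) -> AdaptabilityScore:
    """Build an :class:`AdaptabilityScore` from six accuracies in canonical
    pair order."""
    vals = list(per_pair_accuracies)
    if len(vals) != len(PAIR_ORDER):
        raise ValueError(f"expected {len(PAIR_ORDER)} accuracies, got {len(vals)}")
    return AdaptabilityScore(subject, method, dict(zip(PAIR_ORDER, map(float, vals))))


def make_classifier(C: float = 1.0) -> Pipeline:
    """Feature standardization + linear maximum-margin classifier."""
    return Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(kernel="linear", C=C))]
    )


def method_pipeline(
    method: str,
    fs: float,
    channel_idx=None,
    n_pairs: int = 2,
    C: float = 1.0,
    **kwargs,
) -> Pipeline:
    """Full extractor -> scaler -> SVM pipeline for one feature method.

    Used inside cross-validation so that every trainable step sees only
    the training folds.
    """
    extractors = {
        "psd": lambda: PSDFeatures(fs=fs, channel_idx=channel_idx, **kwargs),
        "wavelet": lambda: WaveletFeatures(fs=fs, channel_idx=channel_idx, **kwargs),
        "riemann": lambda: RiemannFeatures(fs=fs, channel_idx=channel_idx, **kwargs),
        "fbcsp": lambda: FBCSPFeatures(fs=fs, n_pairs=n_pairs, **kwargs),
    }
    if method not in extractors:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    clf = make_classifier(C)
    return Pipeline([("features", extractors[method]())] + list(clf.steps))


def pairwise_accuracy(
    features: FeatureMatrix | None = None,
    folds: int = 10,
    seed: int = 0,
    *,
    X=None,
    y=None,
    estimator=None,
    C: float = 1.0,
) -> float:
    """Mean stratified k-fold CV accuracy for a two-class problem.

    Either pass a :class:`FeatureMatrix` (stateless features computed per
    epoch; standardization and the classifier are still fitted per fold),
    or raw epochs ``X, y`` with an ``estimator`` pipeline whose trainable
    transforms are then fitted fold-internally.
    """
    if features is not None:
        X, y = features.values, np.asarray(features.labels)
    if X is None or y is None:
        raise ValueError("provide a FeatureMatrix or X and y")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    if counts.min() < folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} samples "
            f"(< {folds} folds); reduce the number of folds"
        )
    if estimator is None:
        estimator = make_classifier(C)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(estimator, X, y, cv=cv, scoring="accuracy")
    return float(scores.mean())


def compute_adaptability(
    epochs: EpochSet,
    method: str = "psd",
    folds: int = 10,
    seed: int = 0,
    subject="",
    channels=SENSORIMOTOR_21,
    C: float = 1.0,
    **kwargs,
) -> AdaptabilityScore:
    """Adaptability of one subject with one feature method.

    PSD and wavelet features are per-epoch statistics without trainable
    state, so they are computed once and cross-validated as a feature
    matrix; CSP- and Riemannian-based features are refitted inside each
    training fold.
    """
    accs = []
    available = set(epochs.channel_names)
    channels = tuple(c for c in channels if c in available)
    for pair in PAIR_ORDER:
        sub = epochs.task_subset(*pair)
        if method == "psd":
            fm = psd_features(sub, channels=channels, **kwargs)
            acc = pairwise_accuracy(fm, folds=folds, seed=seed, C=C)
        elif method == "wavelet":
            fm = wavelet_features(sub, channels=channels, **kwargs)
            acc = pairwise_accuracy(fm, folds=folds, seed=seed, C=C)
        else:
            idx = sub.channel_indices(channels)
            pipe = method_pipeline(method, sub.fs, channel_idx=idx, C=C, **kwargs)
            if method == "fbcsp":
                pipe = method_pipeline(method, sub.fs, C=C, **kwargs)
            acc = pairwise_accuracy(
                X=sub.data, y=sub.labels, folds=folds, seed=seed, estimator=pipe
            )
        accs.append(acc)
    return adaptability_score(accs, subject=subject, method=method)


@dataclass
class CorrelationGrid:
    """Pairwise Pearson r and two-sided p between score columns."""

    r: pd.DataFrame
    p: pd.DataFrame


def method_consistency(scores: pd.DataFrame) -> CorrelationGrid:
    """Cross-method consistency of adaptability over subjects.

    ``scores`` is subjects x methods.  Returns Pearson r and p for every
    method pair; constant columns are rejected (undefined r).
    """
    if scores.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    cols = list(scores.columns)
    for c in cols:
        if np.isclose(np.std(scores[c].to_numpy(dtype=float)), 0.0):
            raise ValueError(f"method column {c!r} is constant; r undefined")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            res = stats.pearsonr(scores[a], scores[b])
            r.loc[a, b] = r.loc[b, a] = float(res.statistic)
            p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return CorrelationGrid(r=r, p=p)
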