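"""Jack-knife Euclidean template classification of taste identity.

Single trials of ensemble activity (spike counts in 250-ms bins over
250-1750 ms post-stimulus, i.e. six bins per unit) are compared, by
Euclidean distance in the concatenated unit x bin space, to per-taste
templates formed from the mean of all *other* trials; the held-out trial is
assigned the taste of the nearest template.  Chance is 25% with four tastes.
A cross-condition variant trains templates on one laser condition and tests
on the other, probing whether the taste code itself is reorganized by the
perturbation even when within-condition discriminability is intact.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import TASTES, EnsembleDataset, _normalize_condition

__all__ = [
    "ClassifierResult",
    "jackknife_classify",
    "cross_condition_classify",
    "classify_identity_epoch",
]


@dataclass
class ClassifierResult:
    """Confusion matrix and accuracies of a template-matching run."""

    confusion: pd.DataFrame          # rows = true taste, cols = predicted
    per_taste_accuracy: pd.Series
    overall_accuracy: float
    train_condition: str
    test_condition: str
    window_ms: tuple[float, float]
    bin_ms: float
    n_ties: int = 0

    def __post_init__(self):
        if not 0.0 <= self.overall_accuracy <= 1.0:
            raise ValueError("accuracy outside [0, 1]")


def _features(dataset: EnsembleDataset, mask: np.ndarray,
              window: tuple[float, float], bin_ms: float,
              units: np.ndarray | None):
    counts = dataset.bin_counts(window, int(bin_ms), trials=mask, units=units)
    X = counts.reshape(counts.shape[0], -1).astype(float)
    labels = dataset.trial_table.loc[mask, "taste"].to_numpy()
    return X, labels


def _score(X_test, labels_test, templates):
    """Assign each test row to the nearest template (fixed taste order
    breaks ties); returns (confusion counts 4x4, n_ties)."""
    conf = np.zeros((len(TASTES), len(TASTES)), int)
    n_ties = 0
    tidx = {t: i for i, t in enumerate(TASTES)}
    for x, lab in zip(X_test, labels_test):
        d = np.linalg.norm(templates - x[None, :], axis=1)
        pred = int(np.argmin(d))
        if np.sum(np.isclose(d, d[pred])) > 1:
            n_ties += 1
        conf[tidx[lab], pred] += 1
    return conf, n_ties


def _result(conf, n_ties, train, test, window, bin_ms) -> ClassifierResult:
    conf_df = pd.DataFrame(conf, index=list(TASTES), columns=list(TASTES))
    row_sums = conf_df.sum(axis=1)
    per_taste = pd.Series(np.diag(conf) / np.maximum(row_sums, 1),
                          index=list(TASTES))
    overall = float(np.trace(conf) / conf.sum())
    return ClassifierResult(
        confusion=conf_df,
        per_taste_accuracy=per_taste,
        overall_accuracy=overall,
        train_condition=train,
        test_condition=test,
        window_ms=window,
        bin_ms=bin_ms,
        n_ties=n_ties,
    )


def jackknife_classify(
    dataset: EnsembleDataset,
    condition,
    window: tuple[float, float] = (250.0, 1750.0),
    bin_ms: float = 250.0,
    units: np.ndarray | None = None,
) -> ClassifierResult:
    """Leave-one-trial-out nearest-template classification within a condition.

    For each held-out trial the per-taste templates are the mean binned
    responses of all remaining trials of that condition; the prediction is
    the taste whose template lies at minimal Euclidean distance.  Pass
    ``condition=None`` to pool both laser conditions.
    """
    cond = None if condition is None else _normalize_condition(condition)
    mask = dataset.trial_mask(laser=cond)
    X, labels = _features(dataset, mask, window, bin_ms, units)
    for t in TASTES:
        if np.sum(labels == t) < 2:
            raise ValueError(f"need >= 2 trials of {t} in condition")
    sums = {t: X[labels == t].sum(axis=0) for t in TASTES}
    ns = {t: int(np.sum(labels == t)) for t in TASTES}
    conf = np.zeros((len(TASTES), len(TASTES)), int)
    n_ties = 0
    tidx = {t: i for i, t in enumerate(TASTES)}
    for i in range(X.shape[0]):
        templates = np.stack(
            [
                (sums[t] - (X[i] if labels[i] == t else 0.0))
                / (ns[t] - (1 if labels[i] == t else 0))
                for t in TASTES
            ]
        )
        d = np.linalg.norm(templates - X[i][None, :], axis=1)
        pred = int(np.argmin(d))
        if np.sum(np.isclose(d, d[pred])) > 1:
            n_ties += 1
        conf[tidx[labels[i]], pred] += 1
    name = "On" if cond else "Off"
    return _result(conf, n_ties, name, name, window, bin_ms)


def cross_condition_classify(
    dataset: EnsembleDataset,
    train,
    test,
    window: tuple[float, float] = (250.0, 1750.0),
    bin_ms: float = 250.0,
    units: np.ndarray | None = None,
) -> ClassifierResult:
    """Train templates on one laser condition, score trials of the other.

    No jack-knifing is needed because train and test trials are disjoint.
    """
    tr = _normalize_condition(train)
    te = _normalize_condition(test)
    X_tr, lab_tr = _features(dataset, dataset.trial_mask(laser=tr), window,
                             bin_ms, units)
    X_te, lab_te = _features(dataset, dataset.trial_mask(laser=te), window,
                             bin_ms, units)
    if X_tr.shape[0] == 0 or X_te.shape[0] == 0:
        raise ValueError("both conditions must be populated")
    templates = np.stack([X_tr[lab_tr == t].mean(axis=0) for t in TASTES])
    conf, n_ties = _score(X_te, lab_te, templates)
    return _result(conf, n_ties, "On" if tr else "Off", "On" if te else "Off",
                   window, bin_ms)


def classify_identity_epoch(
    dataset: EnsembleDataset,
    condition,
    window: tuple[float, float] = (250.0, 750.0),
    bin_ms: float = 250.0,
    units: np.ndarray | None = None,
) -> ClassifierResult:
    """Jack-knife classification restricted to the identity epoch
    (two 250-ms bins over 250-750 ms)."""
    return jackknife_classify(dataset, condition, window=window, bin_ms=bin_ms,
                              units=units)
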