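"""Threshold classification on Kozak similarity scores.

Turns the KSS into a binary classifier: a balanced cutoff sweep that
averages misclassification over repeated majority-class subsamples, ROC
/ AUROC evaluation, and a proportion-above-threshold table that reads a
score as an approximate likelihood of initiation.

All subsampling is without replacement, and a score greater than or
equal to the cutoff predicts initiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve

#: The published sweep grid: 0.580 to 0.700 in steps of 0.001, used for
#: both the canonical and the near-cognate cutoff searches.
DEFAULT_GRID = np.round(np.arange(0.580, 0.700 + 1e-9, 0.001), 3)

DEFAULT_N_SIMULATIONS = 1000


@dataclass(frozen=True)
class SweepResult:
    cutoffs: np.ndarray
    mean_error: np.ndarray
    best_cutoff: float
    n_simulations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.cutoffs, "mean_error": self.mean_error})


@dataclass(frozen=True)
class RocSummary:
    points: np.ndarray  # (n, 2) of (false-positive rate, true-positive rate)
    auroc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["fpr", "tpr"])


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _balance(
    pos: np.ndarray, neg: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample the larger class, without replacement, to the smaller size."""
    if len(pos) > len(neg):
        pos = rng.choice(pos, size=len(neg), replace=False)
    elif len(neg) > len(pos):
        neg = rng.choice(neg, size=len(pos), replace=False)
    return pos, neg


def sweep_cutoffs(
    pos_scores,
    neg_scores,
    grid: np.ndarray | None = None,
    n_sim: int = DEFAULT_N_SIMULATIONS,
    rng_seed: np.random.Generator | int | None = None,
) -> SweepResult:
    """Find the cutoff minimising balanced mean misclassification.

    Each simulation subsamples the larger class to the smaller class's
    size; for every cutoff ``c`` the error is the fraction misclassified
    when ``score >= c`` predicts initiation.  Errors are averaged over
    simulations and ties in the argmin break toward the smaller cutoff
    (the more sensitive classifier).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score classes must be non-empty")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if len(grid) == 0 or (np.diff(grid) <= 0).any():
        raise ValueError("cutoff grid must be non-empty and strictly increasing")
    rng = _as_rng(rng_seed)

    total_error = np.zeros(len(grid))
    for _ in range(n_sim):
        p, n = _balance(pos, neg, rng)
        p = np.sort(p)
        n = np.sort(n)
        # false negatives: positives with score < c; false positives: negatives >= c
        fn = np.searchsorted(p, grid, side="left")
        fp = len(n) - np.searchsorted(n, grid, side="left")
        total_error += (fn + fp) / (len(p) + len(n))
    mean_error = total_error / n_sim
    best = float(grid[int(np.argmin(mean_error))])
    return SweepResult(grid, mean_error, best, n_sim)


def classify(scores, cutoff: float) -> np.ndarray:
    """Predict initiation for scores at or above the cutoff."""
    return np.asarray(scores, dtype=float) >= cutoff


def accuracy_at_cutoff(pos_scores, neg_scores, cutoff: float) -> float:
    """Balanced-set accuracy of the threshold rule on given score classes."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    correct = int((pos >= cutoff).sum()) + int((neg < cutoff).sum())
    return correct / (len(pos) + len(neg))


def roc_auroc(scores, labels) -> RocSummary:
    """ROC curve over all distinct score thresholds and its area.

    The area equals the Mann-Whitney probability that a random positive
    outscores a random negative, with ties counted one half.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires at least one positive and one negative label")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return RocSummary(points=np.column_stack([fpr, tpr]), auroc=float(auc(fpr, tpr)))


def proportion_above(
    pos_scores,
    neg_scores,
    thresholds: np.ndarray | None = None,
    n_sim: int = DEFAULT_N_SIMULATIONS,
    rng_seed: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Mean proportion of initiators among examples scoring above a threshold.

    Classes are balanced per simulation; for each threshold ``t`` the
    proportion is positives above ``t`` over all examples above ``t``.
    Thresholds with no examples above them in a simulation contribute no
    term; a threshold undefined in every simulation is reported as NaN.
    Default thresholds run from 0 to 1 in steps of 0.02.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score classes must be non-empty")
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0 + 1e-9, 0.02), 2)
    thresholds = np.asarray(thresholds, dtype=float)
    rng = _as_rng(rng_seed)

    sums = np.zeros(len(thresholds))
    counts = np.zeros(len(thresholds), dtype=int)
    for _ in range(n_sim):
        p, n = _balance(pos, neg, rng)
        p = np.sort(p)
        n = np.sort(n)
        p_above = len(p) - np.searchsorted(p, thresholds, side="right")
        n_above = len(n) - np.searchsorted(n, thresholds, side="right")
        total = p_above + n_above
        defined = total > 0
        sums[defined] += p_above[defined] / total[defined]
        counts += defined
    with np.errstate(invalid="ignore"):
        proportion = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"threshold": thresholds, "proportion": proportion})
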