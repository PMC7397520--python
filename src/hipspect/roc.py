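"""ROC analysis for negatively-oriented perfusion scores.

A perfusion ratio is a *negatively* oriented score — low values indicate
disease — so the sweep calls a case test-positive when its score is at or
below the threshold (``lower_is_positive``).  The curve is built over the
distinct observed scores with ties grouped at one threshold; the AUC is
the trapezoidal area, which on every input equals the Mann-Whitney
pair-counting estimate (ties contributing one half).

Cutoff derivation maximises the Youden index J = sensitivity +
specificity - 1, and the reported cutoff is the midpoint between the
bounding distinct scores, which is how a clean round operating point like
0.5 arises from two well-separated groups.

AUC comparison uses DeLong's method: per-case placement values give an
estimate of the covariance matrix of the two correlated AUCs, from which
a normal z-test on the AUC difference follows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InputError, RocError

Orientation = str  # {"lower_is_positive", "higher_is_positive"}

ORIENTATIONS = ("lower_is_positive", "higher_is_positive")


def _binarize(outcomes, positive_label) -> np.ndarray:
    arr = np.asarray(outcomes)
    if arr.dtype.kind in "USO":
        return arr == positive_label
    return arr.astype(bool)


def _validate(scores: np.ndarray, positive: np.ndarray) -> None:
    if scores.shape != positive.shape:
        raise InputError("scores and outcomes must have equal length")
    if scores.size == 0:
        raise InputError("empty inputs")
    if not np.all(np.isfinite(scores)):
        raise InputError("scores must be finite")
    if positive.all() or (~positive).all():
        raise RocError("ROC undefined: outcomes contain a single class")


@dataclass(frozen=True)
class RocCurve:
    """An oriented threshold sweep with its trapezoidal AUC."""

    thresholds: np.ndarray  # sentinel first, then distinct scores in sweep order
    fpr: np.ndarray
    tpr: np.ndarray
    orientation: Orientation
    auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class YoudenResult:
    """The operating point maximising J = sensitivity + specificity - 1.

    ``threshold`` is the observed score value at the optimum; ``cutoff`` is
    the reported midpoint between that score and the adjacent distinct
    score (when one exists), the value a reader would quote.
    """

    cutoff: float
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass(frozen=True)
class DelongResult:
    """Outcome of DeLong's AUC comparison."""

    auc_a: float
    auc_b: float
    variance_a: float
    variance_b: float
    covariance: float
    z_statistic: float
    p_value: float
    paired: bool


def roc_curve(
    scores: Sequence[float],
    outcomes,
    orientation: Orientation = "lower_is_positive",
    positive_label: str = "onfh",
) -> RocCurve:
    """Build the ROC curve of a score against binary outcomes.

    With ``lower_is_positive`` a case is called positive when its score is
    <= the threshold, and the sweep runs from a -inf sentinel (no calls)
    upward to the maximum score (all calls); ``higher_is_positive`` mirrors
    this from +inf downward.
    """
    if orientation not in ORIENTATIONS:
        raise InputError(f"unknown orientation {orientation!r}")
    scores = np.asarray(scores, dtype=float)
    positive = _binarize(outcomes, positive_label)
    _validate(scores, positive)
    n_pos = int(positive.sum())
    n_neg = int(scores.size - n_pos)

    distinct = np.unique(scores)  # ascending
    if orientation == "lower_is_positive":
        thresholds = np.concatenate(([-np.inf], distinct))
        called = scores[None, :] <= thresholds[:, None]
    else:
        thresholds = np.concatenate(([np.inf], distinct[::-1]))
        called = scores[None, :] >= thresholds[:, None]
    tpr = (called & positive[None, :]).sum(axis=1) / n_pos
    fpr = (called & ~positive[None, :]).sum(axis=1) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        orientation=orientation,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _psi_matrix(pos: np.ndarray, neg: np.ndarray, orientation: Orientation) -> np.ndarray:
    """Pairwise concordance: 1 concordant, 1/2 tied, 0 discordant."""
    diff = pos[:, None] - neg[None, :]
    if orientation == "lower_is_positive":
        return np.where(diff < 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))


def auc_mann_whitney(
    scores: Sequence[float],
    outcomes,
    orientation: Orientation = "lower_is_positive",
    positive_label: str = "onfh",
) -> float:
    """AUC as the Mann-Whitney proportion of concordant positive-negative pairs."""
    if orientation not in ORIENTATIONS:
        raise InputError(f"unknown orientation {orientation!r}")
    scores = np.asarray(scores, dtype=float)
    positive = _binarize(outcomes, positive_label)
    _validate(scores, positive)
    psi = _psi_matrix(scores[positive], scores[~positive], orientation)
    return float(psi.mean())


def youden_cutoff(curve: RocCurve) -> YoudenResult:
    """The threshold maximising the Youden index.

    Ties in J are broken toward higher specificity, then toward the
    threshold nearer the sweep's start (the lower threshold for a
    lower-is-positive score).  When the optimum lies at an observed score
    with a distinct neighbour further along the sweep, the midpoint of the
    two is reported as the cutoff.
    """
    j = curve.tpr - curve.fpr
    order = sorted(
        range(len(j)), key=lambda i: (-j[i], curve.fpr[i], i)
    )
    best = order[0]
    threshold = float(curve.thresholds[best])
    if best + 1 < len(curve.thresholds) and np.isfinite(threshold):
        cutoff = (threshold + float(curve.thresholds[best + 1])) / 2.0
    else:
        cutoff = threshold
    return YoudenResult(
        cutoff=cutoff,
        threshold=threshold,
        sensitivity=float(curve.tpr[best]),
        specificity=1.0 - float(curve.fpr[best]),
        youden_j=float(j[best]),
    )


def _placements(
    scores: np.ndarray, positive: np.ndarray, orientation: Orientation
) -> tuple[float, np.ndarray, np.ndarray]:
    psi = _psi_matrix(scores[positive], scores[~positive], orientation)
    v10 = psi.mean(axis=1)  # one per positive case
    v01 = psi.mean(axis=0)  # one per negative case
    return float(psi.mean()), v10, v01


def _component_cov(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sample covariance matrix of two placement vectors (0 when length 1)."""
    if x.size < 2:
        return np.zeros((2, 2))
    return np.cov(np.vstack([x, y]), ddof=1)


def auc_delong_variance(
    scores: Sequence[float],
    outcomes,
    orientation: Orientation = "lower_is_positive",
    positive_label: str = "onfh",
) -> tuple[float, float]:
    """AUC of a single curve with its DeLong variance estimate."""
    scores = np.asarray(scores, dtype=float)
    positive = _binarize(outcomes, positive_label)
    _validate(scores, positive)
    auc, v10, v01 = _placements(scores, positive, orientation)
    s10 = float(np.var(v10, ddof=1)) if v10.size > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if v01.size > 1 else 0.0
    return auc, s10 / v10.size + s01 / v01.size


def delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcomes,
    paired: bool = True,
    orientation: Orientation = "lower_is_positive",
    positive_label: str = "onfh",
    outcomes_b=None,
) -> DelongResult:
    """Compare two AUCs by DeLong's placement-value method.

    In paired mode both score vectors belong to the same cases (the usual
    situation: two scores per patient) and the placement covariance between
    the curves enters the variance of the AUC difference; in unpaired mode
    the two curves come from independent case sets (``outcomes_b`` gives
    the second set's labels) and the covariance is zero.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if orientation not in ORIENTATIONS:
        raise InputError(f"unknown orientation {orientation!r}")

    if paired:
        if outcomes_b is not None:
            raise InputError("outcomes_b is only meaningful for unpaired comparison")
        positive = _binarize(outcomes, positive_label)
        _validate(scores_a, positive)
        _validate(scores_b, positive)
        if positive.sum() < 2 or (~positive).sum() < 2:
            raise RocError("DeLong test needs at least two cases per class")
        auc_a, v10_a, v01_a = _placements(scores_a, positive, orientation)
        auc_b, v10_b, v01_b = _placements(scores_b, positive, orientation)
        m, n = v10_a.size, v01_a.size
        s10 = _component_cov(v10_a, v10_b)
        s01 = _component_cov(v01_a, v01_b)
        var_a = s10[0, 0] / m + s01[0, 0] / n
        var_b = s10[1, 1] / m + s01[1, 1] / n
        cov = s10[0, 1] / m + s01[0, 1] / n
    else:
        if outcomes_b is None:
            raise InputError("unpaired comparison requires outcomes_b")
        pos_a = _binarize(outcomes, positive_label)
        pos_b = _binarize(outcomes_b, positive_label)
        _validate(scores_a, pos_a)
        _validate(scores_b, pos_b)
        if min(pos_a.sum(), (~pos_a).sum(), pos_b.sum(), (~pos_b).sum()) < 2:
            raise RocError("DeLong test needs at least two cases per class")
        auc_a, var_a = auc_delong_variance(scores_a, pos_a, orientation)
        auc_b, var_b = auc_delong_variance(scores_b, pos_b, orientation)
        cov = 0.0

    identical = paired and np.array_equal(scores_a, scores_b)
    var_diff = var_a + var_b - 2 * cov
    if identical or (var_diff <= 0 and np.isclose(auc_a, auc_b)):
        z, p = 0.0, 1.0
    elif var_diff <= 0:
        raise RocError(
            "degenerate variance: AUCs differ but the estimated variance of the "
            "difference is zero"
        )
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return DelongResult(
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        variance_a=float(var_a),
        variance_b=float(var_b),
        covariance=float(cov),
        z_statistic=float(z),
        p_value=float(p),
        paired=paired,
    )
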