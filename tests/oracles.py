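"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's vectorised code paths: plane means
are accumulated voxel by voxel in Python loops, AUCs are counted pair by
pair, and likelihood-ratio intervals are recomputed from the raw SE
formulas.  They are slow and simple on purpose.
"""

from __future__ import annotations

import math

import numpy as np

CORTICAL = 2
PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


def brute_force_plane_mean(
    counts, labels, spacing, center, radius, plane, exclude_cortical=True
):
    """Per-voxel enumeration of a central-disc plane mean.

    Returns (mean, n_voxels); raises ValueError when no voxel qualifies.
    """
    counts = np.asarray(counts, dtype=float)
    axis = PLANE_AXIS[plane]
    k = int(round(center[axis] / spacing[axis]))
    if not 0 <= k < counts.shape[axis]:
        raise ValueError("central plane outside volume")
    in_plane = [a for a in range(3) if a != axis]
    a, b = in_plane
    values = []
    for ia in range(counts.shape[a]):
        for ib in range(counts.shape[b]):
            d2 = (ia * spacing[a] - center[a]) ** 2 + (ib * spacing[b] - center[b]) ** 2
            if d2 > radius * radius:
                continue
            idx = [0, 0, 0]
            idx[axis] = k
            idx[a] = ia
            idx[b] = ib
            idx = tuple(idx)
            if exclude_cortical and labels is not None and labels[idx] == CORTICAL:
                continue
            values.append(counts[idx])
    if not values:
        raise ValueError("no eligible voxel")
    # selection is the brute-force part; reduce with the same pairwise mean
    # as the implementation so "exact" is not about float summation order
    return float(np.mean(values)), len(values)


def disc_voxel_count(shape2d, spacing2d, center2d, radius):
    """Closed-disc voxel-centre count by direct enumeration."""
    n = 0
    for i in range(shape2d[0]):
        for j in range(shape2d[1]):
            d2 = (i * spacing2d[0] - center2d[0]) ** 2 + (
                j * spacing2d[1] - center2d[1]
            ) ** 2
            if d2 <= radius * radius:
                n += 1
    return n


def pair_count_auc(scores, positive, lower_is_positive=True):
    """AUC by exhaustive positive-negative pair counting."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    pos = scores[positive]
    neg = scores[~positive]
    total = 0.0
    for p in pos:
        for q in neg:
            if p == q:
                total += 0.5
            elif (p < q) == lower_is_positive:
                total += 1.0
    return total / (len(pos) * len(neg))


def exhaustive_youden(scores, positive, lower_is_positive=True):
    """Best (J, sens, spec) over every distinct-score threshold."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    best = (-math.inf, None, None)
    for t in np.unique(scores):
        called = scores <= t if lower_is_positive else scores >= t
        sens = (called & positive).sum() / positive.sum()
        spec = (~called & ~positive).sum() / (~positive).sum()
        j = sens + spec - 1
        if j > best[0]:
            best = (j, sens, spec)
    return best


def log_method_lr_cis(tp, fp, fn, tn, z=1.959963984540054):
    """Hand transcription of the log-method LR confidence intervals."""
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    lr_pos = sens / (1 - spec)
    lr_neg = (1 - sens) / spec
    se_pos = math.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
    se_neg = math.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
    ci_pos = (lr_pos * math.exp(-z * se_pos), lr_pos * math.exp(z * se_pos))
    ci_neg = (lr_neg * math.exp(-z * se_neg), lr_neg * math.exp(z * se_neg))
    return lr_pos, ci_pos, lr_neg, ci_neg
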