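"""2x2 diagnostic accuracy metrics and likelihood ratios with CIs.

A perfusion call (decreased vs normal uptake) is crossed with the observed
outcome (osteonecrosis vs bone union) into a 2x2 table, from which
sensitivity, specificity, accuracy, and the positive/negative likelihood
ratios are computed.  Likelihood-ratio confidence intervals use the log
method: ``exp(ln(LR) +/- z * SE(ln LR))`` with

    SE(ln LR+) = sqrt(1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn))
    SE(ln LR-) = sqrt(1/fn - 1/(tp+fn) + 1/tn - 1/(fp+tn))

Everything is kept at full precision internally; rounding to presentation
precision is left to the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .errors import InputError, ParameterError

ONFH = "onfh"
UNION = "union"
PREDICTED_ONFH = "predicted_onfh"
PREDICTED_VIABLE = "predicted_viable"


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts; positive = predicted perfusion loss & observed ONFH."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ParameterError(f"{name} must be a nonnegative integer, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Observed ONFH cases."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Observed union cases."""
        return self.fp + self.tn

    def haldane(self) -> "ContingencyTableFloat":
        """The table with 0.5 added to every cell (zero-cell correction)."""
        return ContingencyTableFloat(
            self.tp + 0.5, self.fp + 0.5, self.fn + 0.5, self.tn + 0.5
        )


@dataclass(frozen=True)
class ContingencyTableFloat:
    """Internal: a Haldane-corrected table with non-integer cells."""

    tp: float
    fp: float
    fn: float
    tn: float

    @property
    def n_positive(self) -> float:
        return self.tp + self.fn

    @property
    def n_negative(self) -> float:
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticSummary:
    """Accuracy metrics, with likelihood ratios when computed."""

    sensitivity: float
    specificity: float
    accuracy: float
    lr_pos: Optional[float] = None
    lr_neg: Optional[float] = None
    ci_lr_pos: Optional[tuple[float, float]] = None
    ci_lr_neg: Optional[tuple[float, float]] = None
    alpha: float = 0.05

    def __post_init__(self):
        for name in ("sensitivity", "specificity", "accuracy"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class LikelihoodRatios:
    """LR+ and LR- with log-method confidence intervals.

    An infinite LR+ (specificity 1) or an LR- of 0 (sensitivity 1) is
    reported as such with the CI omitted.  ``haldane_corrected`` flags that
    the CI (only) was computed on a +0.5-per-cell table.
    """

    lr_pos: float
    lr_neg: float
    ci_lr_pos: Optional[tuple[float, float]]
    ci_lr_neg: Optional[tuple[float, float]]
    alpha: float
    haldane_corrected: bool = False


def contingency(
    outcomes: Sequence[str], predictions: Sequence[str]
) -> ContingencyTable:
    """Cross observed outcomes with predictions into a 2x2 table."""
    if len(outcomes) != len(predictions):
        raise InputError(
            f"length mismatch: {len(outcomes)} outcomes vs {len(predictions)} predictions"
        )
    if len(outcomes) == 0:
        raise InputError("empty label sequences")
    tp = fp = fn = tn = 0
    for i, (obs, pred) in enumerate(zip(outcomes, predictions)):
        if obs not in (ONFH, UNION):
            raise InputError(f"unknown outcome label {obs!r} at position {i}")
        if pred not in (PREDICTED_ONFH, PREDICTED_VIABLE):
            raise InputError(f"unknown prediction label {pred!r} at position {i}")
        if pred == PREDICTED_ONFH:
            if obs == ONFH:
                tp += 1
            else:
                fp += 1
        else:
            if obs == ONFH:
                fn += 1
            else:
                tn += 1
    return ContingencyTable(tp, fp, fn, tn)


def accuracy_metrics(table: ContingencyTable) -> DiagnosticSummary:
    """Sensitivity, specificity and accuracy of a 2x2 table."""
    if table.n_positive == 0:
        raise InputError("sensitivity undefined: no observed-positive cases")
    if table.n_negative == 0:
        raise InputError("specificity undefined: no observed-negative cases")
    return DiagnosticSummary(
        sensitivity=table.tp / table.n_positive,
        specificity=table.tn / table.n_negative,
        accuracy=(table.tp + table.tn) / table.total,
    )


def _log_ci(lr: float, se: float, alpha: float) -> tuple[float, float]:
    z = stats.norm.ppf(1 - alpha / 2)
    return (lr * math.exp(-z * se), lr * math.exp(z * se))


def likelihood_ratios(
    table: ContingencyTable, alpha: float = 0.05, haldane: bool = False
) -> LikelihoodRatios:
    """LR+ = sens/(1-spec) and LR- = (1-sens)/spec with log-method CIs.

    With ``haldane=True`` a +0.5-per-cell corrected table is used for the
    CI computation only, allowing intervals in the presence of zero cells;
    the point estimates always come from the raw counts.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    m = accuracy_metrics(table)
    sens, spec = m.sensitivity, m.specificity

    lr_pos = math.inf if spec == 1.0 else sens / (1 - spec)
    lr_neg = (1 - sens) / spec if spec > 0 else math.inf

    ci_table = table.haldane() if haldane else table
    ci_pos = ci_neg = None
    # CI defined only for finite nonzero LRs with no zero cell in the SE terms
    if math.isfinite(lr_pos) and lr_pos > 0 and ci_table.tp > 0 and ci_table.fp > 0:
        se = math.sqrt(
            1 / ci_table.tp
            - 1 / ci_table.n_positive
            + 1 / ci_table.fp
            - 1 / ci_table.n_negative
        )
        ci_pos = _log_ci(lr_pos, se, alpha)
    if math.isfinite(lr_neg) and lr_neg > 0 and ci_table.fn > 0 and ci_table.tn > 0:
        se = math.sqrt(
            1 / ci_table.fn
            - 1 / ci_table.n_positive
            + 1 / ci_table.tn
            - 1 / ci_table.n_negative
        )
        ci_neg = _log_ci(lr_neg, se, alpha)

    return LikelihoodRatios(
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        ci_lr_pos=ci_pos,
        ci_lr_neg=ci_neg,
        alpha=alpha,
        haldane_corrected=haldane,
    )


def evaluate_table(table: ContingencyTable, alpha: float = 0.05) -> DiagnosticSummary:
    """Full diagnostic summary: accuracy metrics plus likelihood ratios."""
    m = accuracy_metrics(table)
    lrs = likelihood_ratios(table, alpha=alpha)
    return DiagnosticSummary(
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        accuracy=m.accuracy,
        lr_pos=lrs.lr_pos,
        lr_neg=lrs.lr_neg,
        ci_lr_pos=lrs.ci_lr_pos,
        ci_lr_neg=lrs.ci_lr_neg,
        alpha=alpha,
    )
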