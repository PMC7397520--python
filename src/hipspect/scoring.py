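"""Perfusion scores and cutoff classification.

Absolute SPECT counts vary with injected dose, uptake time and patient
physiology, so the femoral head's uptake is expressed relative to a
reference site:

* **head-to-head ratio** — mean ROI uptake of the affected femoral head
  divided by that of the contralateral (unaffected) head;
* **head-to-acetabulum ratio** — affected head uptake divided by the
  ipsilateral acetabular-dome uptake, the fallback reference when the
  contralateral hip is incomparable (metal implant, osteonecrosis or
  osteoarthritis on that side).

Both ratios are invariant to global count scaling, which is the point of
the relative method.  A low ratio means a perfusion deficit, so a case is
classified as predicted osteonecrosis when its ratio is at or below the
cutoff (ties count as positive — conservative toward detecting necrosis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

from .errors import InputError, ScoreError

AffectedSide = Literal["left", "right"]
ContralateralStatus = Literal["healthy", "implant", "onfh", "oa"]
Outcome = Literal["onfh", "union"]
Prediction = Literal["predicted_onfh", "predicted_viable"]
Reference = Literal["contralateral_head", "ipsilateral_acetabulum"]

CONTRALATERAL_STATUSES = ("healthy", "implant", "onfh", "oa")

PREDICTED_ONFH: Prediction = "predicted_onfh"
PREDICTED_VIABLE: Prediction = "predicted_viable"


@dataclass
class PatientRecord:
    """One patient of the cohort: uptakes, scores, and outcome.

    ``head_to_head_ratio`` is the ground-truth/measured ratio and is stored
    whenever it is known, even for patients whose contralateral hip is
    incomparable; reference selection only controls which ratio feeds the
    primary classification, so that summaries over the whole cohort remain
    possible.
    """

    patient_id: str
    affected_side: AffectedSide
    contralateral_status: ContralateralStatus
    outcome: Outcome
    uptake_head_affected: Optional[float] = None
    uptake_head_unaffected: Optional[float] = None
    uptake_acetabulum_affected: Optional[float] = None
    head_to_head_ratio: Optional[float] = None
    head_to_acetabulum_ratio: Optional[float] = None
    landmarks: Optional[dict[str, tuple[float, float, float]]] = None
    volume_path: Optional[str] = None
    structure_path: Optional[str] = None

    def __post_init__(self):
        if self.contralateral_status not in CONTRALATERAL_STATUSES:
            raise InputError(
                f"unknown contralateral status {self.contralateral_status!r}"
            )
        if self.outcome not in ("onfh", "union"):
            raise InputError(f"unknown outcome {self.outcome!r}")
        for name in ("head_to_head_ratio", "head_to_acetabulum_ratio"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ScoreError(f"{name} must be positive, got {v}")


def head_to_head_ratio(affected_mean: float, unaffected_mean: float) -> float:
    """Affected femoral-head uptake divided by the contralateral head's."""
    if unaffected_mean <= 0:
        raise ScoreError(
            f"unaffected head uptake must be positive, got {unaffected_mean}"
        )
    if affected_mean <= 0:
        raise ScoreError(f"affected head uptake must be positive, got {affected_mean}")
    return affected_mean / unaffected_mean


def head_to_acetabulum_ratio(head_mean: float, dome_mean: float) -> float:
    """Affected femoral-head uptake divided by the ipsilateral dome's."""
    if dome_mean <= 0:
        raise ScoreError(f"acetabular dome uptake must be positive, got {dome_mean}")
    if head_mean <= 0:
        raise ScoreError(f"affected head uptake must be positive, got {head_mean}")
    return head_mean / dome_mean


def select_reference(record: PatientRecord) -> Reference:
    """Choose the reference site for a patient's primary score.

    A healthy contralateral hip serves as the reference; when it carries an
    implant, osteonecrosis or osteoarthritis its uptake is not comparable
    and the ipsilateral acetabular dome is substituted.
    """
    status = record.contralateral_status
    if status == "healthy":
        return "contralateral_head"
    if status in ("implant", "onfh", "oa"):
        return "ipsilateral_acetabulum"
    raise InputError(f"unknown contralateral status {status!r}")


def classify_perfusion(ratio: float, cutoff: float) -> Prediction:
    """Threshold a perfusion ratio: at or below the cutoff predicts ONFH."""
    if ratio <= 0:
        raise ScoreError(f"ratio must be positive, got {ratio}")
    if cutoff <= 0:
        raise ScoreError(f"cutoff must be positive, got {cutoff}")
    return PREDICTED_ONFH if ratio <= cutoff else PREDICTED_VIABLE


def primary_ratio(record: PatientRecord) -> float:
    """The ratio selected by the reference rule for this patient."""
    ref = select_reference(record)
    if ref == "contralateral_head":
        if record.head_to_head_ratio is None:
            raise ScoreError(
                f"patient {record.patient_id}: head-to-head ratio missing for "
                "healthy contralateral hip"
            )
        return record.head_to_head_ratio
    if record.head_to_acetabulum_ratio is None:
        raise ScoreError(
            f"patient {record.patient_id}: head-to-acetabulum ratio missing"
        )
    return record.head_to_acetabulum_ratio


def score_record(
    record: PatientRecord,
    cutoff: float = 0.5,
) -> tuple[Reference, float, Prediction]:
    """Apply reference selection then cutoff classification to one patient."""
    ref = select_reference(record)
    ratio = primary_ratio(record)
    return ref, ratio, classify_perfusion(ratio, cutoff)
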