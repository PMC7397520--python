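"""End-to-end orchestration: simulate -> quantify -> score -> evaluate.

A run takes a :class:`RunConfig`, generates a synthetic cohort, optionally
renders and quantifies a voxel phantom per patient (``phantom`` mode) or
works directly from the drawn ratios (``stats`` mode), classifies every
patient at the configured cutoffs, and produces a single report holding:

* per-group means with normal-theory 95% CIs for uptakes and both ratios
  (the group-comparison table),
* a 2x2 contingency evaluation (sensitivity/specificity/accuracy and
  likelihood ratios with CIs) per configured cutoff, plus one for the
  reference-selection rule (head-to-head when the contralateral hip is
  healthy, head-to-acetabulum otherwise),
* ROC curves, Youden-index cutoffs and a paired DeLong AUC comparison of
  the two ratio scores.

Runs are deterministic under a fixed seed, and every intermediate artifact
(manifest, quantification table, scored table, report) is written to the
output directory in plain-text form.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, roc, scoring
from .errors import HipspectError, InputError
from .phantom import (
    AnatomyModel,
    CohortSpec,
    TruncatedRatio,
    UptakeParams,
    build_hip_phantom,
    records_to_frame,
    simulate_cohort,
    write_cohort_manifest,
    write_structure,
    write_volume,
)
from .roi import (
    ACETABULAR_ROI_DIAMETER_MM,
    HEAD_ROI_DIAMETER_MM,
    make_acetabular_roi,
    make_head_roi,
    roi_mean_uptake,
)
from .scoring import PatientRecord

logger = logging.getLogger(__name__)

Z_95 = 1.96

DEFAULT_CUTOFFS = {"head_to_head": 0.5, "head_to_acetabulum": 0.3}


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs."""

    cohort: CohortSpec = CohortSpec()
    anatomy: AnatomyModel = AnatomyModel()
    mode: str = "stats"  # {"stats", "phantom"}
    noise_model: str = "none"  # phantom mode only: {"none", "poisson"}
    head_roi_diameter_mm: float = HEAD_ROI_DIAMETER_MM
    dome_roi_diameter_mm: float = ACETABULAR_ROI_DIAMETER_MM
    cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    alpha: float = 0.05
    seed: int = 0
    write_volumes: bool = False

    def __post_init__(self):
        if self.mode not in ("stats", "phantom"):
            raise InputError(f"unknown pipeline mode {self.mode!r}")
        if self.noise_model not in ("none", "poisson"):
            raise InputError(f"unknown noise model {self.noise_model!r}")
        unknown = set(self.cutoffs) - {"head_to_head", "head_to_acetabulum"}
        if unknown:
            raise InputError(f"unknown cutoff keys {sorted(unknown)}")

    # -- YAML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "cohort" in data and isinstance(data["cohort"], dict):
            c = dict(data["cohort"])
            for key in (
                "ratio_distribution_onfh",
                "ratio_distribution_union",
                "acetabular_ratio_onfh",
                "acetabular_ratio_union",
            ):
                if key in c and isinstance(c[key], dict):
                    c[key] = TruncatedRatio(**c[key])
            data["cohort"] = CohortSpec(**c)
        if "anatomy" in data and isinstance(data["anatomy"], dict):
            a = dict(data["anatomy"])
            for key, v in a.items():
                if isinstance(v, list):
                    a[key] = tuple(v)
            data["anatomy"] = AnatomyModel(**a)
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# phantom-mode quantification


def quantify_patient(
    record: PatientRecord,
    config: RunConfig,
    out_dir: Optional[Path] = None,
) -> dict:
    """Render one patient's phantom and measure the three ROIs.

    The phantom's affected-head and acetabular rates are chosen so that the
    noiseless tissue rates reproduce the patient's drawn ratios; with
    Poisson noise the measured ratios scatter around them.  Returns the
    three combined means plus per-plane detail.
    """
    uptake = UptakeParams(
        cancellous_head_rate_affected=record.uptake_head_affected,
        cancellous_head_rate_unaffected=record.uptake_head_unaffected,
        acetabular_rate=record.uptake_acetabulum_affected,
        noise_model=config.noise_model,  # type: ignore[arg-type]
        seed=(config.seed * 1000003 + int(record.patient_id[1:])) % (2**31),
        affected_side=record.affected_side,
    )
    volume, structure = build_hip_phantom(config.anatomy, uptake)
    affected = record.affected_side
    unaffected = "right" if affected == "left" else "left"
    sites = {
        "head_affected": make_head_roi(
            volume, structure, config.anatomy.head_center(affected),
            diameter=config.head_roi_diameter_mm,
        ),
        "head_unaffected": make_head_roi(
            volume, structure, config.anatomy.head_center(unaffected),
            diameter=config.head_roi_diameter_mm,
        ),
        "acetabulum_affected": make_acetabular_roi(
            volume, structure, config.anatomy.dome_center(affected),
            diameter=config.dome_roi_diameter_mm,
        ),
    }
    measurements = {
        site: roi_mean_uptake(volume, r, structure) for site, r in sites.items()
    }
    if out_dir is not None and config.write_volumes:
        write_volume(volume, out_dir / f"{record.patient_id}_counts.nii.gz")
        write_structure(structure, out_dir / f"{record.patient_id}_labels.nii.gz")
    return measurements


def _quantification_rows(record: PatientRecord, measurements: dict) -> list[dict]:
    rows = []
    for site, m in measurements.items():
        rows.append(
            {
                "patient_id": record.patient_id,
                "site": site,
                "coronal_mean": m.plane_means[0],
                "axial_mean": m.plane_means[1],
                "sagittal_mean": m.plane_means[2],
                "combined_mean": m.combined_mean,
                "n_voxels_coronal": m.n_voxels_per_plane[0],
                "n_voxels_axial": m.n_voxels_per_plane[1],
                "n_voxels_sagittal": m.n_voxels_per_plane[2],
                "mode": m.mode,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# group summaries (the two-group comparison table)

_SUMMARY_QUANTITIES = (
    "uptake_head_affected",
    "uptake_head_unaffected",
    "uptake_acetabulum_affected",
    "head_to_head_ratio",
    "head_to_acetabulum_ratio",
)


def table3_summary(records: list[PatientRecord]) -> dict:
    """Per-group mean and normal-theory 95% CI for uptakes and both ratios.

    The CI is ``mean +/- 1.96 * sd / sqrt(n)`` (z, not t — matching the
    convention used to parameterise the generator); groups of size < 2 get
    their CI omitted with a flag.
    """
    out: dict = {}
    for group in ("onfh", "union"):
        members = [r for r in records if r.outcome == group]
        out[group] = {"n": len(members)}
        for q in _SUMMARY_QUANTITIES:
            values = np.array(
                [getattr(r, q) for r in members if getattr(r, q) is not None]
            )
            if values.size == 0:
                out[group][q] = {"mean": None, "ci": None, "n": 0, "ci_omitted": True}
                continue
            mean = float(values.mean())
            if values.size < 2:
                out[group][q] = {
                    "mean": mean, "ci": None, "n": int(values.size), "ci_omitted": True,
                }
                continue
            half = Z_95 * float(values.std(ddof=1)) / np.sqrt(values.size)
            out[group][q] = {
                "mean": mean,
                "ci": (mean - half, mean + half),
                "n": int(values.size),
                "ci_omitted": False,
            }
    return out


# ---------------------------------------------------------------------------
# the run itself


@dataclass
class RunReport:
    config: RunConfig
    records: list[PatientRecord]
    table3: dict
    evaluations: dict
    roc_results: dict
    delong: Optional[roc.DelongResult]
    quantification: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        def _eval_dict(e):
            d = dataclasses.asdict(e["summary"])
            d["table"] = dataclasses.asdict(e["table"])
            d["cutoff"] = e["cutoff"]
            return d

        out = {
            "config": self.config.to_dict(),
            "n_patients": len(self.records),
            "n_onfh": sum(r.outcome == "onfh" for r in self.records),
            "table3": self.table3,
            "evaluations": {k: _eval_dict(v) for k, v in self.evaluations.items()},
            "roc": {
                k: {
                    "auc": v["curve"].auc,
                    "n_pos": v["curve"].n_pos,
                    "n_neg": v["curve"].n_neg,
                    "youden": dataclasses.asdict(v["youden"]),
                }
                for k, v in self.roc_results.items()
            },
        }
        if self.delong is not None:
            out["delong"] = dataclasses.asdict(self.delong)
        return out


def _evaluate_cutoff(records, ratios, cutoff, alpha):
    outcomes = [r.outcome for r in records]
    predictions = [
        scoring.classify_perfusion(ratio, cutoff) for ratio in ratios
    ]
    table = diagnostics.contingency(outcomes, predictions)
    summary = diagnostics.evaluate_table(table, alpha=alpha)
    return {"table": table, "summary": summary, "cutoff": cutoff, "predictions": predictions}


def run_pipeline(config: RunConfig, out_dir=None) -> RunReport:
    """Execute one full run; see the module docstring for the stages."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    cohort_spec = replace(config.cohort, seed=config.seed)
    logger.info("simulating cohort: %d ONFH + %d union, seed %d",
                cohort_spec.n_onfh, cohort_spec.n_union, config.seed)
    records = simulate_cohort(cohort_spec)

    quant_frame = None
    if config.mode == "phantom":
        rows = []
        for record in records:
            try:
                measurements = quantify_patient(record, config, out)
            except HipspectError as exc:
                raise type(exc)(
                    f"quantification stage, patient {record.patient_id}: {exc}"
                ) from exc
            rows.extend(_quantification_rows(record, measurements))
            record.uptake_head_affected = measurements["head_affected"].combined_mean
            record.uptake_head_unaffected = measurements["head_unaffected"].combined_mean
            record.uptake_acetabulum_affected = measurements[
                "acetabulum_affected"
            ].combined_mean
            record.head_to_head_ratio = scoring.head_to_head_ratio(
                record.uptake_head_affected, record.uptake_head_unaffected
            )
            record.head_to_acetabulum_ratio = scoring.head_to_acetabulum_ratio(
                record.uptake_head_affected, record.uptake_acetabulum_affected
            )
            record.landmarks = {
                "head_affected": config.anatomy.head_center(record.affected_side),
                "head_unaffected": config.anatomy.head_center(
                    "right" if record.affected_side == "left" else "left"
                ),
                "dome_affected": config.anatomy.dome_center(record.affected_side),
            }
        quant_frame = pd.DataFrame(rows)

    evaluations = {}
    for ratio_name, cutoff in config.cutoffs.items():
        attr = f"{ratio_name}_ratio"
        ratios = [getattr(r, attr) for r in records]
        evaluations[ratio_name] = _evaluate_cutoff(
            records, ratios, cutoff, config.alpha
        )
    # the reference-substitution rule: each patient classified on the ratio
    # its contralateral status allows, at that ratio's own cutoff
    ref_ratios, ref_cutoffs = [], []
    for r in records:
        ref = scoring.select_reference(r)
        if ref == "contralateral_head":
            ref_ratios.append(r.head_to_head_ratio)
            ref_cutoffs.append(config.cutoffs.get("head_to_head", 0.5))
        else:
            ref_ratios.append(r.head_to_acetabulum_ratio)
            ref_cutoffs.append(config.cutoffs.get("head_to_acetabulum", 0.3))
    outcomes = [r.outcome for r in records]
    ref_predictions = [
        scoring.classify_perfusion(ratio, c) for ratio, c in zip(ref_ratios, ref_cutoffs)
    ]
    ref_table = diagnostics.contingency(outcomes, ref_predictions)
    evaluations["reference_selected"] = {
        "table": ref_table,
        "summary": diagnostics.evaluate_table(ref_table, alpha=config.alpha),
        "cutoff": dict(config.cutoffs),
        "predictions": ref_predictions,
    }

    roc_results = {}
    for ratio_name in ("head_to_head", "head_to_acetabulum"):
        scores = [getattr(r, f"{ratio_name}_ratio") for r in records]
        curve = roc.roc_curve(scores, outcomes, orientation="lower_is_positive")
        roc_results[ratio_name] = {"curve": curve, "youden": roc.youden_cutoff(curve)}

    delong = None
    if len(records) >= 4:
        delong = roc.delong_test(
            [r.head_to_head_ratio for r in records],
            [r.head_to_acetabulum_ratio for r in records],
            outcomes,
            paired=True,
        )

    report = RunReport(
        config=config,
        records=records,
        table3=table3_summary(records),
        evaluations=evaluations,
        roc_results=roc_results,
        delong=delong,
        quantification=quant_frame,
    )
    if out is not None:
        _write_artifacts(report, out)
    return report


def _write_artifacts(report: RunReport, out: Path) -> None:
    write_cohort_manifest(report.records, out / "cohort_manifest.csv")
    if report.quantification is not None:
        report.quantification.to_csv(out / "quantification.csv", index=False)
    scored = records_to_frame(report.records)
    for name, ev in report.evaluations.items():
        scored[f"prediction_{name}"] = ev["predictions"]
    scored.to_csv(out / "scored_cohort.csv", index=False)
    for name, res in report.roc_results.items():
        curve = res["curve"]
        pd.DataFrame(
            {
                "threshold": curve.thresholds,
                "sensitivity": curve.tpr,
                "specificity": 1 - curve.fpr,
                "youden_j": curve.tpr - curve.fpr,
            }
        ).to_csv(out / f"roc_{name}.csv", index=False)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, default=_json_default))
    (out / "report.txt").write_text(format_report(report))


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _fmt_ci(ci) -> str:
    return "-" if ci is None else f"({ci[0]:.2f}, {ci[1]:.2f})"


def format_report(report: RunReport) -> str:
    """Human-readable text rendering of the run report."""
    lines = []
    n = len(report.records)
    n_onfh = sum(r.outcome == "onfh" for r in report.records)
    lines.append(f"Cohort: {n} patients ({n_onfh} ONFH, {n - n_onfh} union), "
                 f"seed {report.config.seed}, mode {report.config.mode}")
    lines.append("")
    lines.append("Group comparison (mean, 95% CI):")
    for group, stats_ in report.table3.items():
        lines.append(f"  {group} (n={stats_['n']}):")
        for q in _SUMMARY_QUANTITIES:
            s = stats_[q]
            if s["mean"] is None:
                continue
            ci = "CI omitted" if s["ci"] is None else f"({s['ci'][0]:.2f}-{s['ci'][1]:.2f})"
            lines.append(f"    {q}: {s['mean']:.2f} {ci}")
    lines.append("")
    for name, ev in report.evaluations.items():
        t, s = ev["table"], ev["summary"]
        lines.append(
            f"Cutoff evaluation [{name}] at {ev['cutoff']}: "
            f"TP={t.tp} FP={t.fp} FN={t.fn} TN={t.tn}"
        )
        lines.append(
            f"  sensitivity {100 * s.sensitivity:.1f}%  "
            f"specificity {100 * s.specificity:.1f}%  "
            f"accuracy {100 * s.accuracy:.1f}%"
        )
        lr_pos = "inf" if s.lr_pos is not None and np.isinf(s.lr_pos) else f"{s.lr_pos:.2f}"
        lines.append(
            f"  LR+ {lr_pos} {_fmt_ci(s.ci_lr_pos)}  LR- {s.lr_neg:.2f} {_fmt_ci(s.ci_lr_neg)}"
        )
    lines.append("")
    for name, res in report.roc_results.items():
        y = res["youden"]
        lines.append(
            f"ROC [{name}]: AUC {res['curve'].auc:.3f}; Youden cutoff {y.cutoff:.3f} "
            f"(sens {100 * y.sensitivity:.1f}%, spec {100 * y.specificity:.1f}%)"
        )
    if report.delong is not None:
        d = report.delong
        lines.append(
            f"DeLong comparison: AUC {d.auc_a:.3f} vs {d.auc_b:.3f}, "
            f"z = {d.z_statistic:.3f}, p = {d.p_value:.3f}"
        )
    lines.append("")
    return "\n".join(lines)
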