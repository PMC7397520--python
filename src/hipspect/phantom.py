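"""Synthetic hip SPECT/CT phantom and cohort generator.

No public imaging data exist for this analysis, so every downstream stage
is exercised on synthetic data with the statistical structure the method
assumes.  Two levels are provided:

* :func:`build_hip_phantom` — a voxel phantom of a pelvis region: two
  femoral heads (cancellous core wrapped in a cortical shell), two
  acetabular domes, and uniform background, each tissue class with its own
  expected count rate, optionally Poisson-sampled.  The affected head's
  cancellous rate is reduced relative to the healthy side, emulating the
  perfusion-deficit lesion the ROI analysis is designed to detect.
* :func:`simulate_cohort` — cohort-level draws of the two perfusion ratios
  from truncated normal group distributions, standing in for a fracture
  cohort followed to bone union or osteonecrosis (ONFH).

Group ratio distributions are parameterised by their group mean, a
standard deviation back-computed from a normal-theory 95% CI half-width
(``sd = half_width * sqrt(n) / 1.96``), and truncation bounds.  The
truncated normal's location is calibrated so that the *truncated* mean
equals the stated group mean; the generator's job is to reproduce the
group means, and asymmetric truncation would otherwise bias them.

Geometry uses a desk-scale 96-cubed grid at isotropic 2.95 mm voxels
rather than a clinical 512x512 matrix; all distances are in mm, so ROI
geometry is unchanged.  World coordinate = voxel index * spacing; seeds
are explicit fields, never global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import CohortError, GeometryError, ManifestError, ParameterError
from .roi import (
    ACETABULAR,
    BACKGROUND,
    CANCELLOUS,
    CORTICAL,
    StructureVolume,
    VoxelVolume,
)
from .scoring import CONTRALATERAL_STATUSES, PatientRecord

# default expected count rates per voxel, one per tissue class; head rates
# follow the affected/unaffected group means of the ratio analysis
DEFAULT_BACKGROUND_RATE = 10.0
DEFAULT_AFFECTED_HEAD_RATE = 66.3
DEFAULT_UNAFFECTED_HEAD_RATE = 201.3
DEFAULT_CORTICAL_RATE = 100.0
DEFAULT_ACETABULAR_RATE = 319.1

DEFAULT_VOXEL_MM = 2.95
DEFAULT_GRID = (96, 96, 96)


def sd_from_ci_half_width(half_width: float, n: int, z: float = 1.96) -> float:
    """Back-compute a group sd from a normal-theory 95% CI half-width."""
    if half_width < 0 or n < 1:
        raise ParameterError("half_width must be >= 0 and n >= 1")
    return half_width * math.sqrt(n) / z


@dataclass(frozen=True)
class AnatomyModel:
    """Analytic geometry of the phantom, in world millimetres."""

    femoral_head_center_left: tuple[float, float, float] = (80.0, 140.0, 115.0)
    femoral_head_center_right: tuple[float, float, float] = (200.0, 140.0, 115.0)
    femoral_head_radius: float = 22.0
    cortical_shell_thickness: float = 3.0
    acetabular_dome_center_left: tuple[float, float, float] = (95.0, 140.0, 150.0)
    acetabular_dome_center_right: tuple[float, float, float] = (185.0, 140.0, 150.0)
    acetabular_dome_radius: float = 10.0
    volume_shape: tuple[int, int, int] = DEFAULT_GRID
    voxel_spacing: tuple[float, float, float] = (DEFAULT_VOXEL_MM,) * 3

    def __post_init__(self):
        if self.femoral_head_radius <= 0 or self.acetabular_dome_radius <= 0:
            raise ParameterError("all radii must be positive")
        if not 0 < self.cortical_shell_thickness < self.femoral_head_radius:
            raise ParameterError(
                "cortical shell thickness must be positive and smaller than the head radius"
            )
        if any(s <= 0 for s in self.voxel_spacing):
            raise ParameterError("voxel spacing must be positive")
        ext = self.extent_mm()
        for name in ("femoral_head_center_left", "femoral_head_center_right"):
            c = getattr(self, name)
            r = self.femoral_head_radius
            if any(ci - r < 0 or ci + r > ei for ci, ei in zip(c, ext)):
                raise GeometryError(f"{name} sphere extends outside the volume bounds")

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(
            (n - 1) * s for n, s in zip(self.volume_shape, self.voxel_spacing)
        )  # type: ignore[return-value]

    def head_center(self, side: Literal["left", "right"]) -> tuple[float, float, float]:
        return (
            self.femoral_head_center_left
            if side == "left"
            else self.femoral_head_center_right
        )

    def dome_center(self, side: Literal["left", "right"]) -> tuple[float, float, float]:
        return (
            self.acetabular_dome_center_left
            if side == "left"
            else self.acetabular_dome_center_right
        )


@dataclass(frozen=True)
class UptakeParams:
    """Expected counts per voxel for each tissue class.

    ``noise_model='none'`` reproduces the rates exactly as voxel values;
    ``'poisson'`` draws each voxel from a Poisson with that mean, the noise
    model appropriate for photon counting.
    """

    background_rate: float = DEFAULT_BACKGROUND_RATE
    cancellous_head_rate_affected: float = DEFAULT_AFFECTED_HEAD_RATE
    cancellous_head_rate_unaffected: float = DEFAULT_UNAFFECTED_HEAD_RATE
    cortical_rate: float = DEFAULT_CORTICAL_RATE
    acetabular_rate: float = DEFAULT_ACETABULAR_RATE
    noise_model: Literal["poisson", "none"] = "none"
    seed: int = 0
    affected_side: Literal["left", "right"] = "left"

    def __post_init__(self):
        rates = (
            self.background_rate,
            self.cancellous_head_rate_affected,
            self.cancellous_head_rate_unaffected,
            self.cortical_rate,
            self.acetabular_rate,
        )
        if any(r < 0 for r in rates):
            raise ParameterError(f"uptake rates must be nonnegative, got {rates}")
        if self.noise_model not in ("poisson", "none"):
            raise ParameterError(f"unknown noise model {self.noise_model!r}")
        if self.affected_side not in ("left", "right"):
            raise ParameterError(f"affected_side must be left or right")


def _sphere(shape, spacing, center, radius) -> np.ndarray:
    x = (np.arange(shape[0], dtype=float) * spacing[0])[:, None, None]
    y = (np.arange(shape[1], dtype=float) * spacing[1])[None, :, None]
    z = (np.arange(shape[2], dtype=float) * spacing[2])[None, None, :]
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return d2 <= radius * radius


def build_hip_phantom(
    anatomy: AnatomyModel, uptake: UptakeParams
) -> tuple[VoxelVolume, StructureVolume]:
    """Build one paired (photon-count, tissue-label) phantom.

    Voxel class assignment is voxel-centre-inside-analytic-shape, with the
    femoral heads taking precedence over the domes should they ever overlap;
    there is no partial-volume blending.  Each voxel's expected value is the
    rate of its tissue class; in Poisson mode the counts are sampled with
    the params' seed.
    """
    shape, spacing = anatomy.volume_shape, anatomy.voxel_spacing
    labels = np.full(shape, BACKGROUND, dtype=np.int16)
    rates = np.full(shape, uptake.background_rate, dtype=float)

    for side in ("left", "right"):
        dome = _sphere(shape, spacing, anatomy.dome_center(side), anatomy.acetabular_dome_radius)
        labels[dome] = ACETABULAR
        rates[dome] = uptake.acetabular_rate

    core_radius = anatomy.femoral_head_radius - anatomy.cortical_shell_thickness
    for side in ("left", "right"):
        center = anatomy.head_center(side)
        outer = _sphere(shape, spacing, center, anatomy.femoral_head_radius)
        core = _sphere(shape, spacing, center, core_radius)
        shell = outer & ~core
        labels[shell] = CORTICAL
        rates[shell] = uptake.cortical_rate
        labels[core] = CANCELLOUS
        rates[core] = (
            uptake.cancellous_head_rate_affected
            if side == uptake.affected_side
            else uptake.cancellous_head_rate_unaffected
        )

    if uptake.noise_model == "poisson":
        rng = np.random.default_rng(uptake.seed)
        counts = rng.poisson(rates).astype(float)
    else:
        counts = rates
    return VoxelVolume(counts, spacing), StructureVolume(labels, spacing)


# ---------------------------------------------------------------------------
# cohort-level ratio distributions


@dataclass(frozen=True)
class TruncatedRatio:
    """A truncated-normal group distribution for a perfusion ratio.

    ``mean`` is the mean of the *truncated* distribution: the underlying
    normal's location is calibrated (by root finding) so that truncation
    does not shift the group mean away from the stated value.  ``sd`` is
    the underlying normal's scale; ``sd = 0`` degenerates to a point mass
    at the mean.
    """

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.sd < 0:
            raise ParameterError(f"sd must be nonnegative, got {self.sd}")
        if not self.lower < self.upper:
            raise ParameterError(
                f"truncation bounds must satisfy lower < upper, got "
                f"[{self.lower}, {self.upper}]"
            )
        if not self.lower <= self.mean <= self.upper:
            raise ParameterError(
                f"mean {self.mean} outside truncation bounds [{self.lower}, {self.upper}]"
            )

    def _calibrated_loc(self) -> float:
        """Location of the parent normal whose truncated mean equals ``mean``."""
        if self.sd == 0:
            return self.mean

        def trunc_mean(loc: float) -> float:
            a = (self.lower - loc) / self.sd
            b = (self.upper - loc) / self.sd
            return float(stats.truncnorm.mean(a, b, loc=loc, scale=self.sd))

        span = self.upper - self.lower
        lo, hi = self.lower - 10 * self.sd - span, self.upper + 10 * self.sd + span
        return float(optimize.brentq(lambda m: trunc_mean(m) - self.mean, lo, hi, xtol=1e-12))

    def frozen(self):
        """The calibrated scipy distribution (``None`` when degenerate)."""
        if self.sd == 0:
            return None
        loc = self._calibrated_loc()
        a = (self.lower - loc) / self.sd
        b = (self.upper - loc) / self.sd
        return stats.truncnorm(a, b, loc=loc, scale=self.sd)

    def ppf(self, u) -> np.ndarray:
        """Quantile function (point mass at the mean when sd = 0)."""
        u = np.asarray(u, dtype=float)
        dist = self.frozen()
        if dist is None:
            return np.full_like(u, self.mean)
        return np.asarray(dist.ppf(u))


# defaults reproduce the reported group means with sds back-computed from
# normal-theory 95% CIs (n=6 ONFH, n=24 union); head-to-head bounds keep the
# groups on opposite sides of the 0.5 cutoff, mirroring the reported perfect
# separation of the observed sample
DEFAULT_H2H_ONFH = TruncatedRatio(0.33, sd_from_ci_half_width(0.05, 6), 0.18, 0.45)
DEFAULT_H2H_UNION = TruncatedRatio(1.30, sd_from_ci_half_width(0.27, 24), 0.55, 2.50)
DEFAULT_H2A_ONFH = TruncatedRatio(0.22, sd_from_ci_half_width(0.04, 6), 0.10, 0.29)
DEFAULT_H2A_UNION = TruncatedRatio(0.93, sd_from_ci_half_width(0.21, 24), 0.35, 2.20)

# contralateral-incomparable statuses in the proportions reported for the
# six affected patients: four implants, one contralateral ONFH, one OA
INCOMPARABLE_STATUSES = ("implant", "onfh", "oa")
INCOMPARABLE_PROBS = (4 / 6, 1 / 6, 1 / 6)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated fracture cohort."""

    n_onfh: int = 6
    n_union: int = 24
    ratio_distribution_onfh: TruncatedRatio = DEFAULT_H2H_ONFH
    ratio_distribution_union: TruncatedRatio = DEFAULT_H2H_UNION
    acetabular_ratio_onfh: TruncatedRatio = DEFAULT_H2A_ONFH
    acetabular_ratio_union: TruncatedRatio = DEFAULT_H2A_UNION
    fraction_incomparable_contralateral: float = 6 / 30
    unaffected_head_uptake: float = DEFAULT_UNAFFECTED_HEAD_RATE
    seed: int = 0

    def __post_init__(self):
        if self.n_onfh < 0 or self.n_union < 0:
            raise CohortError("group sizes must be nonnegative")
        if not 0 <= self.fraction_incomparable_contralateral <= 1:
            raise ParameterError("fraction_incomparable_contralateral must be in [0, 1]")
        if self.unaffected_head_uptake <= 0:
            raise ParameterError("unaffected_head_uptake must be positive")


def simulate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw one cohort of patient records.

    Each patient's two perfusion ratios are drawn comonotonically (one
    latent uniform mapped through both groups' quantile functions), so a
    patient with poor head-to-head perfusion also has a poor
    head-to-acetabulum score — the within-patient coupling real scores
    exhibit, since both share the affected-head numerator.  A
    spec-determined fraction of patients is flagged contralateral-
    incomparable with statuses drawn from implant/ONFH/osteoarthritis.
    The drawn head-to-head ratio is stored for every record (it is the
    generator's ground truth); reference selection downstream decides
    which ratio a patient is classified on.
    """
    n_total = spec.n_onfh + spec.n_union
    if n_total == 0:
        raise CohortError("cohort must contain at least one patient")
    rng = np.random.default_rng(spec.seed)

    outcomes = ["onfh"] * spec.n_onfh + ["union"] * spec.n_union
    u = rng.uniform(size=n_total)
    h2h = np.empty(n_total)
    h2a = np.empty(n_total)
    onfh_slice = slice(0, spec.n_onfh)
    union_slice = slice(spec.n_onfh, n_total)
    h2h[onfh_slice] = spec.ratio_distribution_onfh.ppf(u[onfh_slice])
    h2h[union_slice] = spec.ratio_distribution_union.ppf(u[union_slice])
    h2a[onfh_slice] = spec.acetabular_ratio_onfh.ppf(u[onfh_slice])
    h2a[union_slice] = spec.acetabular_ratio_union.ppf(u[union_slice])

    n_incomparable = int(round(spec.fraction_incomparable_contralateral * n_total))
    incomparable = set(
        rng.choice(n_total, size=n_incomparable, replace=False).tolist()
    )
    sides = rng.choice(["left", "right"], size=n_total)

    records = []
    for i in range(n_total):
        if i in incomparable:
            status = str(rng.choice(INCOMPARABLE_STATUSES, p=INCOMPARABLE_PROBS))
        else:
            status = "healthy"
        unaffected = spec.unaffected_head_uptake
        affected = h2h[i] * unaffected
        acetabulum = affected / h2a[i]
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:03d}",
                affected_side=str(sides[i]),  # type: ignore[arg-type]
                contralateral_status=status,  # type: ignore[arg-type]
                outcome=outcomes[i],  # type: ignore[arg-type]
                uptake_head_affected=float(affected),
                uptake_head_unaffected=float(unaffected),
                uptake_acetabulum_affected=float(acetabulum),
                head_to_head_ratio=float(h2h[i]),
                head_to_acetabulum_ratio=float(h2a[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# manifest and volume I/O

MANIFEST_REQUIRED = ("patient_id", "affected_side", "contralateral_status", "outcome")
_FLOAT_COLUMNS = (
    "uptake_head_affected",
    "uptake_head_unaffected",
    "uptake_acetabulum_affected",
    "head_to_head_ratio",
    "head_to_acetabulum_ratio",
)
_LANDMARK_KEYS = ("head_affected", "head_unaffected", "dome_affected")
_PATH_COLUMNS = ("volume_path", "structure_path")


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {k: getattr(r, k) for k in MANIFEST_REQUIRED}
        for k in _FLOAT_COLUMNS + _PATH_COLUMNS:
            row[k] = getattr(r, k)
        for key in _LANDMARK_KEYS:
            coords = (r.landmarks or {}).get(key)
            for axis, v in zip("xyz", coords if coords is not None else (None,) * 3):
                row[f"{key}_{axis}"] = v
        rows.append(row)
    columns = (
        list(MANIFEST_REQUIRED)
        + list(_FLOAT_COLUMNS)
        + [f"{k}_{a}" for k in _LANDMARK_KEYS for a in "xyz"]
        + list(_PATH_COLUMNS)
    )
    return pd.DataFrame(rows, columns=columns)


def write_cohort_manifest(records: Sequence[PatientRecord], path) -> None:
    """Write the cohort to a CSV manifest (header-only when empty)."""
    records_to_frame(records).to_csv(path, index=False)


def _cell(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return v


def read_cohort_manifest(path) -> list[PatientRecord]:
    """Read a cohort manifest; inverse of :func:`write_cohort_manifest`."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MANIFEST_REQUIRED if c not in frame.columns]
    if missing:
        raise ManifestError(f"manifest {path} is missing columns: {missing}")
    records = []
    for idx, row in frame.iterrows():
        data = row.to_dict()
        landmarks = {}
        for key in _LANDMARK_KEYS:
            coords = tuple(_cell(data, f"{key}_{a}") for a in "xyz")
            if all(c is not None for c in coords):
                landmarks[key] = tuple(float(c) for c in coords)
        try:
            records.append(
                PatientRecord(
                    patient_id=str(data["patient_id"]),
                    affected_side=data["affected_side"],
                    contralateral_status=data["contralateral_status"],
                    outcome=data["outcome"],
                    **{k: _cell(data, k) for k in _FLOAT_COLUMNS},
                    landmarks=landmarks or None,
                    volume_path=_cell(data, "volume_path"),
                    structure_path=_cell(data, "structure_path"),
                )
            )
        except Exception as exc:
            raise ManifestError(f"manifest {path}, row {idx}: {exc}") from exc
    return records


def write_volume(volume: VoxelVolume, path) -> None:
    """Write a photon-count volume as NIfTI-1 with the spacing in the affine."""
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.counts.astype(np.float32), affine), str(path))


def write_structure(structure: StructureVolume, path) -> None:
    affine = np.diag(list(structure.spacing) + [1.0])
    nib.save(nib.Nifti1Image(structure.labels.astype(np.int16), affine), str(path))


def read_volume(path) -> VoxelVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelVolume(np.asarray(img.dataobj, dtype=float), spacing)


def read_structure(path) -> StructureVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return StructureVolume(np.asarray(img.dataobj).astype(np.int16), spacing)
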