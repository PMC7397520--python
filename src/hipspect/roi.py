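"""Spherical-ROI photon-uptake quantification.

A reconstructed SPECT volume is sampled with spheres of fixed physical
diameter: 30 mm centred on the femoral head and 10 mm at the acetabular
dome.  The mean uptake of a sphere is computed the way it is read off a
clinical workstation: the mean over the sphere's central cross-sectional
disc in each of the three orthogonal planes (coronal, axial, sagittal),
then the arithmetic mean of those three per-plane values.  A full-3-D
sphere mean is available as an alternative mode and is flagged as such in
the measurement metadata.

Voxels labelled cortical in the paired structure volume are excluded from
all samples when the ROI carries the ``exclude_cortical`` rule; the head
ROI is meant to capture cancellous bone only, since the dense cortical
shell takes up tracer for reasons unrelated to head perfusion.

Conventions, applied identically everywhere:

* world coordinate of voxel index ``i`` along an axis = ``i * spacing``
  (0-based, axis order x = left-right, y = anterior-posterior,
  z = inferior-superior);
* a voxel belongs to a disc/sphere when its centre lies within the radius,
  ties at exactly the radius included (closed ball);
* ROIs that extend past the volume edge are clipped: only in-bounds voxels
  are sampled and the reduced voxel count is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import GeometryError, MeasurementError, ParameterError

logger = logging.getLogger(__name__)

# tissue-class codes shared with the phantom's structure volumes
BACKGROUND = 0
CANCELLOUS = 1
CORTICAL = 2
ACETABULAR = 3

TISSUE_NAMES = {
    BACKGROUND: "background",
    CANCELLOUS: "cancellous",
    CORTICAL: "cortical",
    ACETABULAR: "acetabular_dome",
}

HEAD_ROI_DIAMETER_MM = 30.0
ACETABULAR_ROI_DIAMETER_MM = 10.0

Plane = Literal["coronal", "axial", "sagittal"]
#: axis held fixed for each plane's central cross-section
PLANE_AXIS: dict[str, int] = {"sagittal": 0, "coronal": 1, "axial": 2}


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in np.atleast_1d(np.asarray(spacing, dtype=float)))
    if len(s) == 1:
        s = s * 3
    if len(s) != 3:
        raise ParameterError(f"spacing must be scalar or length 3, got {spacing!r}")
    if any(v <= 0 for v in s):
        raise ParameterError(f"voxel spacing must be positive, got {s}")
    return s  # type: ignore[return-value]


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D nonnegative photon-count grid with physical voxel spacing (mm)."""

    counts: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 3:
            raise ParameterError(f"counts must be 3-D, got shape {counts.shape}")
        if np.any(counts < 0):
            raise ParameterError("photon counts must be nonnegative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "spacing", _as_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape  # type: ignore[return-value]

    def extent_mm(self) -> tuple[float, float, float]:
        """World coordinate of the last voxel centre along each axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]


@dataclass(frozen=True)
class StructureVolume:
    """Integer tissue-class labels co-registered with a :class:`VoxelVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ParameterError(f"labels must be 3-D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            labels = labels.astype(np.int16)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "spacing", _as_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SphericalROI:
    """A sphere of fixed physical diameter placed in world (mm) coordinates."""

    center: tuple[float, float, float]
    diameter: float
    exclusion: Literal["exclude_cortical", "none"] = "exclude_cortical"

    def __post_init__(self):
        if self.diameter <= 0:
            raise ParameterError(f"ROI diameter must be positive, got {self.diameter}")
        if self.exclusion not in ("exclude_cortical", "none"):
            raise ParameterError(f"unknown exclusion rule {self.exclusion!r}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class UptakeMeasurement:
    """Mean uptake of one ROI.

    ``mode`` records whether the value came from the three-orthogonal-plane
    protocol (the default, matching workstation practice) or from the full
    3-D sphere; in three-plane mode ``combined_mean`` is the arithmetic
    mean of the three plane means.
    """

    plane_means: Optional[tuple[float, float, float]]  # (coronal, axial, sagittal)
    combined_mean: float
    n_voxels_per_plane: Optional[tuple[int, int, int]]
    mode: Literal["three_plane", "sphere"] = "three_plane"
    n_voxels_total: Optional[int] = None

    def __post_init__(self):
        if self.mode == "three_plane":
            if self.plane_means is None or self.n_voxels_per_plane is None:
                raise ParameterError("three_plane measurement requires per-plane data")
            if any(n < 1 for n in self.n_voxels_per_plane):
                raise ParameterError("each plane must sample at least one voxel")
            expected = float(np.mean(self.plane_means))
            if not np.isclose(self.combined_mean, expected, rtol=0, atol=1e-9):
                raise ParameterError("combined_mean must equal the mean of plane means")


def _check_paired(volume: VoxelVolume, structure: Optional[StructureVolume]) -> None:
    if structure is not None and structure.shape != volume.shape:
        raise ParameterError(
            f"structure shape {structure.shape} does not match volume {volume.shape}"
        )


def _sphere_intersects(volume: VoxelVolume, roi: SphericalROI) -> bool:
    ext = volume.extent_mm()
    # nearest point of the voxel-centre bounding box to the ROI centre
    nearest = [min(max(c, 0.0), e) for c, e in zip(roi.center, ext)]
    d2 = sum((c - q) ** 2 for c, q in zip(roi.center, nearest))
    return d2 <= roi.radius**2


def make_head_roi(
    volume: VoxelVolume,
    structure: StructureVolume,
    head_center: Sequence[float],
    diameter: float = HEAD_ROI_DIAMETER_MM,
) -> SphericalROI:
    """Place the femoral-head ROI: a 30 mm sphere centred on the head.

    The sphere is aimed at the head centre so that it contains the maximum
    amount of cancellous bone; cortical-labelled voxels are excluded from
    every sample taken through it.
    """
    _check_paired(volume, structure)
    roi = SphericalROI(tuple(head_center), diameter, exclusion="exclude_cortical")
    if not _sphere_intersects(volume, roi):
        raise GeometryError(f"head ROI at {roi.center} lies entirely outside the volume")
    return roi


def make_acetabular_roi(
    volume: VoxelVolume,
    structure: StructureVolume,
    dome_center: Sequence[float],
    diameter: float = ACETABULAR_ROI_DIAMETER_MM,
) -> SphericalROI:
    """Place the acetabular-dome ROI: a 10 mm sphere at the dome.

    The dome offers little cancellous space, so a fixed 10 mm diameter is
    used for every patient.  If the sphere reaches outside the dome's
    cancellous bone a warning is logged; cortical voxels are excluded from
    the samples regardless.
    """
    _check_paired(volume, structure)
    roi = SphericalROI(tuple(dome_center), diameter, exclusion="exclude_cortical")
    if not _sphere_intersects(volume, roi):
        raise GeometryError(f"dome ROI at {roi.center} lies entirely outside the volume")
    mask = _sphere_mask(volume, roi)
    labels = structure.labels[mask]
    if labels.size and np.any((labels != ACETABULAR) & (labels != CANCELLOUS)):
        logger.warning(
            "acetabular ROI at %s exceeds available cancellous space "
            "(%d/%d voxels outside cancellous/dome tissue)",
            roi.center,
            int(np.sum((labels != ACETABULAR) & (labels != CANCELLOUS))),
            labels.size,
        )
    return roi


def _axis_coords(n: int, spacing: float) -> np.ndarray:
    return np.arange(n, dtype=float) * spacing


def _sphere_mask(volume: VoxelVolume, roi: SphericalROI) -> np.ndarray:
    cx, cy, cz = roi.center
    sx, sy, sz = volume.spacing
    nx, ny, nz = volume.shape
    x = _axis_coords(nx, sx)[:, None, None]
    y = _axis_coords(ny, sy)[None, :, None]
    z = _axis_coords(nz, sz)[None, None, :]
    d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    return d2 <= roi.radius * roi.radius


def _plane_disc(
    volume: VoxelVolume, roi: SphericalROI, plane: str
) -> tuple[tuple, np.ndarray]:
    """Index of the central slice and the in-plane closed-disc mask."""
    if plane not in PLANE_AXIS:
        raise ParameterError(f"unknown plane {plane!r}")
    axis = PLANE_AXIS[plane]
    spacing = volume.spacing
    k = int(round(roi.center[axis] / spacing[axis]))
    if not 0 <= k < volume.shape[axis]:
        raise MeasurementError(
            f"central {plane} plane of ROI at {roi.center} lies outside the volume"
        )
    in_plane = [a for a in range(3) if a != axis]
    a, b = in_plane
    ca = _axis_coords(volume.shape[a], spacing[a])
    cb = _axis_coords(volume.shape[b], spacing[b])
    d2 = (ca[:, None] - roi.center[a]) ** 2 + (cb[None, :] - roi.center[b]) ** 2
    disc = d2 <= roi.radius * roi.radius
    index: list = [slice(None)] * 3
    index[axis] = k
    return tuple(index), disc


def _plane_sample(
    volume: VoxelVolume,
    roi: SphericalROI,
    plane: str,
    structure: Optional[StructureVolume],
) -> tuple[float, int]:
    _check_paired(volume, structure)
    index, disc = _plane_disc(volume, roi, plane)
    eligible = disc
    if roi.exclusion == "exclude_cortical":
        if structure is None:
            raise ParameterError(
                "exclude_cortical ROI requires a StructureVolume (or a CT-threshold mask)"
            )
        eligible = disc & (structure.labels[index] != CORTICAL)
    values = volume.counts[index][eligible]
    if values.size == 0:
        raise MeasurementError(
            f"no eligible voxel in the central {plane} plane of ROI at {roi.center}; "
            "the ROI is likely misplaced"
        )
    return float(values.mean()), int(values.size)


def plane_mean_uptake(
    volume: VoxelVolume,
    roi: SphericalROI,
    plane: Plane,
    structure: Optional[StructureVolume] = None,
) -> float:
    """Mean uptake over the ROI's central cross-sectional disc in one plane.

    The disc is the set of voxel centres in the single central slice (the
    slice whose coordinate is nearest the ROI centre along the plane's
    normal) within the ROI radius of the centre, closed at the boundary.
    Cortical voxels are removed first when the ROI excludes cortex.
    """
    mean, _ = _plane_sample(volume, roi, plane, structure)
    return mean


def roi_mean_uptake(
    volume: VoxelVolume,
    roi: SphericalROI,
    structure: Optional[StructureVolume] = None,
    mode: Literal["three_plane", "sphere"] = "three_plane",
) -> UptakeMeasurement:
    """Measure an ROI's mean uptake.

    In ``three_plane`` mode (the reference protocol) the coronal, axial and
    sagittal central-disc means are averaged; in ``sphere`` mode the mean is
    taken over every eligible voxel of the full ball.  The two modes are
    distinguished by the ``mode`` field of the returned measurement.
    """
    if mode == "sphere":
        _check_paired(volume, structure)
        mask = _sphere_mask(volume, roi)
        if roi.exclusion == "exclude_cortical":
            if structure is None:
                raise ParameterError("exclude_cortical ROI requires a StructureVolume")
            mask = mask & (structure.labels != CORTICAL)
        values = volume.counts[mask]
        if values.size == 0:
            raise MeasurementError(f"no eligible voxel in spherical ROI at {roi.center}")
        return UptakeMeasurement(
            plane_means=None,
            combined_mean=float(values.mean()),
            n_voxels_per_plane=None,
            mode="sphere",
            n_voxels_total=int(values.size),
        )
    samples = [_plane_sample(volume, roi, p, structure) for p in ("coronal", "axial", "sagittal")]
    means = tuple(m for m, _ in samples)
    counts = tuple(n for _, n in samples)
    return UptakeMeasurement(
        plane_means=means,  # type: ignore[arg-type]
        combined_mean=float(np.mean(means)),
        n_voxels_per_plane=counts,  # type: ignore[arg-type]
        mode="three_plane",
        n_voxels_total=int(sum(counts)),
    )


def cortical_mask_from_ct(
    ct_hu: np.ndarray, threshold_hu: float = 400.0
) -> np.ndarray:
    """Boolean cortical mask from a CT intensity volume.

    On real fused SPECT/CT data no tissue-label channel exists; thresholding
    the CT at a configurable Hounsfield value is the accepted substitute for
    the label-based cortical exclusion (dense cortical bone is typically
    above a few hundred HU).
    """
    return np.asarray(ct_hu) >= threshold_hu


def structure_from_ct(
    ct_hu: np.ndarray, spacing, threshold_hu: float = 400.0
) -> StructureVolume:
    """Wrap a CT-threshold cortical mask as a two-class StructureVolume."""
    labels = np.where(cortical_mask_from_ct(ct_hu, threshold_hu), CORTICAL, CANCELLOUS)
    return StructureVolume(labels.astype(np.int16), spacing)
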