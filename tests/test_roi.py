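"""Spherical-ROI sampling against brute-force voxel enumeration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hipspect import (
    AnatomyModel,
    SphericalROI,
    StructureVolume,
    UptakeParams,
    VoxelVolume,
    build_hip_phantom,
    make_acetabular_roi,
    make_head_roi,
    plane_mean_uptake,
    roi_mean_uptake,
)
from hipspect.errors import GeometryError, MeasurementError, ParameterError
from hipspect.roi import CANCELLOUS, CORTICAL
from oracles import brute_force_plane_mean, disc_voxel_count

PLANES = ("coronal", "axial", "sagittal")


def _uniform_volume(value=5.0, n=9, spacing=1.0):
    return VoxelVolume(np.full((n, n, n), value), (spacing,) * 3)


class TestPlaneMeans:
    def test_uniform_volume_gives_constant_mean(self):
        vol = _uniform_volume(3.5)
        roi = SphericalROI((4, 4, 4), 6.0, exclusion="none")
        for plane in PLANES:
            assert plane_mean_uptake(vol, roi, plane) == 3.5

    def test_sagittal_plane_of_x_gradient_returns_center_coordinate(self):
        n = 11
        x = np.arange(n, dtype=float)
        counts = np.broadcast_to(x[:, None, None], (n, n, n)).copy()
        vol = VoxelVolume(counts, (1.0, 1.0, 1.0))
        roi = SphericalROI((6.0, 5.0, 5.0), 6.0, exclusion="none")
        assert plane_mean_uptake(vol, roi, "sagittal") == 6.0

    def test_random_fixture_matches_brute_force(self, rng):
        counts = rng.uniform(0, 50, size=(9, 9, 9))
        vol = VoxelVolume(counts, (1.0, 1.0, 1.0))
        roi = SphericalROI((4.0, 4.0, 4.0), 6.0, exclusion="none")
        for plane in PLANES:
            expected, _ = brute_force_plane_mean(
                counts, None, vol.spacing, roi.center, roi.radius, plane, False
            )
            assert plane_mean_uptake(vol, roi, plane) == expected

    @given(
        cx=st.floats(4, 20), cy=st.floats(4, 20), cz=st.floats(4, 20),
        diameter=st.floats(2.0, 20.0),
        seed=st.integers(0, 2**16),
    )
    def test_oracle_equivalence_property(self, cx, cy, cz, diameter, seed):
        """On any small fixture, plane means equal per-voxel enumeration exactly."""
        r = np.random.default_rng(seed)
        counts = r.uniform(0, 10, size=(13, 13, 13))
        labels = r.integers(0, 4, size=(13, 13, 13)).astype(np.int16)
        spacing = (1.9, 1.9, 1.9)
        vol = VoxelVolume(counts, spacing)
        struct = StructureVolume(labels, spacing)
        roi = SphericalROI((cx, cy, cz), diameter)
        for plane in PLANES:
            try:
                expected, n = brute_force_plane_mean(
                    counts, labels, spacing, roi.center, roi.radius, plane, True
                )
            except ValueError:
                with pytest.raises(MeasurementError):
                    plane_mean_uptake(vol, roi, plane, struct)
                continue
            assert plane_mean_uptake(vol, roi, plane, struct) == expected

    def test_zero_eligible_voxels_is_measurement_error(self):
        vol = _uniform_volume()
        struct = StructureVolume(np.full((9, 9, 9), CORTICAL, np.int16), (1.0,) * 3)
        roi = SphericalROI((4, 4, 4), 4.0, exclusion="exclude_cortical")
        with pytest.raises(MeasurementError):
            plane_mean_uptake(vol, roi, "axial", struct)

    def test_exclusion_requires_structure(self):
        vol = _uniform_volume()
        roi = SphericalROI((4, 4, 4), 4.0, exclusion="exclude_cortical")
        with pytest.raises(ParameterError):
            plane_mean_uptake(vol, roi, "axial")


class TestRoiMeasurement:
    def test_combined_mean_is_average_of_plane_means(self, rng):
        counts = rng.uniform(0, 20, size=(15, 15, 15))
        vol = VoxelVolume(counts, (1.0,) * 3)
        roi = SphericalROI((7, 7, 7), 9.0, exclusion="none")
        m = roi_mean_uptake(vol, roi)
        assert m.combined_mean == pytest.approx(np.mean(m.plane_means), abs=1e-12)
        assert m.mode == "three_plane"

    def test_constructed_plane_means_average_exactly(self):
        # slab values force plane means a, b, c along z / y / x symmetry:
        # use a volume constant in each central slice instead
        n = 9
        counts = np.zeros((n, n, n))
        counts[:, :, 4] = 3.0   # axial central slice
        counts[:, 4, :] = 6.0   # coronal central slice
        counts[4, :, :] = 9.0   # sagittal central slice
        # make slices unambiguous where they intersect
        vol = VoxelVolume(counts, (1.0,) * 3)
        roi = SphericalROI((4, 4, 4), 5.0, exclusion="none")
        m = roi_mean_uptake(vol, roi)
        assert m.combined_mean == pytest.approx(np.mean(m.plane_means))

    def test_sphere_mode_flagged_and_matches_mask_mean(self, rng):
        counts = rng.uniform(0, 20, size=(15, 15, 15))
        vol = VoxelVolume(counts, (1.0,) * 3)
        roi = SphericalROI((7, 7, 7), 9.0, exclusion="none")
        m = roi_mean_uptake(vol, roi, mode="sphere")
        assert m.mode == "sphere"
        x, y, z = np.mgrid[0:15, 0:15, 0:15]
        mask = (x - 7) ** 2 + (y - 7) ** 2 + (z - 7) ** 2 <= 4.5**2
        assert m.combined_mean == pytest.approx(counts[mask].mean(), abs=1e-12)

    def test_noiseless_phantom_roi_means_equal_rates(self, default_phantom, anatomy):
        volume, structure = default_phantom
        u = UptakeParams()
        head = make_head_roi(volume, structure, anatomy.head_center("left"))
        m = roi_mean_uptake(volume, head, structure)
        assert m.combined_mean == pytest.approx(u.cancellous_head_rate_affected, abs=1e-9)
        head_u = make_head_roi(volume, structure, anatomy.head_center("right"))
        m_u = roi_mean_uptake(volume, head_u, structure)
        assert m_u.combined_mean == pytest.approx(u.cancellous_head_rate_unaffected, abs=1e-9)
        dome = make_acetabular_roi(volume, structure, anatomy.dome_center("left"))
        m_d = roi_mean_uptake(volume, dome, structure)
        assert m_d.combined_mean == pytest.approx(u.acetabular_rate, abs=1e-9)


class TestRoiPlacement:
    def test_head_roi_samples_only_cancellous(self, default_phantom, anatomy):
        """A 30 mm ROI inside a 22 mm-radius head with a 3 mm shell stays cancellous."""
        volume, structure = default_phantom
        roi = make_head_roi(volume, structure, anatomy.head_center("left"))
        from hipspect.roi import _plane_disc

        for plane in PLANES:
            index, disc = _plane_disc(volume, roi, plane)
            assert np.all(structure.labels[index][disc] == CANCELLOUS)

    def test_corner_roi_clips_to_in_bounds_voxels(self):
        vol = _uniform_volume(2.0, n=9)
        roi = SphericalROI((0.0, 0.0, 4.0), 6.0, exclusion="none")
        m = roi_mean_uptake(vol, roi)
        full = disc_voxel_count((9, 9), (1.0, 1.0), (4.0, 4.0), 3.0)
        clipped = disc_voxel_count((9, 9), (1.0, 1.0), (0.0, 0.0), 3.0)
        assert m.combined_mean == 2.0
        assert clipped < full
        assert m.n_voxels_per_plane[1] == clipped  # axial plane centred at corner

    def test_roi_entirely_outside_is_geometry_error(self, default_phantom):
        volume, structure = default_phantom
        with pytest.raises(GeometryError):
            make_head_roi(volume, structure, (4000.0, 4000.0, 4000.0))

    @pytest.mark.parametrize("diameter_mm", [10.0, 30.0])
    def test_disc_voxel_count_matches_enumeration(self, diameter_mm, default_phantom):
        """Voxel-centre-in-disc counts at 2.95 mm spacing, via brute force."""
        volume, structure = default_phantom
        center = (140.125, 140.125, 115.0)  # off-lattice centre, no boundary ties
        roi = SphericalROI(center, diameter_mm, exclusion="none")
        m = roi_mean_uptake(volume, roi)
        expected = disc_voxel_count(
            (volume.shape[0], volume.shape[1]),
            (volume.spacing[0], volume.spacing[1]),
            (center[0], center[1]),
            diameter_mm / 2,
        )
        assert m.n_voxels_per_plane[1] == expected  # axial: x-y disc

    def test_acetabular_roi_warns_when_exceeding_cancellous_space(
        self, default_phantom, anatomy, caplog
    ):
        volume, structure = default_phantom
        with caplog.at_level("WARNING", logger="hipspect.roi"):
            make_acetabular_roi(
                volume, structure, anatomy.dome_center("left"), diameter=40.0
            )
        assert any("cancellous" in r.message for r in caplog.records)


class TestInvariances:
    def test_translation_equivariance_whole_voxel_shift(self, rng):
        pattern = rng.uniform(0, 10, size=(7, 7, 7))
        big = np.zeros((20, 20, 20))
        shift = (5, 3, 4)
        a = big.copy()
        a[2:9, 2:9, 2:9] = pattern
        b = big.copy()
        b[2 + shift[0]:9 + shift[0], 2 + shift[1]:9 + shift[1], 2 + shift[2]:9 + shift[2]] = pattern
        va, vb = VoxelVolume(a, (1.0,) * 3), VoxelVolume(b, (1.0,) * 3)
        ra = SphericalROI((5.0, 5.0, 5.0), 5.8, exclusion="none")
        rb = SphericalROI((10.0, 8.0, 9.0), 5.8, exclusion="none")
        for plane in PLANES:
            assert plane_mean_uptake(va, ra, plane) == plane_mean_uptake(vb, rb, plane)

    @given(k=st.floats(0.01, 100))
    def test_count_scaling_scales_every_mean(self, k):
        counts = np.random.default_rng(0).uniform(0, 10, size=(9, 9, 9))
        roi = SphericalROI((4, 4, 4), 6.0, exclusion="none")
        m1 = roi_mean_uptake(VoxelVolume(counts, (1.0,) * 3), roi)
        m2 = roi_mean_uptake(VoxelVolume(k * counts, (1.0,) * 3), roi)
        assert m2.combined_mean == pytest.approx(k * m1.combined_mean, rel=1e-12)

    def test_cortical_exclusion_lowers_mean_when_shell_is_hotter(self, anatomy):
        u = UptakeParams(
            cancellous_head_rate_affected=50.0,
            cancellous_head_rate_unaffected=50.0,
            cortical_rate=500.0,
        )
        volume, structure = build_hip_phantom(anatomy, u)
        center = anatomy.head_center("left")
        incl = SphericalROI(center, 48.0, exclusion="none")
        excl = SphericalROI(center, 48.0, exclusion="exclude_cortical")
        m_in = roi_mean_uptake(volume, incl, structure)
        m_ex = roi_mean_uptake(volume, excl, structure)
        assert m_ex.combined_mean <= m_in.combined_mean
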