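import math

import numpy as np
import pytest
from scipy import ndimage

from lobemap.core import VoxelGrid
from lobemap.vessels import (
    compute_vessel_maps,
    equivalent_radius,
    local_thickness_map,
    nearest_vessel_metrics,
    normalized_distance,
    surface_contact_area,
    vessel_distance_map,
)

from _oracles import brute_contact_area, brute_distance_map, brute_local_thickness
from conftest import ANISO


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(data, dtype=np.uint8), spacing, "binary")


def digital_ball(radius, spacing=(1.0, 1.0, 1.0)):
    r = radius
    n = [int(r / s) * 2 + 3 for s in spacing]
    zz, yy, xx = np.meshgrid(*[np.arange(k) * s for k, s in zip(n, spacing)], indexing="ij")
    c = [(k - 1) / 2 * s for k, s in zip(n, spacing)]
    return ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= r * r


def digital_cylinder(radius, length=None, axis=0):
    """Axis-aligned cylinder at unit spacing, cross-section radius ``radius``."""
    length = length or (2 * int(radius) + 5)
    side = 2 * int(radius) + 3
    c = (side - 1) / 2
    yy, xx = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    disk = ((yy - c) ** 2 + (xx - c) ** 2) <= radius * radius
    cyl = np.broadcast_to(disk, (length, side, side))
    return np.moveaxis(cyl, 0, axis).copy()


class TestDistanceMap:
    def test_vessel_voxels_are_zero(self, rng):
        mask = rng.random((6, 6, 6)) < 0.2
        mask[0, 0, 0] = True
        dist = vessel_distance_map(_mask(mask), return_site=False)
        assert (dist.data[mask] == 0).all()
        assert (dist.data[~mask] > 0).all()

    def test_pythagorean_distance(self):
        mask = np.zeros((1, 5, 6), dtype=bool)
        mask[0, 0, 0] = True
        dist = vessel_distance_map(_mask(mask), return_site=False)
        assert dist.data[0, 3, 4] == pytest.approx(5.0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="no vasculature"):
            vessel_distance_map(_mask(np.zeros((3, 3, 3))))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle_anisotropic(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((8, 8, 8)) < 0.08
        if not mask.any():
            mask[4, 4, 4] = True
        grid = _mask(mask, ANISO)
        dist, site = vessel_distance_map(grid)
        assert np.allclose(dist.data, brute_distance_map(mask, ANISO))
        # nearest_site must achieve the stated distance
        sp = np.asarray(ANISO)
        idx = np.indices(mask.shape)
        achieved = np.sqrt((((site - idx) * sp.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
        assert np.allclose(achieved, dist.data)
        assert mask[tuple(site[:, 2, 5, 1])]

    def test_lipschitz_per_physical_step(self, rng):
        mask = rng.random((6, 10, 10)) < 0.05
        mask[3, 5, 5] = True
        dist = vessel_distance_map(_mask(mask, ANISO), return_site=False).data
        for axis, step in enumerate(ANISO):
            d = np.abs(np.diff(dist, axis=axis))
            assert d.max() <= step + 1e-9


class TestLocalThickness:
    def test_empty_mask_all_zero(self):
        out = local_thickness_map(_mask(np.zeros((4, 4, 4))))
        assert out.data.max() == 0

    @pytest.mark.parametrize("radius", [3, 5])
    def test_ball_centre_diameter(self, radius):
        mask = digital_ball(radius)
        out = local_thickness_map(_mask(mask)).data
        centre = tuple(s // 2 for s in mask.shape)
        assert out[centre] == pytest.approx(2 * radius, abs=1.0)

    @pytest.mark.parametrize("radius,axis", [(3, 0), (4, 1), (5, 2)])
    def test_cylinder_axis_diameter(self, radius, axis):
        mask = digital_cylinder(radius, axis=axis)
        out = local_thickness_map(_mask(mask)).data
        centre = tuple(s // 2 for s in mask.shape)
        assert out[centre] == pytest.approx(2 * radius, abs=1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_inscribed_sphere_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = ndimage.binary_dilation(rng.random((7, 7, 7)) < 0.08, iterations=1)
        out = local_thickness_map(_mask(mask, ANISO)).data
        assert np.allclose(out, brute_local_thickness(mask, ANISO))

    def test_monotone_under_dilation(self, rng):
        mask = rng.random((6, 8, 8)) < 0.1
        mask[3, 4, 4] = True
        grown = ndimage.binary_dilation(mask)
        t0 = local_thickness_map(_mask(mask)).data
        t1 = local_thickness_map(_mask(grown)).data
        assert (t1 >= t0 - 1e-9).all()

    def test_bounded_by_mask_extent(self, rng):
        mask = rng.random((6, 8, 8)) < 0.3
        out = local_thickness_map(_mask(mask, ANISO)).data
        extent = math.sqrt(sum(((n - 1) * s) ** 2 for n, s in zip(mask.shape, ANISO)))
        assert out.max() <= extent + 1e-6


class TestNearestVesselMetrics:
    def test_overlapping_object_distance_zero(self):
        vessel = digital_cylinder(4, length=11, axis=0)
        maps = compute_vessel_maps(_mask(vessel))
        obj = np.zeros_like(vessel)
        obj[5, 5, 5] = True  # inside the vessel
        dist, diam = nearest_vessel_metrics(obj, maps)
        assert dist == 0.0
        assert diam == pytest.approx(maps.thickness_um.data[5, 5, 5])

    def test_phantom_distance_and_diameter(self):
        # single-voxel object 12 px from the surface of a radius-10 cylinder
        side, length = 45, 21
        c = (side - 1) / 2
        yy, xx = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        vessel = np.broadcast_to((yy - c) ** 2 + (xx - c) ** 2 <= 100, (length, side, side)).copy()
        obj = np.zeros_like(vessel)
        obj[10, int(c), int(c) + 22] = True  # 22 px from axis → 12 px from surface
        maps = compute_vessel_maps(_mask(vessel))
        dist, diam = nearest_vessel_metrics(obj, maps)
        assert dist == pytest.approx(12.0, abs=1.0)
        assert diam == pytest.approx(20.0, abs=1.5)

    def test_equidistant_tie_is_lexicographic(self):
        vessel = np.zeros((1, 1, 5), dtype=bool)
        vessel[0, 0, 0] = vessel[0, 0, 4] = True
        obj = np.zeros_like(vessel)
        obj[0, 0, 2] = True  # exactly 2 px from both vessel voxels
        maps = compute_vessel_maps(_mask(vessel))
        maps.thickness_um.data[0, 0, 0] = 7.0  # tag the lexicographically first site
        maps.thickness_um.data[0, 0, 4] = 9.0
        _, diam = nearest_vessel_metrics(obj, maps)
        assert diam == 7.0

    def test_shape_mismatch_rejected(self):
        maps = compute_vessel_maps(_mask(np.ones((2, 2, 2))))
        with pytest.raises(ValueError):
            nearest_vessel_metrics(np.ones((3, 3, 3), dtype=bool), maps)


class TestContactArea:
    def test_separated_masks_zero(self):
        obj = np.zeros((3, 3, 5), dtype=bool)
        ves = np.zeros_like(obj)
        obj[1, 1, 0] = True
        ves[1, 1, 3] = True
        assert surface_contact_area(obj, ves, (1, 1, 1)) == 0.0

    def test_single_face_pair_anisotropic(self):
        obj = np.zeros((3, 3, 3), dtype=bool)
        ves = np.zeros_like(obj)
        obj[1, 1, 0] = True
        ves[1, 1, 1] = True  # face-adjacent along x → shared face area dz·dy
        assert surface_contact_area(obj, ves, (1, 1, 1)) == pytest.approx(1.0)
        assert surface_contact_area(obj, ves, ANISO) == pytest.approx(2.9 * 1.22)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_face_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        obj = rng.random((8, 8, 8)) < 0.35
        ves = rng.random((8, 8, 8)) < 0.35
        assert surface_contact_area(obj, ves, ANISO) == pytest.approx(
            brute_contact_area(obj, ves, ANISO)
        )

    def test_symmetric_for_disjoint_masks(self, rng):
        obj = rng.random((6, 6, 6)) < 0.3
        ves = (rng.random((6, 6, 6)) < 0.3) & ~obj
        assert surface_contact_area(obj, ves, ANISO) == pytest.approx(
            surface_contact_area(ves, obj, ANISO)
        )


class TestEquivalentRadius:
    def test_unit_and_scaled_spheres(self):
        assert equivalent_radius(4 * math.pi / 3) == pytest.approx(1.0)
        assert equivalent_radius(4 * math.pi / 3 * 1000) == pytest.approx(10.0)

    def test_cube_root_homogeneity(self):
        assert equivalent_radius(2 * 500.0) == pytest.approx(
            2 ** (1 / 3) * equivalent_radius(500.0)
        )

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            equivalent_radius(0.0)


class TestNormalizedDistance:
    def test_zero_distance(self):
        assert normalized_distance(0.0, 123.0) == 0.0

    def test_worked_value(self):
        assert normalized_distance(20.0, 4 * math.pi / 3 * 1000) == pytest.approx(2.0)

    def test_scale_invariance(self):
        s = 3.0
        v, d = 700.0, 11.0
        assert normalized_distance(d * s, v * s**3) == pytest.approx(normalized_distance(d, v))
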