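"""Exact solid measures, shape conversions, and section/shadow geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from mitostereo.geometry import (
    BodyShape,
    Slab,
    contains,
    cross_section_area,
    cross_section_membership,
    profile_areas,
    report_sphere_diameter,
    shadow_area,
    shadow_membership,
    sphere_diameter_from_volume,
    spherocylinder_length_from_volume,
    surface,
    volume,
)

SPHERE25 = BodyShape("sphere", [0, 0, 0], 25)
CAPSULE = BodyShape("spherocylinder", [0, 0, 0], 25, axis=[1, 0, 0], length=150)
HALF30 = BodyShape("half_sphere", [0, 0, 0], 30, axis=[0, 0, 1])


def mc_volume(body, n, rng):
    """Independent oracle: Monte-Carlo point-in-body volume in the bounding box."""
    lo, hi = body.bounding_box
    pts = rng.uniform(lo, hi, size=(n, 3))
    box = float(np.prod(hi - lo))
    inside = contains(body, pts)
    p = inside.mean()
    se = box * np.sqrt(p * (1 - p) / n)
    return box * p, se


class TestMeasures:
    @pytest.mark.parametrize(
        "body, expected",
        [
            (BodyShape("spherocylinder", [0, 0, 0], 25, axis=[0, 0, 1], length=50), 65449.8),
            (CAPSULE, 261799.4),
            (HALF30, 56548.7),
            (SPHERE25, 65449.8),
        ],
    )
    def test_volume_closed_forms(self, body, expected):
        assert volume(body) == pytest.approx(expected, abs=0.1)

    @pytest.mark.parametrize(
        "body, expected",
        [
            (SPHERE25, 7854.0),
            (CAPSULE, 23561.9),
            (BodyShape("half_sphere", [0, 0, 0], 25, axis=[0, 0, 1]), 3927.0),
        ],
    )
    def test_surface_closed_forms(self, body, expected):
        assert surface(body) == pytest.approx(expected, abs=0.1)

    @pytest.mark.parametrize("body", [SPHERE25, CAPSULE, HALF30])
    def test_monte_carlo_volume_agrees(self, body, rng):
        v, se = mc_volume(body, 1_000_000, rng)
        assert abs(v - volume(body)) < 3 * se

    def test_degenerate_capsule_is_sphere(self):
        sc = BodyShape("spherocylinder", [1, 2, 3], 25, axis=[0, 1, 0], length=50)
        assert volume(sc) == pytest.approx(volume(SPHERE25))
        assert surface(sc) == pytest.approx(surface(SPHERE25))

    def test_invalid_bodies_rejected(self):
        with pytest.raises(ValueError):
            BodyShape("cube", [0, 0, 0], 10)
        with pytest.raises(ValueError):
            BodyShape("sphere", [0, 0, 0], -1)
        with pytest.raises(ValueError):
            BodyShape("spherocylinder", [0, 0, 0], 25, axis=[1, 0, 0], length=40)
        with pytest.raises(ValueError):
            BodyShape("spherocylinder", [0, 0, 0], 25, axis=[2, 0, 0], length=100)
        with pytest.raises(ValueError):
            BodyShape("half_sphere", [0, 0, 0], 25)


class TestShapeConversions:
    def test_smallest_mitosome_reported_diameter(self):
        # 0.0001 um^3 corresponds to a 58-nm sphere after integer rounding
        assert sphere_diameter_from_volume(1e5) == pytest.approx(57.6, abs=0.05)
        assert report_sphere_diameter(1e5) == 58

    def test_diameter_inverse_identity(self):
        assert sphere_diameter_from_volume(np.pi / 6 * 1e6) == pytest.approx(100.0)
        assert report_sphere_diameter(volume(BodyShape("sphere", [0, 0, 0], 29))) == 58

    def test_length_from_volume(self):
        assert spherocylinder_length_from_volume(634_864, 50) == pytest.approx(340.0, abs=0.1)
        # the closed form pairs 0.00025 um^3 with 144 nm, not 340 nm
        assert spherocylinder_length_from_volume(250_000, 50) == pytest.approx(144.0, abs=0.1)
        assert spherocylinder_length_from_volume(volume(SPHERE25), 50) == pytest.approx(50.0)

    def test_length_below_cap_volume_rejected(self):
        with pytest.raises(ValueError):
            spherocylinder_length_from_volume(1e4, 50)
        with pytest.raises(ValueError):
            sphere_diameter_from_volume(0.0)

    @settings(derandomize=True, max_examples=40)
    @given(r=hst.floats(5, 80), extra=hst.floats(0, 400))
    def test_length_volume_round_trip(self, r, extra):
        body = BodyShape("spherocylinder", [0, 0, 0], r, axis=[0, 0, 1], length=2 * r + extra)
        back = spherocylinder_length_from_volume(volume(body), 2 * r)
        assert back == pytest.approx(body.length, rel=1e-6)


class TestMembership:
    def test_cross_section_examples(self):
        assert cross_section_membership(SPHERE25, [[0, 0]], 0.0)[0]
        assert not cross_section_membership(SPHERE25, [[0, 0]], 25.1)[0]
        # inside the cap region of a horizontal capsule: tip at x = 75
        assert cross_section_membership(CAPSULE, [[70, 0]], 0.0)[0]
        assert not cross_section_membership(CAPSULE, [[76, 0]], 0.0)[0]

    def test_shadow_examples(self):
        slab = Slab(20, 63)
        assert shadow_membership(SPHERE25, [[0, 0]], slab)[0]
        # max in-slab radius at z=20 is sqrt(625-400)=15 < 24
        assert not shadow_membership(SPHERE25, [[0, 24]], slab)[0]
        assert not shadow_membership(SPHERE25, [[0, 0]], Slab(26, 69))[0]

    def test_shadow_contains_every_cross_section(self, rng):
        bodies = [SPHERE25, CAPSULE, HALF30,
                  BodyShape("spherocylinder", [3, -4, 6], 20,
                            axis=np.array([1.0, 1.0, 1.0]) / np.sqrt(3), length=120)]
        for body in bodies:
            lo, hi = body.bounding_box
            slab = Slab(lo[2] + 5, lo[2] + 48)
            pts = rng.uniform(lo[:2] - 5, hi[:2] + 5, size=(400, 2))
            for z in np.linspace(slab.z_lo, slab.z_hi - 1e-9, 7):
                cross = cross_section_membership(body, pts, z)
                shadow = shadow_membership(body, pts, slab)
                assert np.all(shadow[cross])


class TestAreas:
    def test_full_extent_shadow_equals_projected_area(self, rng):
        # sphere projects to pi r^2; horizontal capsule to rectangle + disc
        zlo, zhi = SPHERE25.z_extent
        assert shadow_area(SPHERE25, Slab(zlo - 1, zhi + 1)) == pytest.approx(
            np.pi * 625, rel=1e-5)
        zlo, zhi = CAPSULE.z_extent
        assert shadow_area(CAPSULE, Slab(zlo - 1, zhi + 1)) == pytest.approx(
            100 * 50 + np.pi * 625, rel=1e-5)

    def test_thin_area_closed_forms(self):
        assert cross_section_area(SPHERE25, 7.0) == pytest.approx(np.pi * (625 - 49), rel=1e-9)
        assert cross_section_area(CAPSULE, 20.0) == pytest.approx(
            2 * 15 * 100 + np.pi * 225, rel=1e-5)
        assert cross_section_area(HALF30, 10.0) == pytest.approx(np.pi * 800, rel=1e-9)
        assert cross_section_area(HALF30, -1.0) == 0.0

    def test_tilted_capsule_area_matches_grid_oracle(self, rng):
        axis = np.array([1.0, 0.5, 0.8])
        axis /= np.linalg.norm(axis)
        body = BodyShape("spherocylinder", [5, -3, 2], 25, axis=axis, length=150)
        lo, hi = body.bounding_box
        pitch = 0.5
        xs = np.arange(lo[0], hi[0], pitch)
        ys = np.arange(lo[1], hi[1], pitch)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.stack([gx.ravel(), gy.ravel()], -1)
        slab = Slab(-10, 33)
        grid_shadow = np.count_nonzero(shadow_membership(body, pts, slab)) * pitch**2
        assert shadow_area(body, slab) == pytest.approx(grid_shadow, rel=5e-3)
        grid_thin = np.count_nonzero(cross_section_membership(body, pts, 10.0)) * pitch**2
        assert cross_section_area(body, 10.0) == pytest.approx(grid_thin, rel=5e-3)

    def test_profile_areas_vectorised_consistent(self):
        z = np.array([-40.0, -10.0, 0.0, 18.0])
        batched = profile_areas(CAPSULE, z, z)
        singles = [cross_section_area(CAPSULE, zi) for zi in z]
        assert batched == pytest.approx(singles)

    def test_half_sphere_tilted_section(self):
        tilted = BodyShape("half_sphere", [0, 0, 0], 30, axis=[1, 0, 0])
        # the mid-plane through the flat face halves the disc
        assert cross_section_area(tilted, 0.0) == pytest.approx(0.5 * np.pi * 900, rel=1e-9)
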