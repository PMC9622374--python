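import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oformula.optics import (
    OpticalSystem,
    Ray,
    RayMissError,
    Surface,
    TotalInternalReflectionError,
    conic_sag,
    hexapolar_fan,
    intersect,
    paraxial_power,
    refract,
    rms_spot_radius,
    trace,
)


def axial_ray(height=0.0, z0=-10.0):
    return Ray(np.array([0.0, height, z0]), np.array([0.0, 0.0, 1.0]))


class TestConicSag:
    @pytest.mark.parametrize(
        "r,c,k,expected",
        [
            (0.0, 0.1, 0.0, 0.0),                      # apex
            (3.0, 0.1, 0.0, 10.0 - math.sqrt(91.0)),   # circle: R - sqrt(R^2 - r^2)
            (3.0, 0.1, -1.0, 0.45),                    # paraboloid: c r^2 / 2
            (1.0, 1 / 7.7, 0.0, 7.7 - math.sqrt(7.7 ** 2 - 1.0)),
        ],
    )
    def test_against_closed_forms(self, r, c, k, expected):
        assert conic_sag(r, c, k) == pytest.approx(expected, abs=1e-12)

    def test_domain_error_beyond_valid_zone(self):
        with pytest.raises(ValueError):
            conic_sag(11.0, 0.1, 0.0)  # r > R for a sphere


class TestIntersect:
    def test_axial_ray_hits_apex_with_backward_normal(self):
        s = Surface(0.0, 7.7, 1.0, 1.336)
        point, normal = intersect(axial_ray(), s)
        assert np.allclose(point, [0, 0, 0], atol=1e-12)
        assert np.allclose(normal, [0, 0, -1], atol=1e-12)

    def test_point_lies_on_conic_at_sag_height(self):
        s = Surface(0.0, 7.7, 1.0, 1.336, conic_k=-0.52 ** 2)
        point, _ = intersect(axial_ray(height=1.0), s)
        assert point[2] == pytest.approx(conic_sag(1.0, 1 / 7.7, -0.52 ** 2), abs=1e-10)
        assert point[1] == pytest.approx(1.0, abs=1e-12)

    def test_sphere_point_matches_circle_equation(self):
        s = Surface(0.0, 7.7, 1.0, 1.336)
        point, _ = intersect(axial_ray(height=1.0), s)
        assert point[2] == pytest.approx(7.7 - math.sqrt(7.7 ** 2 - 1.0), abs=1e-10)

    def test_miss_beyond_half_aperture(self):
        s = Surface(0.0, 7.7, 1.0, 1.336, half_aperture=2.0)
        with pytest.raises(RayMissError):
            intersect(axial_ray(height=2.5), s)

    def test_planar_surface(self):
        s = Surface(3.0, math.inf, 1.0, 1.5)
        point, normal = intersect(axial_ray(height=1.0), s)
        assert point[2] == pytest.approx(3.0, abs=1e-12)
        assert np.allclose(normal, [0, 0, -1])


class TestRefract:
    def test_normal_incidence_unchanged(self):
        d = np.array([0.0, 0.0, 1.0])
        out = refract(d, np.array([0.0, 0.0, -1.0]), 1.0, 1.7)
        assert np.allclose(out, d, atol=1e-14)

    def test_scalar_snell_30_degrees(self):
        th = math.radians(30)
        d = np.array([math.sin(th), 0.0, math.cos(th)])
        out = refract(d, np.array([0.0, 0.0, -1.0]), 1.0, 1.5)
        assert math.degrees(math.asin(out[0])) == pytest.approx(19.47122, abs=1e-4)

    def test_total_internal_reflection(self):
        th = math.radians(45)
        d = np.array([math.sin(th), 0.0, math.cos(th)])
        with pytest.raises(TotalInternalReflectionError):
            refract(d, np.array([0.0, 0.0, -1.0]), 1.5, 1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        theta=st.floats(0.0, 0.6),
        n1=st.floats(1.0, 1.6),
        n2=st.floats(1.0, 1.6),
        phi=st.floats(0.0, 2 * math.pi),
    )
    def test_snell_invariant_conserved(self, theta, n1, n2, phi):
        """n1 sin(theta_i) = n2 sin(theta_t) at any oblique plane interface."""
        d = np.array([math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi),
                      math.cos(theta)])
        n = np.array([0.0, 0.0, -1.0])
        sin_i = math.hypot(d[0], d[1])  # transverse magnitude: exact at tiny angles
        if (n1 / n2) ** 2 * sin_i ** 2 > 1.0:
            return
        out = refract(d, n, n1, n2)
        sin_t = math.hypot(out[0], out[1])
        assert n1 * sin_i == pytest.approx(n2 * sin_t, abs=1e-12)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)


@pytest.fixture()
def cornea_like():
    return OpticalSystem(
        [
            Surface(0.0, 7.7, 1.0, 1.376),
            Surface(0.545, 6.4, 1.376, 1.336),
        ],
        image_z=31.0,
    )


class TestTrace:
    def test_axial_ray_stays_on_axis(self, cornea_like):
        segs = trace(cornea_like, axial_ray())
        for s in segs:
            assert abs(s.origin[0]) < 1e-15 and abs(s.origin[1]) < 1e-15

    def test_single_surface_focus_matches_paraxial(self):
        # paraxial focus of one refracting sphere: z = n2 R / (n2 - n1)
        s = Surface(0.0, 7.7, 1.0, 1.336)
        sys_ = OpticalSystem([s], image_z=40.0)
        segs = trace(sys_, axial_ray(height=0.1))
        out = segs[-2]
        z_cross = out.origin[2] - out.origin[1] / out.direction[1] * out.direction[2]
        assert z_cross == pytest.approx(1.336 * 7.7 / 0.336, rel=1e-3)

    def test_two_surface_crossing_agrees_with_gaussian_oracle(self, cornea_like):
        sol = paraxial_power(cornea_like)
        segs = trace(cornea_like, axial_ray(height=0.05))
        out = segs[-2]
        z_cross = out.origin[2] - out.origin[1] / out.direction[1] * out.direction[2]
        bf_z = cornea_like.surfaces[-1].apex_z + sol.back_focal_distance
        assert z_cross == pytest.approx(bf_z, rel=1e-3)

    def test_meridional_ray_stays_in_plane(self, cornea_like):
        r = Ray(np.array([0.0, 1.5, -10.0]), np.array([0.0, 0.05, 1.0]))
        for seg in trace(cornea_like, r):
            assert abs(seg.origin[0]) < 1e-12
            assert abs(seg.direction[0]) < 1e-12

    def test_path_reversibility(self, cornea_like):
        """Retracing the mirrored terminal ray reproduces the forward path."""
        segs = trace(cornea_like, Ray(np.array([0.3, 1.2, -10.0]),
                                      np.array([0.01, -0.02, 1.0])))
        fwd_points = [s.origin for s in segs[1:-1]]  # surface hits
        term = segs[-1]
        back = Ray(np.array([term.origin[0], term.origin[1], -term.origin[2]]),
                   np.array([-term.direction[0], -term.direction[1], term.direction[2]]))
        msys = cornea_like.mirrored()
        bsegs = trace(msys, back)
        back_points = [s.origin for s in bsegs[1:-1]][::-1]
        for fp, bp in zip(fwd_points, back_points):
            assert np.allclose([fp[0], fp[1], fp[2]], [bp[0], bp[1], -bp[2]], atol=1e-9)

    def test_trace_propagates_miss_with_surface_index(self, cornea_like):
        with pytest.raises(RayMissError) as err:
            trace(cornea_like, axial_ray(height=6.5))
        assert err.value.surface_index == 0


class TestParaxialPower:
    def test_single_surface_power(self):
        sys_ = OpticalSystem([Surface(0.0, 7.7, 1.0, 1.336)], image_z=30.0)
        assert paraxial_power(sys_).power_d == pytest.approx(1000 * 0.336 / 7.7, abs=1e-9)

    def test_thin_lens_limit_is_sum_of_surface_powers(self):
        n = 1.52
        p1 = 1000 * (n - 1) / 50.0
        p2 = 1000 * (1 - n) / -50.0
        sys_ = OpticalSystem(
            [Surface(0.0, 50.0, 1.0, n), Surface(1e-7, -50.0, n, 1.0)], image_z=100.0
        )
        assert paraxial_power(sys_).power_d == pytest.approx(p1 + p2, abs=1e-6)

    def test_mean_cornea_thick_lens_hand_value(self):
        # P1 + P2 - (t/n) P1 P2 with r_a=7.7, r_p=6.4, cct=0.545
        p1 = 1000 * 0.376 / 7.7
        p2 = -1000 * 0.040 / 6.4
        expected = p1 + p2 - (0.545 / 1000 / 1.376) * p1 * p2
        sys_ = OpticalSystem(
            [Surface(0.0, 7.7, 1.0, 1.376), Surface(0.545, 6.4, 1.376, 1.336)], image_z=31.0
        )
        sol = paraxial_power(sys_)
        assert sol.power_d == pytest.approx(expected, abs=1e-9)
        assert sol.power_d == pytest.approx(42.70, abs=0.05)


class TestSpotMetric:
    def test_hexapolar_fan_size_and_extent(self):
        fan = hexapolar_fan(3.0, 6)
        assert len(fan) == 127
        assert np.max(np.hypot(fan[:, 0], fan[:, 1])) == pytest.approx(1.5, abs=1e-12)

    def test_tiny_pupil_at_paraxial_focus_is_sharp(self):
        s = Surface(0.0, 7.7, 1.0, 1.336)
        sol = paraxial_power(OpticalSystem([s], image_z=1.0))
        sys_ = OpticalSystem([s], image_z=sol.back_focal_distance)
        assert rms_spot_radius(sys_, 0.1, 6) < 1e-4

    def test_defocus_grows_spot(self):
        s = Surface(0.0, 7.7, 1.0, 1.336)
        sol = paraxial_power(OpticalSystem([s], image_z=1.0))
        at_focus = rms_spot_radius(OpticalSystem([s], image_z=sol.back_focal_distance), 3.0, 6)
        defocused = rms_spot_radius(
            OpticalSystem([s], image_z=sol.back_focal_distance + 1.0), 3.0, 6
        )
        assert defocused > at_focus

    def test_blur_scales_linearly_with_pupil_at_fixed_defocus(self):
        # similar triangles; small pupils keep spherical aberration negligible
        s = Surface(0.0, 7.7, 1.0, 1.336)
        sol = paraxial_power(OpticalSystem([s], image_z=1.0))
        sys_ = OpticalSystem([s], image_z=sol.back_focal_distance + 1.0)
        r1 = rms_spot_radius(sys_, 0.2, 6)
        r2 = rms_spot_radius(sys_, 0.4, 6)
        assert r2 / r1 == pytest.approx(2.0, rel=0.05)

    def test_requires_three_rings(self):
        s = Surface(0.0, 7.7, 1.0, 1.336)
        with pytest.raises(ValueError):
            rms_spot_radius(OpticalSystem([s], image_z=30.0), 3.0, n_rings=2)


class TestValidation:
    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            Surface(0.0, 0.0, 1.0, 1.336)

    def test_media_chain_mismatch_rejected(self):
        with pytest.raises(ValueError):
            OpticalSystem(
                [Surface(0.0, 7.7, 1.0, 1.376), Surface(1.0, 6.4, 1.3, 1.336)], image_z=30.0
            )

    def test_backward_direction_rejected(self):
        with pytest.raises(ValueError):
            Ray(np.zeros(3), np.array([0.0, 0.0, -1.0]))
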