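"""Geometric kernels: conic sag, normals, intersections, refraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from cwchord import (
    ConicSurface,
    EyeBiometry,
    EyeModel,
    IncidentAngle,
    Ray,
    conic_sag,
    flip_to_left_eye,
    intersect_ray_surface,
    make_incident_ray,
    refract,
    surface_normal,
    trace_to_pupil_plane,
)
from cwchord.optics import N_AIR, N_CORNEA, RayMissError

FRONT = ConicSurface(7.76, -0.22, 0.0, 1.0, 1.376)
SPHERE = ConicSurface(7.76, 0.0, 0.0, 1.0, 1.376)


def implicit_sag(R, Q, r):
    """Independent oracle: numeric root of the implicit conic equation."""
    f = lambda z: r * r - 2 * R * z + (1 + Q) * z * z
    return brentq(f, 0.0, R / (1 + Q) if Q > -1 else 2 * R, xtol=1e-14)


class TestConicSag:
    def test_apex_is_zero(self):
        assert conic_sag(FRONT, 0.0) == 0.0

    def test_sphere_closed_form(self):
        # 7.76 - sqrt(7.76^2 - 2^2)
        assert conic_sag(SPHERE, 2.0) == pytest.approx(0.2621606, abs=1e-6)

    @given(
        R=st.floats(5.0, 10.0),
        Q=st.floats(-0.9, 0.5),
        r=st.floats(0.01, 3.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_implicit_equation_root(self, R, Q, r):
        surface = ConicSurface(R, Q, 0.0, 1.0, 1.376)
        assert conic_sag(surface, r) == pytest.approx(implicit_sag(R, Q, r), abs=1e-10)

    def test_domain_error_names_radius(self):
        surface = ConicSurface(5.0, 1.0, 0.0, 1.0, 1.376)
        with pytest.raises(ValueError, match="r="):
            conic_sag(surface, 4.0)


class TestSurfaceNormal:
    def test_apex_normal_is_minus_z(self):
        n = surface_normal(FRONT, [0.0, 0.0, 0.0])
        assert np.allclose(n, [0, 0, -1])

    def test_sphere_normal_points_at_centre(self):
        z = conic_sag(SPHERE, 2.0)
        p = np.array([2.0, 0.0, z])
        n = surface_normal(SPHERE, p)
        expected = p - np.array([0, 0, 7.76])
        expected /= np.linalg.norm(expected)
        assert np.allclose(n, expected, atol=1e-12)

    def test_continuity(self):
        p1 = np.array([1.5, 0.3, conic_sag(FRONT, np.hypot(1.5, 0.3))])
        p2 = np.array([1.5001, 0.3, conic_sag(FRONT, np.hypot(1.5001, 0.3))])
        assert np.dot(surface_normal(FRONT, p1), surface_normal(FRONT, p2)) > 0.9999

    def test_off_surface_point_rejected(self):
        with pytest.raises(ValueError, match="surface"):
            surface_normal(FRONT, [2.0, 0.0, 1.0])


class TestIntersect:
    def test_axial_ray_hits_apex(self):
        ray = Ray(np.array([0.0, 0.0, -10.0]), np.array([0.0, 0.0, 1.0]))
        assert np.allclose(intersect_ray_surface(ray, FRONT), [0, 0, 0], atol=1e-12)

    def test_parallel_offset_ray_sphere_sag(self):
        ray = Ray(np.array([2.0, 0.0, -10.0]), np.array([0.0, 0.0, 1.0]))
        p = intersect_ray_surface(ray, SPHERE)
        assert p[2] == pytest.approx(0.2621606, abs=1e-6)

    def test_point_satisfies_surface_equation(self):
        d = np.array([0.15, -0.1, 1.0])
        d /= np.linalg.norm(d)
        ray = Ray(np.array([0.5, 0.4, -8.0]), d)
        p = intersect_ray_surface(ray, FRONT)
        assert p[2] == pytest.approx(conic_sag(FRONT, np.hypot(p[0], p[1])), abs=1e-10)

    def test_oblique_ray_against_marching_oracle(self):
        d = np.array([0.2, 0.1, 1.0])
        d /= np.linalg.norm(d)
        ray = Ray(np.array([-1.0, 0.5, -6.0]), d)
        p = intersect_ray_surface(ray, FRONT)

        def off_surface(t):
            q = ray.origin + t * ray.direction
            return q[2] - conic_sag(FRONT, np.hypot(q[0], q[1]))

        # march until the ray crosses the surface, then bisect
        t = 0.0
        while off_surface(t) < 0:
            t += 0.01
        t_star = brentq(off_surface, t - 0.01, t, xtol=1e-12)
        assert np.allclose(p, ray.origin + t_star * ray.direction, atol=1e-8)

    def test_miss_raises(self):
        ray = Ray(np.array([20.0, 0.0, -10.0]), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(RayMissError):
            intersect_ray_surface(ray, FRONT)


class TestRefract:
    def test_normal_incidence_unchanged(self):
        d = np.array([0.0, 0.0, 1.0])
        assert np.allclose(refract(d, -d, 1.0, 1.376), d, atol=1e-14)

    def test_equal_indices_unchanged(self):
        d = np.array([0.3, 0.1, 1.0])
        d /= np.linalg.norm(d)
        n = np.array([0.1, -0.2, -1.0])
        n /= np.linalg.norm(n)
        assert np.allclose(refract(d, n, 1.336, 1.336), d, atol=1e-13)

    def test_scalar_snell_30_degrees(self):
        d = np.array([np.sin(np.radians(30)), 0.0, np.cos(np.radians(30))])
        out = refract(d, np.array([0.0, 0.0, -1.0]), 1.0, 1.376)
        theta2 = np.degrees(np.arcsin(out[0]))
        assert theta2 == pytest.approx(np.degrees(np.arcsin(0.5 / 1.376)), abs=1e-9)

    @given(
        dx=st.floats(-0.5, 0.5), dy=st.floats(-0.5, 0.5),
        nx=st.floats(-0.3, 0.3), ny=st.floats(-0.3, 0.3),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_snell_invariant_and_coplanarity(self, dx, dy, nx, ny):
        d = np.array([dx, dy, 1.0]); d /= np.linalg.norm(d)
        n = np.array([nx, ny, -1.0]); n /= np.linalg.norm(n)
        out = refract(d, n, N_AIR, N_CORNEA)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)
        sin_in = np.linalg.norm(np.cross(d, n))
        sin_out = np.linalg.norm(np.cross(out, n))
        assert N_AIR * sin_in == pytest.approx(N_CORNEA * sin_out, abs=1e-10)
        # refracted ray lies in the plane of incidence
        assert abs(np.dot(out, np.cross(d, n))) < 1e-10


class TestIncidentRay:
    def test_zero_angle_axial_through_apex(self):
        ray = make_incident_ray(IncidentAngle(0, 0), (0.0, 0.0))
        assert np.allclose(ray.direction, [0, 0, 1])
        assert np.allclose(ray.point_at_z(0.0), [0, 0, 0], atol=1e-12)

    def test_nasal_beam_has_temporal_direction_component(self):
        d = IncidentAngle(-5.0, 0.0).direction()
        assert d[0] == pytest.approx(np.sin(np.radians(5.0)), abs=1e-12)

    def test_rotation_inverse_recovers_axis(self):
        angle = IncidentAngle(-6.2, 2.4)
        back = angle.rotation().inv().apply(angle.direction())
        assert np.allclose(back, [0, 0, 1], atol=1e-12)

    def test_apex_plane_crossing_matches_offset(self):
        ray = make_incident_ray(IncidentAngle(-5.0, 2.0), (0.7, -0.4))
        assert np.allclose(ray.point_at_z(0.0), [0.7, -0.4, 0.0], atol=1e-12)


class TestTraceToPupil:
    def test_axial_centred_hits_stop_centre(self, centred_model):
        ray = make_incident_ray(IncidentAngle(0, 0), (0.0, 0.0))
        _, p = trace_to_pupil_plane(ray, centred_model)
        assert np.allclose(p, [0, 0, centred_model.pupil_z], atol=1e-12)

    def test_snell_holds_at_both_surfaces(self, mean_model):
        ray = make_incident_ray(IncidentAngle(-5.0, 1.0), (0.5, 0.2))
        segments, _ = trace_to_pupil_plane(ray, mean_model)
        for before, after, surface in (
            (segments[0], segments[1], mean_model.front),
            (segments[1], segments[2], mean_model.back),
        ):
            n = surface_normal(surface, after.origin)
            sin_in = np.linalg.norm(np.cross(before.direction, n))
            sin_out = np.linalg.norm(np.cross(after.direction, n))
            assert surface.n_before * sin_in == pytest.approx(
                surface.n_after * sin_out, abs=1e-10
            )

    def test_mirror_symmetry(self, mean_eye):
        mirrored = EyeBiometry(
            "left", mean_eye.Ra, mean_eye.Qa, mean_eye.Rp, mean_eye.Qp,
            mean_eye.CCT, mean_eye.ACD, mean_eye.Pup, -mean_eye.Pup_X, mean_eye.Pup_Y,
        )
        m1 = EyeModel.from_biometry(mean_eye)
        m2 = EyeModel.from_biometry(mirrored)
        ray1 = make_incident_ray(IncidentAngle(-5.0, 1.5), (0.4, 0.3))
        ray2 = make_incident_ray(IncidentAngle(5.0, 1.5), (-0.4, 0.3))
        _, p1 = trace_to_pupil_plane(ray1, m1)
        _, p2 = trace_to_pupil_plane(ray2, m2)
        assert p1[0] == pytest.approx(-p2[0], abs=1e-12)
        assert p1[1] == pytest.approx(p2[1], abs=1e-12)

    def test_paraxial_limit_matches_matrix_optics(self, mean_eye):
        """Near-axis trace agrees with an independent 2x2 ABCD computation."""
        model = EyeModel.from_biometry(mean_eye)
        p1 = (1.376 - 1.0) / mean_eye.Ra
        p2 = (1.336 - 1.376) / mean_eye.Rp
        # y_pupil = A*y0 + B*u for [y, n u] propagation apex -> stop plane
        aq = model.pupil_z - mean_eye.CCT
        a11 = (1 - aq / 1.336 * p2) * (1 - mean_eye.CCT / 1.376 * p1) - aq / 1.336 * p1
        a12 = (1 - aq / 1.336 * p2) * mean_eye.CCT / 1.376 + aq / 1.336
        for ix in (0.05, -0.1):
            u = -np.sin(np.radians(ix))
            y0 = 0.02
            ray = make_incident_ray(IncidentAngle(ix, 0.0), (y0, 0.0))
            _, p = trace_to_pupil_plane(ray, model)
            assert p[0] == pytest.approx(a11 * y0 + a12 * u, abs=1e-4)


class TestFlip:
    def test_right_eye_negates_pup_x(self, mean_eye):
        right = EyeBiometry("right", 7.8, -0.2, 6.5, -0.1, 0.55, 3.3, 3.0, 0.30, -0.05)
        left = flip_to_left_eye(right)
        assert left.laterality == "left"
        assert left.Pup_X == -0.30
        assert left.Pup_Y == -0.05

    def test_left_eye_unchanged(self, mean_eye):
        assert flip_to_left_eye(mean_eye) == mean_eye

    def test_involutive_on_pup_x(self):
        right = EyeBiometry("od", 7.8, -0.2, 6.5, -0.1, 0.55, 3.3, 3.0, 0.30, -0.05)
        once = flip_to_left_eye(right)
        assert flip_to_left_eye(once).Pup_X == once.Pup_X

    def test_unknown_laterality_rejected(self):
        with pytest.raises(ValueError, match="laterality"):
            EyeBiometry("both", 7.8, -0.2, 6.5, -0.1, 0.55, 3.3, 3.0, 0.3, 0.0)


class TestValidation:
    def test_acd_not_exceeding_cct_rejected(self):
        with pytest.raises(ValueError, match="ACD"):
            EyeBiometry("left", 7.8, -0.2, 6.5, -0.1, 0.55, 0.4, 3.0, 0.0, 0.0)

    def test_nonpositive_pupil_rejected(self):
        with pytest.raises(ValueError, match="pupil"):
            EyeBiometry("left", 7.8, -0.2, 6.5, -0.1, 0.55, 3.3, 0.0, 0.0, 0.0)
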