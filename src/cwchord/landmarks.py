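"""Pupil-centre and Purkinje-reflex landmarks and the Chang-Waring chord.

Two chief rays define the chord for a given eye and incident beam angle:

* the **pupil-centre ray** — the incident-direction ray whose refracted
  continuation passes exactly through the centre of the aperture stop.
  Its landmark coordinate is read where the refracted (aqueous) segment
  crosses the entrance-pupil plane, i.e. at the depth where an anterior
  segment instrument focused on the pupil localises the pupil centre.
* the **Purkinje ray** — the incident-direction ray that meets the
  corneal front surface perpendicularly (is collinear with the surface
  normal and hence not refracted): the location of the first Purkinje
  reflex of a coaxial light source.  Its landmark is the incident line's
  apex-plane crossing.

Both landmarks are then rotated about the apex onto the plane
perpendicular to the incident beam — the frame in which a coaxially
aligned instrument reports them — and the Chang-Waring chord is their
difference, ``CW = PupR - PurkinjeR``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .optics import (
    EyeModel,
    IncidentAngle,
    N_AIR,
    N_CORNEA,
    intersect_ray_surface,
    make_incident_ray,
    refract,
    surface_normal,
    trace_to_pupil_plane,
)
from .paraxial import entrance_pupil_depth

__all__ = [
    "ConvergenceError",
    "LandmarkResult",
    "find_pupil_centre_ray",
    "find_purkinje_ray",
    "project_to_ray_plane",
    "compute_cw_chord",
]

_MAX_ITER = 200


class ConvergenceError(RuntimeError):
    """A landmark solver failed to reach its residual tolerance."""


@dataclass(frozen=True)
class LandmarkResult:
    """Apex-plane and ray-perpendicular-plane landmark coordinates (mm).

    ``CW_X = PupR_X - PurkinjeR_X`` and ``CW_Y = PupR_Y - PurkinjeR_Y``
    hold exactly by construction.
    """

    PupC_X: float
    PupC_Y: float
    PurkinjeC_X: float
    PurkinjeC_Y: float
    PupR_X: float
    PupR_Y: float
    PurkinjeR_X: float
    PurkinjeR_Y: float
    CW_X: float
    CW_Y: float
    pupil_iterations: int
    purkinje_iterations: int
    pupil_residual_mm: float
    purkinje_residual: float


def _solve_pupil_offset(model: EyeModel, angle: IncidentAngle, tol: float):
    """Lateral offset (apex-plane crossing) of the pupil-centre chief ray."""
    target = model.stop_centre[:2]

    def residual(v):
        _, p = trace_to_pupil_plane(make_incident_ray(angle, v), model)
        return p[:2] - target

    sol = root(residual, np.zeros(2), method="hybr", options={"maxfev": _MAX_ITER * 3})
    resid = float(np.linalg.norm(sol.fun))
    if resid > tol:
        raise ConvergenceError(
            f"pupil-centre ray solver residual {resid:.3e} mm exceeds tol {tol:.1e}"
        )
    return sol.x, sol.nfev, resid


def find_pupil_centre_ray(
    model: EyeModel, angle: IncidentAngle, tol: float = 1e-9
) -> tuple[float, float]:
    """Locate the pupil-centre landmark ``(PupC_X, PupC_Y)``.

    The incident-direction ray through the centre of the aperture stop is
    found by a 2-D root solve on its lateral offset (started from the
    apex); the landmark is the refracted chief ray's lateral position at
    the entrance-pupil depth.  ``tol`` bounds the residual miss distance
    at the pupil plane, in mm.
    """
    offset, _, _ = _solve_pupil_offset(model, angle, tol)
    segments, _ = trace_to_pupil_plane(make_incident_ray(angle, offset), model)
    p = segments[2].point_at_z(entrance_pupil_depth(model))
    return float(p[0]), float(p[1])


def _purkinje_residual(model: EyeModel, angle: IncidentAngle, v):
    ray = make_incident_ray(angle, v)
    p = intersect_ray_surface(ray, model.front)
    n = surface_normal(model.front, p)
    d_refr = refract(ray.direction, n, N_AIR, N_CORNEA)
    return d_refr - ray.direction


def find_purkinje_ray(
    model: EyeModel, angle: IncidentAngle, tol: float = 1e-12
) -> tuple[float, float]:
    """Locate the Purkinje-reflex landmark ``(PurkinjeC_X, PurkinjeC_Y)``.

    Solves for the incident-direction ray that hits the corneal front
    surface perpendicularly, i.e. whose refracted direction equals the
    incident direction (dot product 1).  ``tol`` bounds ``1 - dot`` at the
    solution.  Coordinates are the incident line's apex-plane crossing.
    """
    def residual(v):
        return _purkinje_residual(model, angle, v)[:2]

    sol = root(residual, np.zeros(2), method="hybr", options={"maxfev": _MAX_ITER * 3})
    # 1 - cos(theta) = |delta d|^2 / 2 for unit vectors
    one_minus_dot = 0.5 * float(
        np.sum(np.square(_purkinje_residual(model, angle, sol.x)))
    )
    if one_minus_dot > tol:
        raise ConvergenceError(
            f"Purkinje solver 1-dot residual {one_minus_dot:.3e} exceeds {tol:.1e}"
        )
    return float(sol.x[0]), float(sol.x[1])


def project_to_ray_plane(point, angle: IncidentAngle) -> tuple[float, float]:
    """Coordinates of ``point`` on the plane perpendicular to the beam.

    Applies the inverse of the incident-direction rotation about the
    corneal apex (quaternion composition of the two axis rotations) and
    returns the rotated X, Y — what a coaxially aligned instrument reads.
    """
    p = angle.rotation().inv().apply(np.asarray(point, dtype=float))
    return float(p[0]), float(p[1])


def compute_cw_chord(
    model: EyeModel,
    angle: IncidentAngle,
    pupil_tol: float = 1e-9,
    purkinje_tol: float = 1e-12,
) -> LandmarkResult:
    """Run both landmark solvers and form the Chang-Waring chord.

    Both apex-plane landmarks are rotated to the ray-perpendicular plane
    and subtracted: ``CW = PupR - PurkinjeR``.
    """
    offset, pup_it, pup_res = _solve_pupil_offset(model, angle, pupil_tol)
    segments, _ = trace_to_pupil_plane(make_incident_ray(angle, offset), model)
    pup_c = segments[2].point_at_z(entrance_pupil_depth(model))[:2]

    def purk_resid(v):
        return _purkinje_residual(model, angle, v)[:2]

    sol = root(purk_resid, np.zeros(2), method="hybr", options={"maxfev": _MAX_ITER * 3})
    purk_res = 0.5 * float(np.sum(np.square(_purkinje_residual(model, angle, sol.x))))
    if purk_res > purkinje_tol:
        raise ConvergenceError(
            f"Purkinje solver 1-dot residual {purk_res:.3e} exceeds {purkinje_tol:.1e}"
        )
    purk_c = sol.x

    pup_r = project_to_ray_plane([pup_c[0], pup_c[1], 0.0], angle)
    purk_r = project_to_ray_plane([purk_c[0], purk_c[1], 0.0], angle)
    return LandmarkResult(
        PupC_X=float(pup_c[0]),
        PupC_Y=float(pup_c[1]),
        PurkinjeC_X=float(purk_c[0]),
        PurkinjeC_Y=float(purk_c[1]),
        PupR_X=pup_r[0],
        PupR_Y=pup_r[1],
        PurkinjeR_X=purk_r[0],
        PurkinjeR_Y=purk_r[1],
        CW_X=pup_r[0] - purk_r[0],
        CW_Y=pup_r[1] - purk_r[1],
        pupil_iterations=pup_it,
        purkinje_iterations=sol.nfev,
        pupil_residual_mm=pup_res,
        purkinje_residual=purk_res,
    )
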