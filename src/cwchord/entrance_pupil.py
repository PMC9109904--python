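"""Entrance-pupil footprint raytracing and constraining-ellipse fit.

A collimated bundle of equidistant rays is traced along the incident
direction through both corneal surfaces; rays passing the aperture stop
are marked, and their incident-segment crossings of the apex plane form
the footprint of the entrance pupil as seen from object space.  The
moment-based "constraining" ellipse of that footprint yields the
entrance-pupil centre, diameters, orientation and distortion; comparing
its long diameter with the anatomical pupil diameter gives the
entrance-pupil magnification (typically 12-15% for human corneas).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import (
    EyeModel,
    IncidentAngle,
    N_AIR,
    N_AQUEOUS,
    N_CORNEA,
    intersect_ray_surface,
    refract,
    surface_normal,
    RAY_START_Z,
)

__all__ = [
    "EllipseResult",
    "hexagonal_disc_grid",
    "trace_pupil_bundle",
    "fit_constraining_ellipse",
    "entrance_pupil_metrics",
]


@dataclass(frozen=True)
class EllipseResult:
    """Constraining ellipse of the entrance-pupil footprint (mm / degrees).

    ``EllipseC_*`` is the centre in the apex plane; ``EllipseR_*``,
    ``D_long``, ``D_short`` and the orientations describe the fit on the
    ray-perpendicular plane (the instrument view).  ``aspect`` is
    ``D_long / D_short`` and ``magnification`` is ``D_long / Pup - 1``.
    """

    EllipseC_X: float
    EllipseC_Y: float
    EllipseR_X: float
    EllipseR_Y: float
    D_long: float
    D_short: float
    A_long: float
    A_short: float
    aspect: float
    n_marked: int
    magnification: float | None = None


def hexagonal_disc_grid(n_points: int, diameter: float) -> np.ndarray:
    """Deterministic, approximately ``n_points`` hexagonal grid on a disc.

    Hexagonal packing gives uniform areal density (each sample owns a cell
    of area ``pitch**2 * sqrt(3)/2``), which is what makes the
    uniform-disc moment calibration of the ellipse fit exact up to grid
    resolution.
    """
    if n_points < 7:
        raise ValueError("need at least 7 grid points")
    radius = diameter / 2.0
    pitch = np.sqrt(np.pi * radius * radius / (n_points * np.sqrt(3.0) / 2.0))
    row_spacing = pitch * (np.sqrt(3.0) / 2.0)
    m_i = int(np.ceil(radius / pitch)) + 1
    m_j = int(np.ceil(radius / row_spacing)) + 1
    i = np.arange(-m_i, m_i + 1)
    j = np.arange(-m_j, m_j + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    x = (ii + 0.5 * (np.abs(jj) % 2)) * pitch
    y = jj * pitch * (np.sqrt(3.0) / 2.0)
    pts = np.column_stack([x.ravel(), y.ravel()])
    return pts[np.sum(pts * pts, axis=1) <= radius * radius]


def trace_pupil_bundle(
    model: EyeModel,
    angle: IncidentAngle,
    n_rays: int = 10_000,
    bundle_diameter: float = 7.0,
) -> np.ndarray:
    """Apex-plane footprint points of the rays transmitted by the stop.

    The bundle is an equidistant hexagonal grid over a disc of
    ``bundle_diameter`` in the plane perpendicular to the incident
    direction, collimated along it.  A ray is marked when its traced
    intersection with the pupillary plane lies within ``Pup/2`` of the
    stop centre; the returned ``(n_marked, 2)`` array holds the marked
    rays' incident-segment crossings of the apex plane ``z = 0``.

    Raises
    ------
    ValueError
        If the bundle does not cover the stop (``bundle_diameter <= Pup``)
        or no ray is transmitted (degenerate aperture).
    """
    if bundle_diameter <= model.stop_diameter:
        raise ValueError("bundle diameter must exceed the pupil diameter")
    if n_rays < 100:
        raise ValueError("n_rays must be at least 100")

    d = angle.direction()
    ex = np.cross([0.0, 1.0, 0.0], d)
    ex /= np.linalg.norm(ex)
    ey = np.cross(d, ex)
    grid = hexagonal_disc_grid(n_rays, bundle_diameter)
    origins = grid[:, :1] * ex + grid[:, 1:2] * ey + RAY_START_Z / d[2] * d

    p1 = intersect_ray_surface(origins, model.front, directions=d)
    ok = np.all(np.isfinite(p1), axis=-1)
    p1 = p1[ok]
    d1 = refract(d, surface_normal(model.front, p1), N_AIR, N_CORNEA)
    p2 = intersect_ray_surface(p1, model.back, directions=d1)
    ok2 = np.all(np.isfinite(p2), axis=-1)
    p1, d1, p2 = p1[ok2], d1[ok2], p2[ok2]
    d2 = refract(d1, surface_normal(model.back, p2), N_CORNEA, N_AQUEOUS)
    t = (model.pupil_z - p2[:, 2]) / d2[:, 2]
    at_pupil = p2 + t[:, np.newaxis] * d2
    miss = at_pupil[:, :2] - model.stop_centre[:2]
    marked = np.sum(miss * miss, axis=1) <= (model.stop_diameter / 2.0) ** 2
    if not np.any(marked):
        raise ValueError("degenerate aperture: no ray transmitted by the stop")

    origins_kept = origins[ok][ok2][marked]
    t0 = -origins_kept[:, 2] / d[2]
    feet = origins_kept + t0[:, np.newaxis] * d
    return feet[:, :2]


def _moment_fit(points: np.ndarray):
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 10:
        raise ValueError("need at least 10 footprint points")
    centre = pts.mean(axis=0)
    dev = pts - centre
    cov = dev.T @ dev / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise np.linalg.LinAlgError("degenerate (collinear) footprint")
    diameters = 4.0 * np.sqrt(evals)  # uniform-filled-disc equivalence
    angles = np.degrees(np.arctan2(evecs[1], evecs[0])) % 180.0
    # eigh sorts ascending: index 1 is the long axis
    return centre, diameters[1], diameters[0], angles[1], angles[0]


def fit_constraining_ellipse(points: np.ndarray) -> EllipseResult:
    """Moment-based constraining ellipse of a 2-D point set.

    The centre is the centroid and the principal axes are the
    eigenvectors of the second-central-moment matrix; diameters are
    ``4 * sqrt(eigenvalue)``, calibrated so a uniformly sampled disc of
    diameter ``d`` returns ``D_long = D_short = d``.
    """
    centre, d_long, d_short, a_long, a_short = _moment_fit(points)
    return EllipseResult(
        EllipseC_X=float(centre[0]),
        EllipseC_Y=float(centre[1]),
        EllipseR_X=float(centre[0]),
        EllipseR_Y=float(centre[1]),
        D_long=float(d_long),
        D_short=float(d_short),
        A_long=float(a_long),
        A_short=float(a_short),
        aspect=float(d_long / d_short),
        n_marked=int(np.asarray(points).shape[0]),
    )


def entrance_pupil_metrics(
    model: EyeModel,
    angle: IncidentAngle,
    n_rays: int = 10_000,
    bundle_diameter: float = 7.0,
) -> EllipseResult:
    """Entrance-pupil ellipse in the instrument view, plus magnification.

    Fits the constraining ellipse twice: on the apex-plane footprint (for
    the ``EllipseC`` centre) and on the footprint rotated to the
    ray-perpendicular plane (for the reported centre, diameters and
    orientations).  Magnification is ``D_long / Pup - 1``.
    """
    feet = trace_pupil_bundle(model, angle, n_rays, bundle_diameter)
    centre_c = feet.mean(axis=0)
    rot = angle.rotation().inv()
    feet3 = np.column_stack([feet, np.zeros(feet.shape[0])])
    rotated = rot.apply(feet3)[:, :2]
    centre_r, d_long, d_short, a_long, a_short = _moment_fit(rotated)
    return EllipseResult(
        EllipseC_X=float(centre_c[0]),
        EllipseC_Y=float(centre_c[1]),
        EllipseR_X=float(centre_r[0]),
        EllipseR_Y=float(centre_r[1]),
        D_long=float(d_long),
        D_short=float(d_short),
        A_long=float(a_long),
        A_short=float(a_short),
        aspect=float(d_long / d_short),
        n_marked=int(feet.shape[0]),
        magnification=float(d_long / model.stop_diameter - 1.0),
    )
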