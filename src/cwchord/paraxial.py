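"""First-order (paraxial) properties of the corneal model.

A 2x2 ray-transfer (ABCD) matrix in the reduced-angle convention
``[y, n*u]`` propagates a paraxial ray from the apex plane (air side) to
the pupillary plane.  From it follow the two quantities the chord
computation needs: the axial position of the entrance pupil (the virtual
image of the aperture stop formed by the cornea) and its lateral
magnification.  For a typical adult cornea the entrance pupil sits about
0.5 mm in front of the anatomical pupil and is magnified by ~12%.
"""

from __future__ import annotations

import numpy as np

from .optics import EyeModel

__all__ = [
    "apex_to_pupil_matrix",
    "entrance_pupil_depth",
    "entrance_pupil_magnification",
]


def apex_to_pupil_matrix(model: EyeModel) -> np.ndarray:
    """ABCD matrix from the apex plane (in air) to the pupillary plane.

    Acts on ``[y, n*u]`` column vectors, where ``y`` is ray height (mm)
    and ``n*u`` the reduced slope.
    """
    f, b = model.front, model.back
    p1 = (f.n_after - f.n_before) / f.R
    p2 = (b.n_after - b.n_before) / b.R
    cct = b.apex_z - f.apex_z
    aqueous = model.pupil_z - b.apex_z
    refract1 = np.array([[1.0, 0.0], [-p1, 1.0]])
    through_cornea = np.array([[1.0, cct / f.n_after], [0.0, 1.0]])
    refract2 = np.array([[1.0, 0.0], [-p2, 1.0]])
    through_aqueous = np.array([[1.0, aqueous / b.n_after], [0.0, 1.0]])
    return through_aqueous @ refract2 @ through_cornea @ refract1


def entrance_pupil_depth(model: EyeModel) -> float:
    """Axial position (mm behind the apex) of the entrance pupil.

    All incident rays aimed at the centre of the aperture stop pass, in
    object space, through a single pivot point on the axis: the entrance
    pupil centre.  With the apex-to-pupil matrix ``[[A, B], [C, D]]`` the
    pivot lies at ``z = B / A``.
    """
    m = apex_to_pupil_matrix(model)
    return float(m[0, 1] / m[0, 0])


def entrance_pupil_magnification(model: EyeModel) -> float:
    """Lateral magnification of the entrance pupil (``1/A``)."""
    m = apex_to_pupil_matrix(model)
    return float(1.0 / m[0, 0])
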