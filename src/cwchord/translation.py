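"""Linear translation between the Chang-Waring chord and angle alpha.

Raytracing is not available in the software of clinical instruments, so
the chord/angle relation is distilled into a pair of multivariable
linear models: a *forward* model predicting the chord components
``(CW_X, CW_Y)`` from biometry and the incident beam angle, and its
algebraic *reversal* predicting the incident angle (angle alpha) from
biometry and a measured chord.  Effect sizes are chosen by a classical
forward/backward stepwise procedure on term p-values, coefficients by
ordinary least squares, and the reversal is exact whenever each chord
component depends on a single angle component (which the stepwise
selection yields in practice: ``CW_X`` on ``I_X``, ``CW_Y`` on ``I_Y``).

Both models are stored as 2x10 coefficient matrices over a fixed
regressor basis so a prediction is a single matrix-vector product::

    [CW_XM, CW_YM]^T = F . [1, Ra, Qa, Rp, CCT, ACD, Pup_X, Pup_Y, I_X, I_Y]^T
    [I_XM,  I_YM ]^T = R . [1, Ra, Qa, Rp, CCT, ACD, Pup_X, Pup_Y, CW_X, CW_Y]^T

A reference coefficient set fitted to a large clinical cohort ships as
the versioned JSON fixture ``published_2022`` (see :func:`published_model`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .optics import EyeBiometry, IncidentAngle

__all__ = [
    "FORWARD_COLUMNS",
    "REVERSE_COLUMNS",
    "TranslationModel",
    "stepwise_select",
    "fit_translation_model",
    "invert_translation_model",
    "predict_cw",
    "predict_alpha",
    "published_model",
]

FORWARD_COLUMNS = ("1", "Ra", "Qa", "Rp", "CCT", "ACD", "Pup_X", "Pup_Y", "I_X", "I_Y")
REVERSE_COLUMNS = ("1", "Ra", "Qa", "Rp", "CCT", "ACD", "Pup_X", "Pup_Y", "CW_X", "CW_Y")

#: default stepwise candidate pool: the matrix basis plus the two
#: parameters that never survive selection but are always screened.
CANDIDATES = ("Ra", "Qa", "Rp", "Qp", "CCT", "ACD", "Pup_X", "Pup_Y", "Pup", "I_X", "I_Y")

_RESPONSES = ("CW_X", "CW_Y")
_ANGLES = ("I_X", "I_Y")


@dataclass(frozen=True)
class TranslationModel:
    """Forward (chord) and reverse (angle) 2x10 coefficient matrices.

    Row 0 of ``forward`` predicts ``CW_X``, row 1 predicts ``CW_Y``;
    rows of ``reverse`` predict ``I_X`` and ``I_Y``.  ``masks`` flags the
    forward terms retained by effect-size selection; masked-out
    coefficients are exactly zero.
    """

    forward: np.ndarray
    reverse: np.ndarray
    masks: np.ndarray
    diagnostics: dict | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.forward, dtype=float)
        r = np.asarray(self.reverse, dtype=float)
        m = np.asarray(self.masks, dtype=bool)
        for name, arr in (("forward", f), ("reverse", r), ("masks", m)):
            if arr.shape != (2, 10):
                raise ValueError(f"{name} matrix must be 2x10, got {arr.shape}")
        if np.any(f[~m] != 0):
            raise ValueError("masked-out forward coefficients must be exactly 0")
        object.__setattr__(self, "forward", f)
        object.__setattr__(self, "reverse", r)
        object.__setattr__(self, "masks", m)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "regressors": list(FORWARD_COLUMNS),
            "reverse_regressors": list(REVERSE_COLUMNS),
            "forward": self.forward.tolist(),
            "reverse": self.reverse.tolist(),
            "masks": self.masks.astype(int).tolist(),
            "provenance": self.provenance,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, payload: dict) -> "TranslationModel":
        return cls(
            forward=np.asarray(payload["forward"], dtype=float),
            reverse=np.asarray(payload["reverse"], dtype=float),
            masks=np.asarray(payload["masks"], dtype=bool),
            provenance=payload.get("provenance", {}),
        )

    @classmethod
    def load(cls, path) -> "TranslationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _design_matrix(table: pd.DataFrame, columns) -> np.ndarray:
    cols = [np.ones(len(table))]
    for name in columns[1:]:
        cols.append(np.asarray(table[name], dtype=float))
    return np.column_stack(cols)


def _ols(y: np.ndarray, x: np.ndarray):
    return sm.OLS(y, x).fit()


def stepwise_select(
    y,
    X: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.05,
    max_iter: int = 100,
    rmse_tol: float = 1e-12,
    step_tol: float = 1e-9,
) -> list[str]:
    """Forward/backward stepwise regressor selection by term p-values.

    Starts from the constant-only model; at each iteration first removes
    the worst selected term with p >= ``p_remove``, otherwise adds the
    candidate with the smallest p-value below ``p_enter``.  Stops when no
    change occurs, after ``max_iter`` iterations, when the RMS prediction
    error improves by less than ``rmse_tol`` or the coefficient vector
    moves by less than ``step_tol``.

    Returns the selected column names of ``X`` in entry order.

    Raises
    ------
    ValueError
        On rank deficiency of the selected design (names the columns).
    """
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more observations than candidate regressors")
    selected: list[str] = []
    prev_rmse = np.sqrt(np.mean((y - y.mean()) ** 2))
    prev_coefs = np.array([y.mean()])

    def fit_on(names):
        x = np.column_stack([np.ones(len(y))] + [np.asarray(X[n], float) for n in names])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(f"rank-deficient design; collinear columns among {names}")
        return _ols(y, x)

    for _ in range(max_iter):
        changed = False
        if selected:
            res = fit_on(selected)
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] >= p_remove:
                selected.pop(worst)
                changed = True
        if not changed:
            best_name, best_p = None, p_enter
            for name in X.columns:
                if name in selected:
                    continue
                res = _ols(
                    y,
                    np.column_stack(
                        [np.ones(len(y))]
                        + [np.asarray(X[n], float) for n in selected + [name]]
                    ),
                )
                p = res.pvalues[-1]
                if p < best_p:
                    best_name, best_p = name, p
            if best_name is not None:
                selected.append(best_name)
                changed = True
        if not changed:
            break
        res = fit_on(selected) if selected else None
        rmse = np.sqrt(np.mean(res.resid**2)) if res is not None else prev_rmse
        coefs = res.params if res is not None else prev_coefs
        step = (
            np.linalg.norm(coefs - prev_coefs)
            if coefs.shape == prev_coefs.shape
            else np.inf
        )
        if abs(prev_rmse - rmse) < rmse_tol or step < step_tol:
            break
        prev_rmse, prev_coefs = rmse, coefs
    return selected


def fit_translation_model(
    results: pd.DataFrame,
    masks: np.ndarray | None = None,
    candidates=CANDIDATES,
    p_enter: float = 0.05,
    p_remove: float = 0.05,
) -> TranslationModel:
    """Fit the forward chord model and derive its reversal.

    When ``masks`` is ``None`` the effect sizes are chosen per response by
    :func:`stepwise_select` over ``candidates`` (which may include
    parameters outside the 2x10 matrix basis, e.g. ``Qp`` and ``Pup``; a
    selected regressor without a matrix column is reported in the
    diagnostics and left out of the matrix).  Coefficients are then
    ordinary least squares with unselected terms fixed at zero.
    """
    df = results
    if "error" in df.columns:
        df = df[df["error"].fillna("").astype(str) == ""]
    forward = np.zeros((2, 10))
    mask_arr = np.zeros((2, 10), dtype=bool)
    mask_arr[:, 0] = True  # intercept always present
    diagnostics: dict = {}

    for i, response in enumerate(_RESPONSES):
        y = np.asarray(df[response], dtype=float)
        if masks is None:
            pool = [c for c in candidates if c in df.columns]
            selected = stepwise_select(y, df[pool], p_enter, p_remove)
        else:
            mask_arr[i] = np.asarray(masks[i], dtype=bool)
            mask_arr[i, 0] = True
            selected = [FORWARD_COLUMNS[j] for j in range(1, 10) if mask_arr[i, j]]
        in_basis = [c for c in selected if c in FORWARD_COLUMNS]
        outside = [c for c in selected if c not in FORWARD_COLUMNS]
        x = _design_matrix(df, ("1",) + tuple(in_basis))
        res = _ols(y, x)
        forward[i, 0] = res.params[0]
        for coef, name in zip(res.params[1:], in_basis):
            j = FORWARD_COLUMNS.index(name)
            forward[i, j] = coef
            mask_arr[i, j] = True
        diagnostics[response] = {
            "selected": in_basis,
            "selected_outside_basis": outside,
            "pvalues": dict(zip(("1",) + tuple(in_basis), res.pvalues.tolist())),
            "rmse": float(np.sqrt(np.mean(res.resid**2))),
            "r2": float(res.rsquared),
        }

    model = TranslationModel(
        forward=forward,
        reverse=np.zeros((2, 10)),
        masks=mask_arr,
        diagnostics=diagnostics,
        provenance={"n": int(len(df)), "fit": "ols+stepwise"},
    )
    reverse = invert_translation_model(model)
    return TranslationModel(
        forward=forward,
        reverse=reverse,
        masks=mask_arr,
        diagnostics=diagnostics,
        provenance=model.provenance,
    )


def invert_translation_model(model) -> np.ndarray:
    """Algebraic reversal of the forward chord model.

    Requires each chord component to depend on exactly one angle
    component (row 0 on ``I_X``, row 1 on ``I_Y``); then

    ``I_X = (CW_X - b0 - sum(biometry terms)) / coef(I_X)``

    and likewise for ``I_Y``.  Returns the 2x10 reverse matrix over
    ``(1, biometry..., CW_X, CW_Y)``.  Applying the same algebra to the
    reverse matrix recovers the forward matrix (involution).

    Raises
    ------
    ValueError
        If a row's own angle coefficient is zero or the cross-angle
        coefficient is nonzero.
    """
    f = model.forward if isinstance(model, TranslationModel) else np.asarray(model, float)
    reverse = np.zeros((2, 10))
    for i in range(2):
        own, cross = (8, 9) if i == 0 else (9, 8)
        a = f[i, own]
        if a == 0:
            raise ValueError(
                f"cannot invert: zero coefficient of {_ANGLES[i]} in row {i}"
            )
        if f[i, cross] != 0:
            raise ValueError(
                "cannot invert: each chord component must depend on exactly "
                "one angle component"
            )
        reverse[i, :8] = -f[i, :8] / a
        reverse[i, own] = 1.0 / a
    return reverse


def _row_vector(biometry, extra1: float, extra2: float) -> np.ndarray:
    if isinstance(biometry, EyeBiometry):
        b = biometry
        vals = (b.Ra, b.Qa, b.Rp, b.CCT, b.ACD, b.Pup_X, b.Pup_Y)
    else:
        vals = tuple(float(biometry[k]) for k in ("Ra", "Qa", "Rp", "CCT", "ACD", "Pup_X", "Pup_Y"))
    return np.array((1.0,) + vals + (extra1, extra2))


def predict_cw(biometry, angle, model: TranslationModel) -> tuple[float, float]:
    """Predict the chord ``(CW_XM, CW_YM)`` in mm.

    ``biometry`` may be an :class:`EyeBiometry` or any mapping with the
    biometric keys; ``angle`` an :class:`IncidentAngle` or ``(I_X, I_Y)``.
    """
    if isinstance(angle, IncidentAngle):
        ix, iy = angle.I_X, angle.I_Y
    else:
        ix, iy = float(angle[0]), float(angle[1])
    out = model.forward @ _row_vector(biometry, ix, iy)
    return float(out[0]), float(out[1])


def predict_alpha(biometry, cw, model: TranslationModel) -> tuple[float, float]:
    """Predict the incident angle ``(I_XM, I_YM)`` in degrees from a chord."""
    out = model.reverse @ _row_vector(biometry, float(cw[0]), float(cw[1]))
    return float(out[0]), float(out[1])


def published_model() -> TranslationModel:
    """The bundled ``published_2022`` reference coefficient set."""
    payload = json.loads(
        resources.files("cwchord").joinpath("data/published_2022.json").read_text()
    )
    return TranslationModel.from_dict(payload)
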