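"""Monte-Carlo machinery: angle sampling, synthetic biometry, batch runs.

No clinical anterior-segment dataset ships with this package, so the
canonical input for simulation studies is a synthetic population whose
marginal distributions emulate a large tomographer cohort: truncated
normals for each biometric parameter, a configurable correlation between
the front and back corneal radii (the two are strongly coupled in real
corneas), and independence everywhere else.  Incident beam angles follow
the Liou-Brennan fixation geometry: the horizontal angle is drawn from
Normal(-5 deg, 2 deg) restricted to [-9, -1] and the vertical angle from
Normal(0, 2 deg) restricted to [-4, 4].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entrance_pupil import entrance_pupil_metrics
from .landmarks import compute_cw_chord
from .optics import EyeBiometry, EyeModel, IncidentAngle, flip_to_left_eye

__all__ = [
    "ParameterSpec",
    "PopulationSpec",
    "sample_incident_angles",
    "synthesize_population",
    "run_monte_carlo",
    "summarize_population",
    "BIOMETRY_COLUMNS",
]

BIOMETRY_COLUMNS = ("Ra", "Qa", "Rp", "Qp", "CCT", "ACD", "Pup", "Pup_X", "Pup_Y")

_LANDMARK_COLUMNS = (
    "PupC_X",
    "PupC_Y",
    "PurkinjeC_X",
    "PurkinjeC_Y",
    "PupR_X",
    "PupR_Y",
    "PurkinjeR_X",
    "PurkinjeR_Y",
    "CW_X",
    "CW_Y",
)
_ELLIPSE_COLUMNS = (
    "EllipseC_X",
    "EllipseC_Y",
    "EllipseR_X",
    "EllipseR_Y",
    "D_long",
    "D_short",
    "A_long",
    "A_short",
    "aspect",
    "magnification",
)


@dataclass(frozen=True)
class ParameterSpec:
    """Truncated-normal specification of one biometric parameter."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not self.lower <= self.upper:
            raise ValueError("truncation bounds must be ordered")


def _default_parameters() -> dict[str, ParameterSpec]:
    # Means/SDs of a large anterior-segment OCT cohort; truncation at the
    # empirical 5%/95% quantiles widened by two SDs.
    return {
        "Ra": ParameterSpec(7.76, 0.28, 6.77, 8.83),
        "Qa": ParameterSpec(-0.22, 0.13, -0.70, 0.25),
        "Rp": ParameterSpec(6.56, 0.25, 5.67, 7.49),
        "Qp": ParameterSpec(-0.11, 0.11, -0.55, 0.28),
        "CCT": ParameterSpec(0.55, 0.04, 0.41, 0.68),
        "ACD": ParameterSpec(3.36, 0.40, 1.87, 4.79),
        "Pup": ParameterSpec(3.24, 0.81, 0.83, 6.28),
        "Pup_X": ParameterSpec(-0.30, 0.21, -1.12, 0.42),
        "Pup_Y": ParameterSpec(-0.10, 0.19, -0.78, 0.58),
    }


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a synthetic left-eye biometry population."""

    n: int
    seed: int | None = None
    ra_rp_correlation: float = 0.85
    parameters: dict[str, ParameterSpec] = field(default_factory=_default_parameters)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be at least 1")
        if not -1.0 <= self.ra_rp_correlation <= 1.0:
            raise ValueError("|correlation| must not exceed 1")
        missing = set(BIOMETRY_COLUMNS) - set(self.parameters)
        if missing:
            raise ValueError(f"missing parameter specs: {sorted(missing)}")


def _truncated_normal(rng: np.random.Generator, spec: ParameterSpec, n: int) -> np.ndarray:
    """Rejection-sample a truncated normal (exact, no reweighting)."""
    if spec.sd == 0:
        return np.full(n, spec.mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(spec.mean, spec.sd, size=max(n - filled, 64))
        keep = draw[(draw >= spec.lower) & (draw <= spec.upper)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def sample_incident_angles(n: int, seed=None) -> pd.DataFrame:
    """Sample ``n`` incident beam angles (degrees).

    ``I_X ~ Normal(-5, 2)`` rejected outside ``[-9, -1]``;
    ``I_Y ~ Normal(0, 2)`` rejected outside ``[-4, 4]``.  ``seed`` may be
    an int or a :class:`numpy.random.Generator`.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ix = _truncated_normal(rng, ParameterSpec(-5.0, 2.0, -9.0, -1.0), n)
    iy = _truncated_normal(rng, ParameterSpec(0.0, 2.0, -4.0, 4.0), n)
    return pd.DataFrame({"I_X": ix, "I_Y": iy})


def synthesize_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a synthetic left-eye biometry table from ``spec``.

    ``Ra`` and ``Rp`` are drawn jointly from a bivariate normal with the
    configured correlation (rejection-truncated to both parameters'
    bounds); every other parameter is an independent truncated normal.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.parameters
    n = spec.n

    ra_s, rp_s = p["Ra"], p["Rp"]
    rho = spec.ra_rp_correlation
    cov = np.array(
        [
            [ra_s.sd**2, rho * ra_s.sd * rp_s.sd],
            [rho * ra_s.sd * rp_s.sd, rp_s.sd**2],
        ]
    )
    ra = np.empty(n)
    rp = np.empty(n)
    filled = 0
    if ra_s.sd == 0 and rp_s.sd == 0:
        ra[:], rp[:] = ra_s.mean, rp_s.mean
        filled = n
    while filled < n:
        draw = rng.multivariate_normal([ra_s.mean, rp_s.mean], cov, size=max(n - filled, 64))
        inside = (
            (draw[:, 0] >= ra_s.lower)
            & (draw[:, 0] <= ra_s.upper)
            & (draw[:, 1] >= rp_s.lower)
            & (draw[:, 1] <= rp_s.upper)
        )
        keep = draw[inside]
        take = min(keep.shape[0], n - filled)
        ra[filled : filled + take] = keep[:take, 0]
        rp[filled : filled + take] = keep[:take, 1]
        filled += take

    table = {"laterality": np.full(n, "left", dtype=object), "Ra": ra, "Rp": rp}
    for name in ("Qa", "Qp", "CCT", "ACD", "Pup", "Pup_X", "Pup_Y"):
        table[name] = _truncated_normal(rng, p[name], n)
    df = pd.DataFrame(table, columns=("laterality",) + BIOMETRY_COLUMNS)
    # guard against an infeasible ACD/CCT overlap in user-supplied specs
    bad = df["ACD"] <= df["CCT"]
    if bad.any():
        raise ValueError("sampled ACD <= CCT; tighten the truncation bounds")
    return df


def _row_to_biometry(row) -> EyeBiometry:
    return EyeBiometry(
        laterality=row.get("laterality", "left"),
        Ra=row["Ra"],
        Qa=row["Qa"],
        Rp=row["Rp"],
        Qp=row["Qp"],
        CCT=row["CCT"],
        ACD=row["ACD"],
        Pup=row["Pup"],
        Pup_X=row["Pup_X"],
        Pup_Y=row["Pup_Y"],
    )


def run_monte_carlo(
    population: pd.DataFrame,
    angles: pd.DataFrame,
    compute_ellipse: bool = False,
    ellipse_subsample: int = 300,
    n_rays: int = 2000,
    bundle_diameter: float = 7.0,
) -> pd.DataFrame:
    """Trace every eye of ``population`` at its paired incident angle.

    Returns one row per eye holding the biometry, the angles, all
    landmark/chord coordinates and (optionally, on the first
    ``ellipse_subsample`` eyes) the entrance-pupil ellipse metrics.
    Per-eye failures are flagged in an ``error`` column rather than
    aborting the batch.
    """
    if len(population) != len(angles):
        raise ValueError("population and angles must have equal length")
    records = []
    ellipse_rows = min(ellipse_subsample, len(population)) if compute_ellipse else 0
    for i, (idx, row) in enumerate(population.iterrows()):
        rec = {c: row[c] for c in BIOMETRY_COLUMNS}
        rec["I_X"] = angles.iloc[i]["I_X"]
        rec["I_Y"] = angles.iloc[i]["I_Y"]
        rec["error"] = ""
        try:
            eye = flip_to_left_eye(_row_to_biometry(row))
            model = EyeModel.from_biometry(eye)
            rec["Pup_X"] = eye.Pup_X  # left-normalised
            angle = IncidentAngle(rec["I_X"], rec["I_Y"])
            lm = compute_cw_chord(model, angle)
            for c in _LANDMARK_COLUMNS:
                rec[c] = getattr(lm, c)
            if i < ellipse_rows:
                ell = entrance_pupil_metrics(model, angle, n_rays, bundle_diameter)
                for c in _ELLIPSE_COLUMNS:
                    rec[c] = getattr(ell, c)
        except Exception as exc:  # noqa: BLE001 - per-row fault isolation
            rec["error"] = f"{type(exc).__name__}: {exc}"
        records.append(rec)
    return pd.DataFrame(records, index=population.index)


def summarize_population(results: pd.DataFrame) -> pd.DataFrame:
    """Column-wise MEAN, SD, MEDIAN and empirical 5%/95% quantiles.

    Only numeric columns are summarised; rows flagged in an ``error``
    column are excluded first.
    """
    df = results
    if "error" in df.columns:
        df = df[df["error"].fillna("").astype(str) == ""]
    num = df.select_dtypes(include=[np.number])
    if len(num) < 2:
        raise ValueError("need at least 2 valid rows to summarise")
    out = pd.DataFrame(
        {
            "MEAN": num.mean(),
            "SD": num.std(ddof=1),
            "MEDIAN": num.median(),
            "5% CL": num.quantile(0.05),
            "95% CL": num.quantile(0.95),
        }
    )
    return out.T
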