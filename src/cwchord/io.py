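"""CSV input/output for per-eye biometry tables.

The expected table mirrors a clinical anterior-segment tomographer
export reduced to the raytracing-relevant columns: ``laterality, Ra, Qa,
Rp, Qp, CCT, ACD, Pup, Pup_X, Pup_Y`` (lengths in mm), optionally
``I_X``/``I_Y`` in degrees and a ``status`` column used to exclude
pseudophakic, mydriatic, ectatic or incomplete records.  Headers are
matched case-insensitively; the locale variant with semicolon separators
and comma decimals is supported behind flags.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .population import BIOMETRY_COLUMNS

__all__ = ["SchemaError", "read_biometry_csv", "write_results_csv", "DEFAULT_EXCLUDED_STATUS"]

logger = logging.getLogger("cwchord")

REQUIRED_COLUMNS = ("laterality",) + BIOMETRY_COLUMNS
OPTIONAL_COLUMNS = ("I_X", "I_Y")

#: status tokens excluded by default, mirroring typical clinical filtering
DEFAULT_EXCLUDED_STATUS = ("pseudophakic", "mydriasis", "ectasia", "incomplete")

# crude unit plausibility windows (mm / dimensionless / degrees)
_PLAUSIBLE = {
    "Ra": (4.0, 14.0),
    "Rp": (3.0, 12.0),
    "Qa": (-3.0, 3.0),
    "Qp": (-3.0, 3.0),
    "CCT": (0.2, 1.2),
    "ACD": (1.0, 7.0),
    "Pup": (0.5, 10.0),
    "Pup_X": (-3.0, 3.0),
    "Pup_Y": (-3.0, 3.0),
    "I_X": (-45.0, 45.0),
    "I_Y": (-45.0, 45.0),
}


class SchemaError(ValueError):
    """The CSV does not conform to the biometry schema."""


def read_biometry_csv(
    path,
    *,
    delimiter: str = ",",
    decimal: str = ".",
    status_column: str | None = "status",
    excluded_status=DEFAULT_EXCLUDED_STATUS,
    normalise: bool = True,
) -> pd.DataFrame:
    """Read, validate and left-normalise a biometry table.

    Right-eye rows have ``Pup_X`` negated and their laterality set to
    ``left`` when ``normalise`` is true.  Rows whose ``status`` matches
    an excluded token are dropped (counts logged); rows violating the
    biometric invariants raise a :class:`SchemaError` naming the row.
    """
    df = pd.read_csv(path, sep=delimiter, decimal=decimal, comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    lookup = {c.lower(): c for c in df.columns}
    missing = [c for c in REQUIRED_COLUMNS if c.lower() not in lookup]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    rename = {lookup[c.lower()]: c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c.lower() in lookup}
    df = df.rename(columns=rename)

    if status_column and status_column.lower() in lookup:
        status = df[lookup[status_column.lower()]].astype(str).str.strip().str.lower()
        drop = status.isin([s.lower() for s in excluded_status])
        if drop.any():
            counts = status[drop].value_counts().to_dict()
            logger.info("excluding %d rows by status: %s", int(drop.sum()), counts)
        df = df[~drop].copy()

    for col in BIOMETRY_COLUMNS + tuple(c for c in OPTIONAL_COLUMNS if c in df.columns):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        lo, hi = _PLAUSIBLE[col]
        values = df[col].to_numpy(dtype=float)
        implausible = np.isfinite(values) & ((values < lo) | (values > hi))
        if implausible.any():
            row = int(df.index[implausible][0])
            raise SchemaError(
                f"{path}: column {col} value {values[implausible][0]!r} at row "
                f"{row} outside plausible range [{lo}, {hi}] (unit error?)"
            )

    bad_rows = []
    for idx, r in df.iterrows():
        problems = []
        if not np.isfinite([r[c] for c in BIOMETRY_COLUMNS]).all():
            problems.append("incomplete numeric data")
        else:
            if r["Ra"] <= 0 or r["Rp"] <= 0:
                problems.append("non-positive corneal radius")
            if r["CCT"] <= 0:
                problems.append("non-positive CCT")
            if r["ACD"] <= r["CCT"]:
                problems.append("ACD <= CCT")
            if r["Pup"] <= 0:
                problems.append("non-positive pupil diameter")
        if str(r["laterality"]).strip().lower() not in ("left", "right", "l", "r", "od", "os"):
            problems.append(f"unknown laterality {r['laterality']!r}")
        if problems:
            bad_rows.append((idx, problems))
    if bad_rows:
        detail = "; ".join(f"row {i}: {', '.join(p)}" for i, p in bad_rows[:10])
        raise SchemaError(f"{path}: {len(bad_rows)} invalid rows ({detail})")

    if normalise:
        lat = df["laterality"].astype(str).str.strip().str.lower()
        right = lat.isin(["right", "r", "od"])
        df.loc[right, "Pup_X"] = -df.loc[right, "Pup_X"]
        df["laterality"] = "left"
    return df.reset_index(drop=True)


def write_results_csv(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a results table with ``# key: value`` provenance header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)
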