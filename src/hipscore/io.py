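"""Table schemas and delimited-text I/O.

All tables are comma-delimited UTF-8 with mandatory headers.  The reader is
tolerant — unknown extra columns are preserved with a warning — while the
writer is strict about emitting exactly the schema columns first.  Machine
files keep full float precision; human-facing report rounding happens in
the pipeline, not here.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .scoring import STRUCTURES

#: schema name -> (required columns, numeric columns)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "cohort": (
        ("id", "sex", "age_months", "height_cm", "weight_kg"),
        ("age_months", "height_cm", "weight_kg"),
    ),
    "scores": (("image_id", "rater_id", *STRUCTURES), STRUCTURES),
    "scored": (
        ("image_id", *STRUCTURES, "q", "qualified"),
        (*STRUCTURES, "q"),
    ),
    "angles": (
        ("case_id", "method", "alpha_deg", "beta_deg"),
        ("alpha_deg", "beta_deg"),
    ),
    "stats_report": (("statistic", "value", "p", "n"), ("value", "n")),
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a delimited table and check it against a named schema.

    Raises :class:`ValidationError` for a missing file, a missing required
    column, or a non-numeric cell in a numeric column (naming row and
    column).  Extra columns are kept, with a warning.
    """
    if schema not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{schema} table not found: {path}")
    df = pd.read_csv(path)
    required, numeric = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: unknown column(s) {extra} preserved", stacklevel=2)
    for c in numeric:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any() or df[c].isna().any():
            row = int(np.flatnonzero((coerced.isna()).to_numpy())[0])
            raise ValidationError(f"{path}: non-numeric or missing value at row {row}, column {c!r}")
        df[c] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> Path:
    """Write a table, schema columns first, full precision, UTF-8."""
    required, _ = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"cannot write {schema}: missing column(s) {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ordered = [*required, *[c for c in df.columns if c not in required]]
    df[ordered].to_csv(path, index=False)
    return path


def write_weights(weights: dict[str, float], path: str | Path) -> Path:
    """Structure-name -> weight mapping as a small JSON file (full precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(weights, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def read_weights(path: str | Path) -> dict[str, float]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"weights file not found: {path}")
    data = json.loads(path.read_text(encoding="utf-8"))
    missing = [s for s in STRUCTURES if s not in data]
    if missing:
        raise ValidationError(f"{path}: missing weight(s) for {missing}")
    return {s: float(data[s]) for s in STRUCTURES}


def write_json(obj: dict, path: str | Path) -> Path:
    """Deterministic JSON dump (sorted keys, no timestamps)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path
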