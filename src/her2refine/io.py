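"""Cohort CSV schema, scoring round-trips, and run manifests.

The cohort exchange format is a UTF-8 comma-separated file with a header
row and columns ``case_id``, the eight membranous pattern percentages
(``pct_faint_complete`` ... ``pct_strong_incomplete``), ``pct_cytoplasmic``,
and optionally ``mrna`` and ``clinical_score``; scores serialise as "0",
"1+", "2+", "3+".  Numeric values round-trip at 12 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .profiles import (
    PATTERN_FIELDS,
    ExpressionProfile,
    RefinedRuleSet,
    guideline_score,
    modified_h_score,
    refined_score,
    validate_profile,
)

__all__ = [
    "SchemaError",
    "PATTERN_COLUMNS",
    "REQUIRED_COLUMNS",
    "read_cohort",
    "write_cohort",
    "profiles_from_frame",
    "score_frame",
    "append_manifest",
]

PATTERN_COLUMNS = tuple(f"pct_{name}" for name in PATTERN_FIELDS)
REQUIRED_COLUMNS = ("case_id", *PATTERN_COLUMNS, "pct_cytoplasmic")
FLOAT_FORMAT = "%.12g"


class SchemaError(ValueError):
    """Cohort file violates the CSV schema; message carries row/column."""


def read_cohort(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`SchemaError` naming the missing column or offending
    row/column when validation fails.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if validate:
        _validate_frame(df, str(path))
    return df


def _validate_frame(df: pd.DataFrame, origin: str) -> None:
    for col in (*PATTERN_COLUMNS, "pct_cytoplasmic"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(f"{origin}: column {col!r} non-numeric at row {bad[0]}")
        out = df.index[(numeric < 0) | (numeric > 100)]
        if len(out):
            raise SchemaError(
                f"{origin}: column {col!r} outside [0, 100] at row {out[0]}"
            )
    total = df[list(PATTERN_COLUMNS)].sum(axis=1)
    over = df.index[total > 100.0 + 1e-9]
    if len(over):
        raise SchemaError(
            f"{origin}: membranous percentages sum to {total[over[0]]:.6g} > 100 "
            f"at row {over[0]}"
        )


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def profiles_from_frame(df: pd.DataFrame) -> list[ExpressionProfile]:
    """Materialise one :class:`ExpressionProfile` per row."""
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            ExpressionProfile(
                case_id=str(row.get("case_id", "")),
                cytoplasmic_pct=float(row.get("pct_cytoplasmic", 0.0)),
                **{name: float(row[f"pct_{name}"]) for name in PATTERN_FIELDS},
            )
        )
    return profiles


def score_frame(
    df: pd.DataFrame,
    rules: RefinedRuleSet | None = None,
    ruleset: str = "both",
) -> pd.DataFrame:
    """Append per-case scores to a cohort frame.

    Adds ``refined_score`` and/or ``guideline_score`` plus ``h_score``
    (modified H-score).  A case whose only staining is cytoplasmic scores
    0 and is flagged in ``cytoplasmic_only``.
    """
    rules = rules or RefinedRuleSet()
    out = df.copy()
    profiles = profiles_from_frame(df)
    for p in profiles:
        violations = validate_profile(p)
        if violations:
            raise SchemaError(f"case {p.case_id!r}: {violations[0]}")
    if ruleset in ("both", "refined"):
        out["refined_score"] = [str(refined_score(p, rules)) for p in profiles]
    if ruleset in ("both", "guideline"):
        out["guideline_score"] = [str(guideline_score(p)) for p in profiles]
    if ruleset not in ("both", "refined", "guideline"):
        raise ValueError(f"unknown ruleset {ruleset!r}")
    out["h_score"] = [float(modified_h_score(p)) for p in profiles]
    out["cytoplasmic_only"] = [
        p.cytoplasmic_pct > 0 and p.membranous_total == 0 for p in profiles
    ]
    return out


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def append_manifest(
    path: str | Path,
    command: str,
    seed: int | None = None,
    config=None,
    inputs: Iterable[str] = (),
    outputs: Iterable[str] = (),
) -> dict:
    """Append one JSON-lines record to the run manifest (append-only)."""
    record = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "command": command,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "inputs": list(inputs),
        "outputs": list(outputs),
        "version": __version__,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("a", encoding="utf-8") as fh:
        fh.write(json.dumps(record) + "\n")
    return record
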