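"""Cohort table schema, validation, and CSV round-trip.

A cohort is a plain :class:`pandas.DataFrame` with one row per
(subject, visit).  Nine clinical outcome assessment (COA) columns hold the
observed severity indicators; optional columns hold external correlates
(quantitative EEG power ratios, quality of life, behavior).  Missing values
are NaN in memory and empty cells on disk.
"""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

# Canonical order of the nine observed COA variables (weight-table order:
# motor first, then comorbidities, communication, vision, feeding).
OBSERVED_VARS: tuple[str, ...] = (
    "motor",
    "insomnia",
    "sleepiness",
    "seizures",
    "alertness",
    "comm_clinician",
    "csbs",
    "vision",
    "feeding",
)

# Instrument blocks: all domains of one questionnaire are reported (or
# missing) together.  EEG / QoL / behavior correlates get their own blocks.
INSTRUMENTS: dict[str, tuple[str, ...]] = {
    "clinician": ("motor", "vision", "comm_clinician"),
    "caregiver": ("seizures", "alertness", "feeding", "behavior"),
    "sleep": ("insomnia", "sleepiness"),
    "csbs": ("csbs",),
    "qol": ("qol_total",),
    "eeg": ("eeg_alpha_delta", "eeg_theta_delta"),
}

# Raw scale range of each bounded variable.  Eight COAs run 0-100; the
# communication checklist total runs 0-57.  EEG power ratios are unbounded.
SCALE_RANGES: dict[str, tuple[float, float]] = {
    "motor": (0.0, 100.0),
    "insomnia": (0.0, 100.0),
    "sleepiness": (0.0, 100.0),
    "seizures": (0.0, 100.0),
    "alertness": (0.0, 100.0),
    "comm_clinician": (0.0, 100.0),
    "csbs": (0.0, 57.0),
    "vision": (0.0, 100.0),
    "feeding": (0.0, 100.0),
    "qol_total": (0.0, 100.0),
    "behavior": (0.0, 100.0),
}

# Raw score direction: True means a higher raw score indicates better
# functioning (so harmonization flips it to a severity direction).  The
# clinician/caregiver assessments and the sleep questionnaire are scored
# higher-is-better; the communication checklist total is scored
# higher-is-more-severe in this cohort's convention.  Directions are
# configuration, not constants, because published instrument conventions
# differ; these defaults match the study data dictionary.
HIGHER_IS_BETTER: dict[str, bool] = {
    "motor": True,
    "insomnia": True,
    "sleepiness": True,
    "seizures": True,
    "alertness": True,
    "comm_clinician": True,
    "csbs": False,
    "vision": True,
    "feeding": True,
}

EXTERNAL_VARS: tuple[str, ...] = (
    "eeg_alpha_delta",
    "eeg_theta_delta",
    "qol_total",
    "behavior",
)

META_COLS: tuple[str, ...] = ("subject_id", "visit", "age_group", "sex")

AGE_GROUPS = ("under7", "over7")
VISITS = ("baseline", "retest")


class CohortError(ValueError):
    """Malformed cohort table (schema, range, or duplicate-key violation)."""


def validate_cohort(df: pd.DataFrame, *, ranges: dict | None = None) -> pd.DataFrame:
    """Validate a cohort frame in place and return it.

    Checks: required columns present, every present bounded score within its
    declared range, no duplicate (subject_id, visit), retest rows reference
    an existing baseline subject.
    """
    ranges = dict(SCALE_RANGES if ranges is None else ranges)
    missing_cols = [c for c in ("subject_id", "visit") if c not in df.columns]
    if missing_cols:
        raise CohortError(f"cohort is missing required columns: {missing_cols}")
    missing_obs = [c for c in OBSERVED_VARS if c not in df.columns]
    if missing_obs:
        raise CohortError(f"cohort is missing observed-score columns: {missing_obs}")

    bad_visit = set(df["visit"].dropna()) - set(VISITS)
    if bad_visit:
        raise CohortError(f"unknown visit labels: {sorted(bad_visit)}")

    dup = df.duplicated(subset=["subject_id", "visit"])
    if dup.any():
        rows = df.index[dup].tolist()[:5]
        raise CohortError(f"duplicate (subject_id, visit) pairs at rows {rows}")

    for col, (lo, hi) in ranges.items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        out = vals.notna() & ((vals < lo - 1e-9) | (vals > hi + 1e-9))
        if out.any():
            row = int(df.index[out][0])
            raise CohortError(
                f"value {vals[out].iloc[0]!r} in column {col!r} at row {row} "
                f"is outside the declared range [{lo}, {hi}]"
            )

    retest = df[df["visit"] == "retest"]
    if len(retest):
        base_ids = set(df.loc[df["visit"] == "baseline", "subject_id"])
        orphans = set(retest["subject_id"]) - base_ids
        if orphans:
            raise CohortError(
                f"retest rows without a baseline row: {sorted(orphans)[:5]}"
            )
    return df


def _provenance_lines(meta: dict) -> list[str]:
    return [f"# {k}={v}" for k, v in meta.items()]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_cohort(df: pd.DataFrame, path: str | Path, *, meta: dict | None = None) -> None:
    """Write a cohort CSV with '#'-prefixed provenance header lines.

    Missing values are written as empty cells.
    """
    path = Path(path)
    buf = io.StringIO()
    for line in _provenance_lines(meta or {}):
        buf.write(line + "\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_cohort(path: str | Path, *, validate: bool = True) -> pd.DataFrame:
    """Read a cohort CSV (empty cells = missing; '#' lines are provenance).

    Unknown columns are preserved.  Handles UTF-8 BOM and CRLF endings.
    """
    df = pd.read_csv(path, comment="#", encoding="utf-8-sig", skip_blank_lines=True)
    df.columns = [c.strip() for c in df.columns]
    for col in OBSERVED_VARS + EXTERNAL_VARS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if validate:
        validate_cohort(df)
    return df
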