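"""Reading and writing survival tables.

The on-disk format is a plain CSV with one row per subject: a follow-up
time column (years by default), an event indicator column (1 = event,
0 = right-censored) and any number of named covariate columns. Rows with
missing values are rejected with a per-row report; structurally invalid
fields (non-numeric entries, non-positive times, event codes outside
{0, 1}) raise errors that name the offending line numbers, counting the
header as line 1.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .regression import SurvivalData

__all__ = ["read_survival_table", "write_survival_table", "file_checksum"]

logger = logging.getLogger("hypertabph")

_TIME_DIVISORS = {"years": 1.0, "months": 12.0, "days": 365.25}


def file_checksum(path) -> str:
    """SHA-256 of a file, for run provenance logging."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _lines(index) -> list[int]:
    # +2: header occupies line 1 and pandas indexes data rows from 0
    return [int(i) + 2 for i in index]


def read_survival_table(
    path,
    time_col: str = "time",
    event_col: str = "event",
    covariates: Sequence[str] | None = None,
    time_unit: str = "years",
) -> SurvivalData:
    """Read and validate a survival CSV into a :class:`SurvivalData`.

    ``covariates`` selects covariate columns (default: every column other
    than time, event and an optional ``id``). ``time_unit`` converts
    day- or month-scaled times to years at read time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if time_unit not in _TIME_DIVISORS:
        raise ValueError(f"unknown time unit {time_unit!r}; use years/months/days")
    try:
        # round-trip parsing keeps written floats bitwise identical on reread
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    for col in (time_col, event_col):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if covariates is None:
        covariates = [
            c for c in frame.columns if c not in (time_col, event_col, "id")
        ]
    else:
        missing = [c for c in covariates if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: covariate columns not found: {missing}")

    used = [time_col, event_col, *covariates]
    sub = frame[used]
    na_rows = sub.index[sub.isna().any(axis=1)]
    if len(na_rows):
        for ln in _lines(na_rows):
            logger.warning("%s: dropping line %d (missing values)", path, ln)
        sub = sub.drop(index=na_rows)
    if sub.empty:
        raise ValueError(f"{path}: all rows rejected (missing values)")

    numeric = sub.apply(pd.to_numeric, errors="coerce")
    bad = numeric.index[numeric.isna().any(axis=1)]
    if len(bad):
        raise ValueError(
            f"{path}: non-numeric fields on lines {_lines(bad)}"
        )
    time = numeric[time_col].to_numpy(dtype=float) / _TIME_DIVISORS[time_unit]
    event = numeric[event_col].to_numpy()
    bad_t = numeric.index[time <= 0]
    if len(bad_t):
        raise ValueError(f"{path}: non-positive times on lines {_lines(bad_t)}")
    bad_e = numeric.index[~np.isin(event, (0, 1))]
    if len(bad_e):
        raise ValueError(
            f"{path}: event indicators outside {{0, 1}} on lines {_lines(bad_e)}"
        )
    data = SurvivalData(
        time=time, event=event.astype(int), covariates=numeric[list(covariates)].reset_index(drop=True)
    )
    logger.info(
        "%s: read %d subjects (%d events, %d covariates)",
        path,
        data.n,
        data.n_events,
        len(data.names),
    )
    return data


def write_survival_table(data: SurvivalData, path) -> None:
    """Write a SurvivalData back to the survival CSV format."""
    frame = pd.DataFrame({"time": data.time, "event": data.event})
    frame = pd.concat([frame, data.covariates.reset_index(drop=True)], axis=1)
    frame.to_csv(path, index=False)
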