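"""Long-format CSV reading and writing for AGF data.

One generic long-format dialect is supported: UTF-8 CSV with a header
row and columns

    subject_id, electrode_id, condition_label, ipg_us,
    phase_duration_us, current_value, current_unit, amplitude_uv

plus an optional ``g`` column carrying the condition gain when known
(simulated data round-trips it; measured data normally omits it, and the
gain defaults to 1).  One current unit per file.  Rows are grouped by
(subject, electrode, condition); groups are sorted by current, with a
logged warning when the file was out of order, and groups with fewer
than 3 points are rejected with a logged reason while the remaining
curves load.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .errors import ParseError
from .model import AGFCurve, StimulusCondition
from .units import SUPPORTED_UNITS

logger = logging.getLogger("ecapagf")

REQUIRED_COLUMNS = (
    "subject_id",
    "electrode_id",
    "condition_label",
    "ipg_us",
    "phase_duration_us",
    "current_value",
    "current_unit",
    "amplitude_uv",
)
_NUMERIC = ("ipg_us", "phase_duration_us", "current_value", "amplitude_uv", "g")
GROUP_KEYS = ["subject_id", "electrode_id", "condition_label"]


def read_agf_csv(path, dialect: str = "generic") -> List[AGFCurve]:
    """Read a long-format AGF CSV into a list of curves.

    Malformed content (missing columns, non-numeric fields, mixed or
    unknown current units, duplicate currents within a group) raises
    :class:`ParseError` naming the offending lines; recoverable issues
    (unsorted rows, short groups) are logged and handled.
    """
    if dialect != "generic":
        raise ParseError(f"unknown dialect {dialect!r}; only 'generic' is supported")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    # line numbers in the physical file: header is line 1
    df.index = df.index + 2

    bad_lines = []
    for col in _NUMERIC:
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()].tolist()
        bad_lines.extend((line, col) for line in bad)
        df[col] = converted
    if bad_lines:
        detail = ", ".join(f"line {ln} ({col})" for ln, col in bad_lines[:20])
        raise ParseError(f"{path}: non-numeric fields at {detail}")

    units = set(df["current_unit"].unique())
    unknown = units - set(SUPPORTED_UNITS)
    if unknown:
        raise ParseError(f"{path}: unknown current unit(s) {sorted(unknown)}")
    if len(units) > 1:
        raise ParseError(f"{path}: mixed current units {sorted(units)}; one per file")

    dup_mask = df.duplicated(subset=GROUP_KEYS + ["current_value"], keep=False)
    if dup_mask.any():
        lines = df.index[dup_mask].tolist()
        raise ParseError(
            f"{path}: duplicate (group, current) rows at lines {lines}"
        )

    curves: List[AGFCurve] = []
    for (subj, elec, label), grp in df.groupby(GROUP_KEYS, sort=True):
        if len(grp) < 3:
            logger.warning(
                "rejecting %s/%s/%s: only %d point(s), need >= 3",
                subj, elec, label, len(grp),
            )
            continue
        if not grp["current_value"].is_monotonic_increasing:
            logger.warning(
                "currents out of order in %s/%s/%s; sorting", subj, elec, label
            )
        grp = grp.sort_values("current_value")
        g = float(grp["g"].iloc[0]) if "g" in grp.columns else 1.0
        condition = StimulusCondition(
            label=str(label),
            ipg_us=float(grp["ipg_us"].iloc[0]),
            phase_duration_us=float(grp["phase_duration_us"].iloc[0]),
            g=g,
        )
        curves.append(
            AGFCurve(
                subject_id=str(subj),
                electrode_id=str(elec),
                condition=condition,
                currents=grp["current_value"].to_numpy(float),
                amplitudes=grp["amplitude_uv"].to_numpy(float),
                current_unit=str(grp["current_unit"].iloc[0]),
            )
        )
    return curves


def write_agf_csv(curves: List[AGFCurve], path) -> None:
    """Write curves to the generic long-format CSV, loss-free.

    Floats are written at full repr precision, so a write/read round
    trip preserves curve data to better than 1e-12 relative error.
    """
    rows = []
    for curve in curves:
        for i_val, v_val in zip(curve.currents, curve.amplitudes):
            rows.append(
                {
                    "subject_id": curve.subject_id,
                    "electrode_id": curve.electrode_id,
                    "condition_label": curve.condition.label,
                    "ipg_us": curve.condition.ipg_us,
                    "phase_duration_us": curve.condition.phase_duration_us,
                    "current_value": repr(float(i_val)),
                    "current_unit": curve.current_unit,
                    "amplitude_uv": repr(float(v_val)),
                    "g": repr(float(curve.condition.g)),
                }
            )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + ["g"]).to_csv(
        path, index=False
    )
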