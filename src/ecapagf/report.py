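"""End-to-end offset report: CSV in, per-electrode effect table out.

This is the package's equivalent of an "offset-effect calculator": it
loads a two-condition AGF file, pairs the conditions on each electrode
(longer IPG = higher-gain condition), fits sigmoids, computes every
differential measure, and reports excluded electrodes with their
reasons — exclusion bookkeeping being part of the method's practice
(truncated or noisy electrodes routinely yield no measurable growth
function).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, ECAPError
from .features import fit_sigmoid
from .effects import compute_ipg_effects
from .io import read_agf_csv
from .model import AGFCurve

logger = logging.getLogger("ecapagf")


@dataclass(frozen=True)
class ReportConfig:
    """Tunables of the offset report (flat, config-file friendly)."""

    frac_lo: float = 0.2
    frac_hi: float = 0.8
    n_levels: int = 10

    @classmethod
    def from_mapping(cls, mapping: Dict) -> "ReportConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


RESULT_COLUMNS = [
    "subject_id",
    "electrode_id",
    "condition_long",
    "condition_short",
    "offset_db",
    "offset_n_levels",
    "slope_effect_lin",
    "slope_effect_log",
    "slope_ratio_lin",
    "i50_offset_db",
    "overlap_lo_uv",
    "overlap_hi_uv",
]


def pair_conditions(curves: List[AGFCurve]) -> List[Tuple[AGFCurve, AGFCurve]]:
    """Group curves by electrode and order each pair as (long, short) IPG.

    Every electrode must carry exactly two conditions; anything else is
    a configuration error, not a per-electrode exclusion.
    """
    by_electrode: Dict[Tuple[str, str], List[AGFCurve]] = {}
    for curve in curves:
        by_electrode.setdefault((curve.subject_id, curve.electrode_id), []).append(curve)
    pairs = []
    for key in sorted(by_electrode):
        group = by_electrode[key]
        if len(group) != 2:
            raise ConfigError(
                f"electrode {key[0]}/{key[1]} has {len(group)} condition(s); "
                "the offset report requires exactly 2"
            )
        group.sort(key=lambda c: c.condition.ipg_us, reverse=True)
        pairs.append((group[0], group[1]))
    return pairs


def run_offset_report(
    input_path, config: ReportConfig = ReportConfig()
) -> Tuple[pd.DataFrame, List[Dict[str, str]]]:
    """Compute the per-electrode effect table for a two-condition AGF file.

    Returns ``(results, exclusions)``: a DataFrame with one row per
    usable electrode in deterministic (subject, electrode) order, and a
    list of ``{subject_id, electrode_id, reason}`` dicts for electrodes
    that failed the linear-region or overlap rules.
    """
    curves = read_agf_csv(input_path)
    pairs = pair_conditions(curves)
    rows, exclusions = [], []
    for curve_long, curve_short in pairs:
        try:
            fit_l = fit_sigmoid(curve_long)
            fit_s = fit_sigmoid(curve_short)
            res = compute_ipg_effects(
                curve_long,
                curve_short,
                frac_lo=config.frac_lo,
                frac_hi=config.frac_hi,
                n_levels=config.n_levels,
                fit_a=fit_l,
                fit_b=fit_s,
            )
        except ECAPError as exc:
            reason = str(exc)
            logger.warning(
                "excluding %s/%s: %s",
                curve_long.subject_id, curve_long.electrode_id, reason,
            )
            exclusions.append(
                {
                    "subject_id": curve_long.subject_id,
                    "electrode_id": curve_long.electrode_id,
                    "reason": reason,
                }
            )
            continue
        rows.append(
            {
                "subject_id": res.subject_id,
                "electrode_id": res.electrode_id,
                "condition_long": res.condition_pair[0],
                "condition_short": res.condition_pair[1],
                "offset_db": res.offset_db,
                "offset_n_levels": res.offset_n_levels,
                "slope_effect_lin": res.slope_effect_lin,
                "slope_effect_log": res.slope_effect_log,
                "slope_ratio_lin": res.slope_ratio_lin,
                "i50_offset_db": np.nan
                if res.i50_offset_db is None
                else res.i50_offset_db,
                "overlap_lo_uv": res.overlap_lo_uv,
                "overlap_hi_uv": res.overlap_hi_uv,
            }
        )
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return results, exclusions
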