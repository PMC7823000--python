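"""Differential IPG-effect measures from a pair of growth functions.

Given two AGFs measured on the same electrode with stimuli differing only
in interphase gap (hence only in the effective gain g), this module
computes the full family of differential measures that circulate in the
ECAP literature:

* the **IPG slope effect** — difference of linear-region slopes — in any
  coordinate convention, plus the slope *ratio*;
* the **I50 % offset** — difference between fitted half-max currents;
* the **IPG offset effect** — the mean horizontal dB offset between the
  overlapping linear portions of the two curves, the measure that is
  provably independent of recording (r), survival (n) and
  stimulating-side (s) factors under the multiplicative growth model and
  therefore isolates the gain (neural-health) factor.

Sign convention throughout: ``curve_a`` is the long-IPG (higher-gain)
condition, and offsets are reported as short-IPG current minus long-IPG
current at equal output, so a healthier (larger) gain ratio gives a
positive offset in dB.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import DomainError, InsufficientRegionError, InvalidFitError, NoOverlapError
from .model import AGFCurve
from .features import LinearRegion, SigmoidFit, extract_linear_region

#: Overlap must span at least this fraction of the narrower curve's
#: linear-region amplitude range (in log-amplitude), else the electrode
#: is rejected as having no usable overlap.
MIN_OVERLAP_FRAC = 0.1


@dataclass(frozen=True)
class OffsetDiagnostics:
    """Per-level detail behind one mean offset estimate."""

    levels_uv: np.ndarray
    offsets_db: np.ndarray
    overlap_lo_uv: float
    overlap_hi_uv: float
    region_a: LinearRegion
    region_b: LinearRegion


@dataclass(frozen=True)
class IPGEffectResult:
    """All differential measures for one electrode's condition pair.

    Fields that could not be computed (e.g. ``i50_offset_db`` when a
    sigmoid fit failed) are None rather than raising, so a cohort run
    can keep partial results per electrode.
    """

    subject_id: str
    electrode_id: str
    condition_pair: Tuple[str, str]
    offset_db: Optional[float]
    offset_n_levels: int
    slope_effect_lin: Optional[float]
    slope_effect_log: Optional[float]
    slope_ratio_lin: Optional[float]
    i50_offset_db: Optional[float]
    overlap_lo_uv: Optional[float]
    overlap_hi_uv: Optional[float]


def _check_pair(curve_a: AGFCurve, curve_b: AGFCurve) -> None:
    # identical condition labels are legal (g1 == g2 comparisons), but the
    # pair must refer to one electrode to be meaningful
    if (curve_a.subject_id, curve_a.electrode_id) != (
        curve_b.subject_id,
        curve_b.electrode_id,
    ):
        raise DomainError(
            "IPG effects compare two conditions on one electrode; got "
            f"{curve_a.subject_id}/{curve_a.electrode_id} vs "
            f"{curve_b.subject_id}/{curve_b.electrode_id}"
        )


def ipg_slope_effect(
    curve_a: AGFCurve,
    curve_b: AGFCurve,
    coords: str = "lin_lin",
    frac_lo: float = 0.2,
    frac_hi: float = 0.8,
    fit_a: Optional[SigmoidFit] = None,
    fit_b: Optional[SigmoidFit] = None,
) -> float:
    """Signed slope difference slope(a) - slope(b) in the given coordinates.

    On linear coordinates this measure scales with r*s*n — the textbook
    confound — and on log-log coordinates it degenerates to ~0; both
    behaviours are exactly what makes it a poor neural-health estimate.
    """
    _check_pair(curve_a, curve_b)
    reg_a = extract_linear_region(curve_a, fit_a, frac_lo, frac_hi, coords)
    reg_b = extract_linear_region(curve_b, fit_b, frac_lo, frac_hi, coords)
    return reg_a.slope - reg_b.slope


def ipg_slope_ratio(
    curve_a: AGFCurve,
    curve_b: AGFCurve,
    coords: str = "lin_lin",
    frac_lo: float = 0.2,
    frac_hi: float = 0.8,
    fit_a: Optional[SigmoidFit] = None,
    fit_b: Optional[SigmoidFit] = None,
) -> float:
    """Slope ratio slope(a) / slope(b) in the given coordinates."""
    _check_pair(curve_a, curve_b)
    reg_a = extract_linear_region(curve_a, fit_a, frac_lo, frac_hi, coords)
    reg_b = extract_linear_region(curve_b, fit_b, frac_lo, frac_hi, coords)
    if reg_b.slope == 0:
        raise DomainError("slope ratio undefined: denominator slope is zero")
    return reg_a.slope / reg_b.slope


def _inverse_samples(curve: AGFCurve, region: LinearRegion):
    """(log10 amplitude, dB current) pairs of the linear region, monotone.

    Sorted by amplitude; ties at duplicate amplitudes are broken by
    averaging the corresponding currents, giving a single-valued
    piecewise-linear inverse in (dB current <- log amplitude) space.
    """
    amps = curve.amplitudes[region.indices]
    dbs = curve.currents_db[region.indices]
    if np.any(amps <= 0):
        raise InsufficientRegionError(
            "offset inversion needs strictly positive amplitudes"
        )
    order = np.argsort(amps, kind="stable")
    amps, dbs = amps[order], dbs[order]
    uniq, inv = np.unique(amps, return_inverse=True)
    if uniq.size < 2:
        raise InsufficientRegionError(
            "offset inversion needs at least two distinct amplitudes"
        )
    mean_db = np.zeros(uniq.size)
    np.add.at(mean_db, inv, dbs)
    mean_db /= np.bincount(inv)
    return np.log10(uniq), mean_db


def ipg_offset_effect(
    curve_a: AGFCurve,
    curve_b: AGFCurve,
    frac_lo: float = 0.2,
    frac_hi: float = 0.8,
    n_levels: int = 10,
    min_overlap_frac: float = MIN_OVERLAP_FRAC,
    fit_a: Optional[SigmoidFit] = None,
    fit_b: Optional[SigmoidFit] = None,
) -> Tuple[float, OffsetDiagnostics]:
    """Mean dB current offset between overlapping linear portions.

    Each curve is restricted to its linear region; the amplitude ranges
    are intersected; ``n_levels`` log-spaced output levels are laid over
    the overlap; at each level the required current on each curve is
    read off by piecewise-linear interpolation in (dB current, log
    amplitude) space; and the offset is the mean of
    ``dB(curve_b) - dB(curve_a)`` — short-IPG current minus long-IPG
    current.  The shared output grid makes the result indifferent to
    whether the output axis is thought of as linear or logarithmic.

    Raises :class:`NoOverlapError` when the overlap is empty or spans
    less than ``min_overlap_frac`` of the narrower region's amplitude
    range — the electrode-exclusion rule of the method.
    """
    _check_pair(curve_a, curve_b)
    if n_levels < 2:
        raise DomainError(f"n_levels must be >= 2, got {n_levels}")
    reg_a = extract_linear_region(curve_a, fit_a, frac_lo, frac_hi, "log_log")
    reg_b = extract_linear_region(curve_b, fit_b, frac_lo, frac_hi, "log_log")
    log_amp_a, db_a = _inverse_samples(curve_a, reg_a)
    log_amp_b, db_b = _inverse_samples(curve_b, reg_b)

    lo = max(log_amp_a[0], log_amp_b[0])
    hi = min(log_amp_a[-1], log_amp_b[-1])
    narrower = min(log_amp_a[-1] - log_amp_a[0], log_amp_b[-1] - log_amp_b[0])
    if hi <= lo or (narrower > 0 and (hi - lo) < min_overlap_frac * narrower):
        raise NoOverlapError(
            "linear regions of the two conditions share no usable "
            f"amplitude overlap on {curve_a.subject_id}/{curve_a.electrode_id}"
        )
    levels_log = np.linspace(lo, hi, n_levels)
    db_at_a = np.interp(levels_log, log_amp_a, db_a)
    db_at_b = np.interp(levels_log, log_amp_b, db_b)
    offsets = db_at_b - db_at_a
    diag = OffsetDiagnostics(
        levels_uv=10.0**levels_log,
        offsets_db=offsets,
        overlap_lo_uv=float(10.0**lo),
        overlap_hi_uv=float(10.0**hi),
        region_a=reg_a,
        region_b=reg_b,
    )
    return float(np.mean(offsets)), diag


def i50_offset(fit_a: SigmoidFit, fit_b: SigmoidFit) -> float:
    """Offset between fitted half-max currents, dB: i50(b) - i50(a).

    Same sign convention as :func:`ipg_offset_effect`: positive when the
    long-IPG condition (``fit_a``) reaches half-max at lower current.
    """
    if not (fit_a.converged and fit_b.converged):
        raise InvalidFitError("i50 offset requires two converged sigmoid fits")
    return fit_b.i50_db - fit_a.i50_db


def compute_ipg_effects(
    curve_a: AGFCurve,
    curve_b: AGFCurve,
    frac_lo: float = 0.2,
    frac_hi: float = 0.8,
    n_levels: int = 10,
    fit_a: Optional[SigmoidFit] = None,
    fit_b: Optional[SigmoidFit] = None,
) -> IPGEffectResult:
    """All differential measures for one electrode, tolerating partial failure.

    Slope measures or the i50 offset that cannot be computed are left as
    None; the offset effect failing (no linear region / no overlap)
    propagates, because without it the electrode carries no usable
    result.
    """
    offset_db, diag = ipg_offset_effect(
        curve_a, curve_b, frac_lo, frac_hi, n_levels, fit_a=fit_a, fit_b=fit_b
    )

    def _try(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (InsufficientRegionError, DomainError, InvalidFitError):
            return None

    slope_lin = _try(
        ipg_slope_effect, curve_a, curve_b, "lin_lin", frac_lo, frac_hi, fit_a, fit_b
    )
    slope_log = _try(
        ipg_slope_effect, curve_a, curve_b, "log_log", frac_lo, frac_hi, fit_a, fit_b
    )
    ratio_lin = _try(
        ipg_slope_ratio, curve_a, curve_b, "lin_lin", frac_lo, frac_hi, fit_a, fit_b
    )
    i50 = None
    if fit_a is not None and fit_b is not None:
        i50 = _try(i50_offset, fit_a, fit_b)
    return IPGEffectResult(
        subject_id=curve_a.subject_id,
        electrode_id=curve_a.electrode_id,
        condition_pair=(curve_a.condition.label, curve_b.condition.label),
        offset_db=offset_db,
        offset_n_levels=n_levels,
        slope_effect_lin=slope_lin,
        slope_effect_log=slope_log,
        slope_ratio_lin=ratio_lin,
        i50_offset_db=i50,
        overlap_lo_uv=diag.overlap_lo_uv,
        overlap_hi_uv=diag.overlap_hi_uv,
    )
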