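"""Feature extraction from amplitude growth functions.

Three things are extracted from an :class:`~ecapagf.model.AGFCurve`:

* a Boltzmann sigmoid fit on (dB current, uV amplitude) pairs, yielding
  saturation amplitude ``vmax``, half-max current ``i50_db``, steepness
  and a derived threshold;
* the *linear region* of the curve — the points between configurable
  amplitude fractions of ``vmax`` (default 20-80 %), where slope and
  offset measures are defined — with an ordinary least-squares line in
  one of three coordinate conventions;
* normalised copies of a curve (division by its own maximum or a
  supplied reference), provided because output normalisation is a common
  but subtly hazardous practice in AGF analysis.

Coordinate conventions for slopes:

``lin_lin``   amplitude (uV) vs current (uA)        -> slope in uV/uA
``log_lin``   amplitude (uV) vs current (dB re 1uA) -> slope in uV/dB
``log_log``   amplitude (dB re 1uV) vs current (dB) -> dimensionless slope;
              equals the growth exponent k for power-law data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, InsufficientRegionError, ValidationError
from .model import AGFCurve, sigmoid_amplitude

COORD_CONVENTIONS = ("lin_lin", "log_lin", "log_log")


@dataclass(frozen=True)
class SigmoidFit:
    """Result of fitting the Boltzmann sigmoid to one AGF.

    ``threshold_db`` is the current at 10 % of the fitted ``vmax`` — a
    documented convention of this package (the literature names a
    threshold feature without fixing its level).  When the optimiser
    fails, ``converged`` is False and the parameters are the best-effort
    values (the initial guesses), so downstream code must check the flag.
    """

    vmax: float
    i50_db: float
    slope_param: float
    threshold_db: float
    r_squared: float
    converged: bool

    def __post_init__(self) -> None:
        if not self.vmax > 0:
            raise ValidationError(f"vmax must be > 0, got {self.vmax}")

    def predict(self, currents_db) -> np.ndarray:
        """Fitted amplitudes at the given dB currents."""
        return sigmoid_amplitude(
            currents_db, self.vmax, self.i50_db, self.slope_param
        )


@dataclass(frozen=True)
class LinearRegion:
    """The linear portion of one AGF and its fitted line.

    ``indices`` is the contiguous run of curve points whose amplitudes
    lie within ``[frac_lo, frac_hi] * vmax_used``.  ``vmax_fallback``
    records whether ``vmax_used`` came from a sigmoid fit (False) or,
    for truncated data without a usable fit, from the observed maximum
    amplitude (True).
    """

    indices: np.ndarray
    frac_lo: float
    frac_hi: float
    coords: str
    slope: float
    intercept: float
    vmax_used: float
    vmax_fallback: bool

    @property
    def n_points(self) -> int:
        return int(self.indices.size)


def _initial_guess(x_db: np.ndarray, amps: np.ndarray):
    """Deterministic sigmoid initialisation (no random restarts).

    vmax0 = 1.1 * observed max; i50_0 = interpolated current at half the
    observed max; slope0 = (dB current range) / 4.
    """
    vmax0 = 1.1 * float(np.max(amps))
    half = 0.5 * float(np.max(amps))
    i50_0 = float(np.interp(half, amps, x_db))
    slope0 = max((float(x_db[-1]) - float(x_db[0])) / 4.0, 1e-3)
    return vmax0, i50_0, slope0


def _threshold_from(i50_db: float, slope_param: float) -> float:
    # V = 0.1*vmax  <=>  exp((i50-x)/b) = 9  <=>  x = i50 - b*ln 9
    return i50_db - slope_param * np.log(9.0)


def fit_sigmoid(curve: AGFCurve) -> SigmoidFit:
    """Least-squares Boltzmann fit of one AGF on (dB current, uV) pairs.

    Requires at least 5 points with non-constant amplitudes.  Input
    points are canonically sorted by current before fitting, so the fit
    is invariant to point order.  A failed optimisation returns the
    deterministic initial guesses with ``converged=False`` rather than
    raising, because truncated human-style data routinely defeats the
    fit and the offset pipeline has a documented fallback.
    """
    if len(curve) < 5:
        raise ValidationError(
            f"sigmoid fit needs >= 5 points, got {len(curve)}"
        )
    amps = curve.amplitudes
    if np.ptp(amps) == 0:
        raise ValidationError("sigmoid fit needs non-constant amplitudes")
    x_db = curve.currents_db
    order = np.argsort(x_db)
    x_db, amps = x_db[order], amps[order]

    p0 = _initial_guess(x_db, amps)
    try:
        popt, _ = curve_fit(
            sigmoid_amplitude,
            x_db,
            amps,
            p0=p0,
            bounds=([1e-12, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, ValueError):
        popt, converged = np.asarray(p0), False

    vmax, i50_db, slope_param = (float(v) for v in popt)
    resid = amps - sigmoid_amplitude(x_db, vmax, i50_db, slope_param)
    ss_tot = float(np.sum((amps - amps.mean()) ** 2))
    r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return SigmoidFit(
        vmax=vmax,
        i50_db=i50_db,
        slope_param=slope_param,
        threshold_db=_threshold_from(i50_db, slope_param),
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        converged=converged,
    )


def _region_xy(curve: AGFCurve, idx: np.ndarray, coords: str):
    amps = curve.amplitudes[idx]
    if coords == "lin_lin":
        return curve.currents_uA[idx], amps
    if coords == "log_lin":
        return curve.currents_db[idx], amps
    if coords == "log_log":
        if np.any(amps <= 0):
            raise InsufficientRegionError(
                "log_log coordinates need strictly positive amplitudes"
            )
        return curve.currents_db[idx], 20.0 * np.log10(amps)
    raise ValidationError(
        f"unknown coords {coords!r}; expected one of {COORD_CONVENTIONS}"
    )


def resolve_vmax(
    curve: AGFCurve, fit: Optional[SigmoidFit] = None, vmax: Optional[float] = None
):
    """Saturation amplitude used for region selection, with fallback flag.

    Priority: explicit ``vmax`` argument, then a *converged* sigmoid
    fit, then the observed maximum amplitude (flagged as a fallback —
    the right behaviour for truncated data where the true saturation
    level is never reached).
    """
    if vmax is not None:
        if not vmax > 0:
            raise DomainError(f"vmax must be > 0, got {vmax}")
        return float(vmax), False
    if fit is not None and fit.converged:
        return float(fit.vmax), False
    return float(np.max(curve.amplitudes)), True


def extract_linear_region(
    curve: AGFCurve,
    fit: Optional[SigmoidFit] = None,
    frac_lo: float = 0.2,
    frac_hi: float = 0.8,
    coords: str = "lin_lin",
    vmax: Optional[float] = None,
) -> LinearRegion:
    """Select the 20-80 %-of-maximum region and fit an OLS line in *coords*.

    The selected indices are the contiguous span from the first to the
    last point inside the amplitude band; fewer than 3 surviving points
    raises :class:`InsufficientRegionError`, the signal that this curve
    has no measurable linear region.
    """
    if not (0.0 <= frac_lo < frac_hi <= 1.0):
        raise ValidationError(
            f"need 0 <= frac_lo < frac_hi <= 1, got ({frac_lo}, {frac_hi})"
        )
    vmax_used, fallback = resolve_vmax(curve, fit, vmax)
    amps = curve.amplitudes
    mask = (amps >= frac_lo * vmax_used) & (amps <= frac_hi * vmax_used)
    if not mask.any():
        raise InsufficientRegionError(
            f"no points within [{frac_lo}, {frac_hi}] * vmax for "
            f"{curve.subject_id}/{curve.electrode_id}"
        )
    first, last = np.flatnonzero(mask)[[0, -1]]
    idx = np.arange(first, last + 1)
    if idx.size < 3:
        raise InsufficientRegionError(
            f"only {idx.size} points in linear region of "
            f"{curve.subject_id}/{curve.electrode_id}; need >= 3"
        )
    x, y = _region_xy(curve, idx, coords)
    slope, intercept = np.polyfit(x, y, 1)
    return LinearRegion(
        indices=idx,
        frac_lo=frac_lo,
        frac_hi=frac_hi,
        coords=coords,
        slope=float(slope),
        intercept=float(intercept),
        vmax_used=vmax_used,
        vmax_fallback=fallback,
    )


def normalize_curve(curve: AGFCurve, reference="own_max") -> AGFCurve:
    """Divide amplitudes by a reference value.

    ``reference`` is either the string ``"own_max"`` (divide by the
    curve's own maximum) or a positive number — e.g. a shared subject
    maximum, the practice whose pitfalls motivate keeping slope
    comparisons off normalised linear coordinates.  The amplitude unit
    tag becomes dimensionless.
    """
    if isinstance(reference, str):
        if reference != "own_max":
            raise ValidationError(
                f"reference must be 'own_max' or a number, got {reference!r}"
            )
        ref = float(np.max(curve.amplitudes))
    else:
        ref = float(reference)
    if ref <= 0:
        raise DomainError(f"normalisation reference must be > 0, got {ref}")
    return curve.with_amplitudes(
        curve.amplitudes / ref, amplitude_unit="dimensionless"
    )
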