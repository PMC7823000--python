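"""Generative model of ECAP amplitude growth.

The core model is multiplicative: the ECAP amplitude evoked by a current
``I`` is

    V = r * n * (s * g * I) ** k

where ``r`` collects recording-side factors (recording-electrode position,
impedance), ``n`` is the number of responding neurons, ``s`` collects
stimulating-electrode factors, ``g`` is a gain set by stimulus parameters
such as the interphase gap (IPG), and ``k`` is the exponent converting
effective current at the neurons into neural activity.  ``s`` and ``g``
multiply the current *before* the power law because they scale the
effective current; ``r`` and ``n`` scale the response *after* it.

A population generalisation replaces the single set of factors with
per-neuron values and sums the per-neuron responses:

    V = sum_i r_i * (s_i * g_i * I) ** k_i

Real growth functions saturate, so a Boltzmann sigmoid on the dB-current
axis is also provided, with the gain ``g`` entering as a pure horizontal
dB shift — the property that makes the equal-output current offset between
two conditions a clean readout of the gain ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .errors import DomainError, ValidationError
from .units import SUPPORTED_UNITS, db_re_1uA, to_uA

ArrayLike = Union[float, Sequence[float], np.ndarray]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusCondition:
    """One pulse-parameter setting and its effective current gain.

    Parameters
    ----------
    label:
        Free-text condition name, e.g. ``"IPG58"``.
    ipg_us:
        Interphase gap in microseconds (> 0).
    phase_duration_us:
        Phase duration in microseconds (> 0).
    g:
        Dimensionless effective-current gain of this condition (> 0).
        Longer interphase gaps increase neural excitability and hence
        ``g``; the mapping from IPG to ``g`` is an empirical input, not
        something this package derives.
    """

    label: str
    ipg_us: float
    phase_duration_us: float
    g: float

    def __post_init__(self) -> None:
        if not self.ipg_us > 0:
            raise ValidationError(f"ipg_us must be > 0, got {self.ipg_us}")
        if not self.phase_duration_us > 0:
            raise ValidationError(
                f"phase_duration_us must be > 0, got {self.phase_duration_us}"
            )
        if not self.g > 0:
            raise ValidationError(f"gain g must be > 0, got {self.g}")


@dataclass(frozen=True)
class PopulationFactors:
    """Neural and non-neural multiplicative factors of the growth model.

    Scalar fields give the homogeneous model; supplying length-``n``
    vectors for ``s``, ``k``, ``r`` or ``g_scale`` gives the per-neuron
    population sum.  By default the recording factor ``r`` is applied
    once to the population sum — the recording electrode is common to
    all fibres — but a length-``n`` ``r`` is accepted for the strict
    per-neuron form.

    Parameters
    ----------
    r:
        Recording-side factor(s), dimensionless, > 0.
    n:
        Number of neurons, positive integer.
    s:
        Stimulating-side factor(s), dimensionless, > 0.
    k:
        Growth exponent(s), > 0.
    g_scale:
        Optional per-neuron multiplier on the condition gain, length
        ``n``; defaults to all ones (every neuron sees the same gain).
    """

    r: ArrayLike = 1.0
    n: int = 1
    s: ArrayLike = 1.0
    k: ArrayLike = 1.0
    g_scale: Optional[ArrayLike] = None

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValidationError(f"n must be a positive integer, got {self.n}")
        for name in ("r", "s", "k"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.ndim != 1 or arr.size not in (1, self.n):
                raise ValidationError(
                    f"{name} must be scalar or length-{self.n}, got shape {arr.shape}"
                )
            if not np.all(arr > 0):
                raise ValidationError(f"all {name} values must be > 0")
        if self.g_scale is not None:
            gs = np.asarray(self.g_scale, dtype=float)
            if gs.shape != (self.n,):
                raise ValidationError(
                    f"g_scale must have length n={self.n}, got shape {gs.shape}"
                )
            if not np.all(gs > 0):
                raise ValidationError("all g_scale values must be > 0")

    @property
    def is_homogeneous(self) -> bool:
        """True when every neuron shares identical factors."""
        if self.g_scale is not None and np.ptp(np.asarray(self.g_scale)) > 0:
            return False
        return all(
            np.asarray(getattr(self, name), dtype=float).size == 1
            or np.ptp(np.asarray(getattr(self, name), dtype=float)) == 0
            for name in ("r", "s", "k")
        )

    def _per_neuron(self, name: str) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
        return np.broadcast_to(arr, (self.n,)) if arr.size == 1 else arr


@dataclass(frozen=True)
class SaturatingShape:
    """Parameters of the Boltzmann sigmoid growth shape.

    ``V(I_dB) = vmax / (1 + exp((i50_db - I_dB) / slope_param))``

    Parameters
    ----------
    vmax:
        Saturation amplitude in microvolts (> 0).
    i50_db:
        Current at half-maximal amplitude, dB re 1 uA.
    slope_param:
        Steepness of the sigmoid in dB (larger = shallower); > 0.
    """

    vmax: float
    i50_db: float
    slope_param: float

    def __post_init__(self) -> None:
        if not self.vmax > 0:
            raise ValidationError(f"vmax must be > 0, got {self.vmax}")
        if not self.slope_param > 0:
            raise ValidationError(
                f"slope_param must be > 0, got {self.slope_param}"
            )


@dataclass(frozen=True)
class AGFCurve:
    """One amplitude growth function: ECAP amplitude vs stimulus current.

    Invariants: equal lengths, strictly increasing currents,
    non-negative amplitudes.
    """

    subject_id: str
    electrode_id: str
    condition: StimulusCondition
    currents: np.ndarray
    amplitudes: np.ndarray
    current_unit: str = "uA"
    amplitude_unit: str = "uV"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "currents", np.asarray(self.currents, dtype=float)
        )
        object.__setattr__(
            self, "amplitudes", np.asarray(self.amplitudes, dtype=float)
        )
        if self.current_unit not in SUPPORTED_UNITS:
            raise ValidationError(
                f"unknown current unit {self.current_unit!r}; "
                f"expected one of {SUPPORTED_UNITS}"
            )
        if self.currents.ndim != 1 or self.currents.shape != self.amplitudes.shape:
            raise ValidationError(
                "currents and amplitudes must be 1-D arrays of equal length"
            )
        if self.currents.size and not np.all(np.diff(self.currents) > 0):
            raise ValidationError("currents must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise ValidationError("amplitudes must be non-negative")

    def __len__(self) -> int:
        return int(self.currents.size)

    @property
    def currents_uA(self) -> np.ndarray:
        """Currents converted to microamperes."""
        return to_uA(self.currents, self.current_unit)

    @property
    def currents_db(self) -> np.ndarray:
        """Currents converted to dB re 1 uA."""
        return db_re_1uA(self.currents_uA)

    def with_amplitudes(self, amplitudes: np.ndarray, **meta) -> "AGFCurve":
        """Copy of the curve with replaced amplitudes (and optional metadata)."""
        return replace(self, amplitudes=np.asarray(amplitudes, float), **meta)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def simulate_amplitude(
    current_uA: float,
    factors: PopulationFactors,
    condition: StimulusCondition,
) -> float:
    """ECAP amplitude (uV) of the multiplicative growth model at one current.

    Homogeneous factors give exactly ``r * n * (s * g * I) ** k``; per-neuron
    factors give the population sum, with a scalar ``r`` applied once to the
    sum (recording factor common to all fibres) and a vector ``r`` applied
    per neuron.
    """
    if not np.isscalar(current_uA) or not current_uA > 0:
        raise DomainError(f"current must be a positive scalar, got {current_uA}")
    return float(
        _population_response(np.asarray([current_uA], float), factors, condition)[0]
    )


def _population_response(
    currents_uA: np.ndarray,
    factors: PopulationFactors,
    condition: StimulusCondition,
) -> np.ndarray:
    g = condition.g
    r_arr = np.atleast_1d(np.asarray(factors.r, dtype=float))
    if factors.is_homogeneous and r_arr.size == 1:
        r = float(r_arr[0])
        s = float(np.atleast_1d(np.asarray(factors.s, float))[0])
        k = float(np.atleast_1d(np.asarray(factors.k, float))[0])
        gs = 1.0 if factors.g_scale is None else float(np.asarray(factors.g_scale)[0])
        return r * factors.n * (s * g * gs * currents_uA) ** k

    s = factors._per_neuron("s")
    k = factors._per_neuron("k")
    gs = (
        np.ones(factors.n)
        if factors.g_scale is None
        else np.asarray(factors.g_scale, dtype=float)
    )
    # (n_currents, n_neurons) effective drive, then per-neuron power law
    drive = np.outer(currents_uA, s * g * gs)
    per_neuron = drive ** k[np.newaxis, :]
    if r_arr.size == 1:
        return float(r_arr[0]) * per_neuron.sum(axis=1)
    return (per_neuron * r_arr[np.newaxis, :]).sum(axis=1)


def simulate_curve(
    currents,
    factors: PopulationFactors,
    condition: StimulusCondition,
    *,
    subject_id: str = "sim",
    electrode_id: str = "E1",
    current_unit: str = "uA",
) -> AGFCurve:
    """Simulate a noiseless power-law AGF over a strictly increasing grid.

    ``currents`` are interpreted in ``current_unit`` and stored unchanged;
    amplitudes are computed from the microampere values.  The model is
    monotone, so the resulting amplitudes are strictly increasing.
    """
    currents = np.asarray(currents, dtype=float)
    if currents.ndim != 1 or currents.size == 0:
        raise ValidationError("currents must be a non-empty 1-D sequence")
    if not np.all(np.diff(currents) > 0):
        raise ValidationError("currents must be strictly increasing")
    i_uA = to_uA(currents, current_unit)
    if not np.all(i_uA > 0):
        raise DomainError("all currents must be positive")
    amplitudes = _population_response(i_uA, factors, condition)
    return AGFCurve(
        subject_id=subject_id,
        electrode_id=electrode_id,
        condition=condition,
        currents=currents,
        amplitudes=amplitudes,
        current_unit=current_unit,
    )


def sigmoid_amplitude(
    currents_db,
    vmax: float,
    i50_db: float,
    slope_param: float,
) -> np.ndarray:
    """Boltzmann sigmoid on the dB-current axis (shared with the fitter)."""
    x = np.asarray(currents_db, dtype=float)
    return vmax / (1.0 + np.exp((i50_db - x) / slope_param))


def simulate_sigmoid_curve(
    currents,
    shape: SaturatingShape,
    condition: StimulusCondition,
    factors: Optional[PopulationFactors] = None,
    *,
    subject_id: str = "sim",
    electrode_id: str = "E1",
    current_unit: str = "uA",
) -> AGFCurve:
    """Simulate a saturating AGF.

    The stimulating-side factors ``s`` and ``g`` shift the sigmoid left
    on the dB axis by ``20*log10(g*s)`` without changing its shape; the
    recording factor ``r`` scales the output, so the asymptote is
    ``r * vmax``.  Requires scalar ``r`` and ``s`` (the saturating shape
    already summarises the population).
    """
    currents = np.asarray(currents, dtype=float)
    if currents.ndim != 1 or not np.all(np.diff(currents) > 0):
        raise ValidationError("currents must be strictly increasing")
    factors = factors or PopulationFactors()
    r_arr = np.asarray(factors.r, dtype=float)
    s_arr = np.asarray(factors.s, dtype=float)
    if r_arr.size != 1 or s_arr.size != 1:
        raise ValidationError(
            "sigmoid simulation requires scalar r and s factors"
        )
    i_uA = to_uA(currents, current_unit)
    if not np.all(i_uA > 0):
        raise DomainError("all currents must be positive")
    x_db = db_re_1uA(i_uA) + 20.0 * np.log10(condition.g * float(s_arr))
    amplitudes = float(r_arr) * sigmoid_amplitude(
        x_db, shape.vmax, shape.i50_db, shape.slope_param
    )
    return AGFCurve(
        subject_id=subject_id,
        electrode_id=electrode_id,
        condition=condition,
        currents=currents,
        amplitudes=amplitudes,
        current_unit=current_unit,
    )


def add_noise(
    curve: AGFCurve,
    sigma_uv: float,
    noise_floor_uv: float = 0.0,
    *,
    seed: int,
) -> AGFCurve:
    """Additive zero-mean Gaussian measurement noise with a hard floor.

    Amplitudes below ``noise_floor_uv`` after noising are set to the
    floor, emulating the recording system's noise floor.  Deterministic
    given ``seed``; ``sigma_uv = 0`` returns an identical curve.
    """
    if sigma_uv < 0 or noise_floor_uv < 0:
        raise DomainError("sigma_uv and noise_floor_uv must be >= 0")
    if sigma_uv == 0 and noise_floor_uv == 0:
        return curve
    rng = np.random.default_rng(seed)
    noisy = curve.amplitudes + rng.normal(0.0, sigma_uv, size=len(curve))
    noisy = np.where(noisy < noise_floor_uv, noise_floor_uv, noisy)
    return curve.with_amplitudes(noisy)


def gain_offset_db(g_long: float, g_short: float) -> float:
    """Theoretical equal-output current offset for a gain pair, in dB.

    At equal output the power-law model gives
    ``log I_short - log I_long = log g_long - log g_short`` independently
    of r, s, n and k; in the 20*log10 convention this is
    ``20*log10(g_long / g_short)``.
    """
    if not (g_long > 0 and g_short > 0):
        raise DomainError("gains must be > 0")
    return 20.0 * np.log10(g_long / g_short)
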