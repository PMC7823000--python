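"""Stimulus-current unit conversions.

Three current units circulate in ECAP work:

``uA``
    Microamperes, the physical unit.
``dB_re_1uA``
    Decibels re 1 microampere, amplitude-of-current convention:
    ``dB = 20 * log10(I_uA)``.  All horizontal-offset measures in this
    package are expressed on this scale.
``CL``
    Cochlear-device "current level" steps, a logarithmic device unit.
    The conversion used here is the widely documented device convention
    ``I_uA = 17.5 * 100 ** (CL / 255)``; it is a convention of this
    package, not a manufacturer guarantee.
"""

from __future__ import annotations

import numpy as np

SUPPORTED_UNITS = ("uA", "dB_re_1uA", "CL")

#: Reference current of the CL scale at CL = 0, in microamperes.
CL_REF_UA = 17.5
#: Number of CL steps per factor-of-100 change in current.
CL_STEPS_PER_100X = 255.0


def _check_unit(unit: str) -> None:
    if unit not in SUPPORTED_UNITS:
        raise ValueError(
            f"unsupported current unit {unit!r}; expected one of {SUPPORTED_UNITS}"
        )


def to_uA(values, unit: str):
    """Convert current values in *unit* to microamperes."""
    _check_unit(unit)
    values = np.asarray(values, dtype=float)
    if unit == "uA":
        return values
    if unit == "dB_re_1uA":
        return 10.0 ** (values / 20.0)
    return CL_REF_UA * 100.0 ** (values / CL_STEPS_PER_100X)


def from_uA(values, unit: str):
    """Convert current values in microamperes to *unit*."""
    _check_unit(unit)
    values = np.asarray(values, dtype=float)
    if unit == "uA":
        return values
    if unit == "dB_re_1uA":
        return 20.0 * np.log10(values)
    return CL_STEPS_PER_100X * np.log10(values / CL_REF_UA) / 2.0


def convert_current(value, from_unit: str, to_unit: str):
    """Convert a current value (scalar or array) between supported units.

    Round trips are exact to floating-point precision because every
    conversion passes through microamperes with monotone maps.
    """
    _check_unit(from_unit)
    _check_unit(to_unit)
    if from_unit == to_unit:
        return np.asarray(value, dtype=float)
    return from_uA(to_uA(value, from_unit), to_unit)


def db_re_1uA(current_uA):
    """Shorthand for the dB re 1 uA transform, 20*log10(I)."""
    return 20.0 * np.log10(np.asarray(current_uA, dtype=float))
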