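"""Shared fixtures: canonical condition pairs and curve builders."""

import numpy as np
import pytest

from ecapagf import (
    PopulationFactors,
    SaturatingShape,
    StimulusCondition,
    simulate_curve,
    simulate_sigmoid_curve,
)


def make_condition_pair(g_long=2.0, g_short=1.0):
    """A long/short IPG condition pair differing only in gain."""
    long = StimulusCondition("IPG58", ipg_us=58.0, phase_duration_us=104.0, g=g_long)
    short = StimulusCondition("IPG8", ipg_us=8.0, phase_duration_us=104.0, g=g_short)
    return long, short


def make_power_pair(
    g_long=2.0,
    g_short=1.0,
    r=1.0,
    s=1.0,
    n=1,
    k=1.0,
    currents=None,
    current_unit="uA",
):
    """Two noiseless power-law AGFs on one electrode, differing only in g."""
    if currents is None:
        currents = np.linspace(1.0, 10.0, 30)
    cond_long, cond_short = make_condition_pair(g_long, g_short)
    factors = PopulationFactors(r=r, n=n, s=s, k=k)
    kwargs = dict(subject_id="S1", electrode_id="E1", current_unit=current_unit)
    return (
        simulate_curve(currents, factors, cond_long, **kwargs),
        simulate_curve(currents, factors, cond_short, **kwargs),
    )


def make_sigmoid_pair(
    g_long=2.0,
    g_short=1.0,
    vmax=500.0,
    i50_db=40.0,
    slope_param=6.0,
    r=1.0,
    s=1.0,
    span_db=18.0,
    n_points=31,
):
    """Two noiseless saturating AGFs on a shared dB grid, differing only in g."""
    cond_long, cond_short = make_condition_pair(g_long, g_short)
    shape = SaturatingShape(vmax=vmax, i50_db=i50_db, slope_param=slope_param)
    factors = PopulationFactors(r=r, s=s)
    shift = 20.0 * np.log10(max(g_long, g_short) * s)
    grid = np.linspace(i50_db - span_db - shift, i50_db + span_db, n_points)
    kwargs = dict(subject_id="S1", electrode_id="E1", current_unit="dB_re_1uA")
    return (
        simulate_sigmoid_curve(grid, shape, cond_long, factors, **kwargs),
        simulate_sigmoid_curve(grid, shape, cond_short, factors, **kwargs),
    )


@pytest.fixture
def power_pair():
    return make_power_pair()


@pytest.fixture
def sigmoid_pair():
    return make_sigmoid_pair()
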