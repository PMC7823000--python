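"""Tests for the differential IPG-effect measures.

The anchor facts: on linear coordinates the slope effect scales with the
recording factor (doubling r doubles it), on log-log coordinates it
degenerates to 0 (ratio 1), and the equal-output offset equals
20*log10(g_long/g_short) dB independently of every non-neural factor.
"""

import numpy as np
import pytest
from scipy.optimize import brentq

from ecapagf import (
    DomainError,
    InvalidFitError,
    NoOverlapError,
    PopulationFactors,
    fit_sigmoid,
    gain_offset_db,
    i50_offset,
    ipg_offset_effect,
    ipg_slope_effect,
    ipg_slope_ratio,
    normalize_curve,
    simulate_curve,
)
from conftest import make_condition_pair, make_power_pair, make_sigmoid_pair

DOUBLING_DB = 20.0 * np.log10(2.0)  # 6.0206 dB


class TestSlopeEffect:
    def test_worked_example_baseline_electrode(self):
        """g doubling on the unit electrode: linear slopes go 1 -> 2."""
        a, b = make_power_pair(g_long=2.0, g_short=1.0, r=1.0)
        assert ipg_slope_effect(a, b, "lin_lin") == pytest.approx(1.0, abs=1e-9)

    def test_worked_example_r_doubled_electrode(self):
        """Same gain change with r doubled: slopes go 2 -> 4, effect 2."""
        a, b = make_power_pair(g_long=2.0, g_short=1.0, r=2.0)
        assert ipg_slope_effect(a, b, "lin_lin") == pytest.approx(2.0, abs=1e-9)

    def test_identical_conditions_give_zero(self):
        a, b = make_power_pair(g_long=1.5, g_short=1.5, r=2.0, k=1.3)
        for coords in ("lin_lin", "log_lin", "log_log"):
            assert ipg_slope_effect(a, b, coords) == pytest.approx(0.0, abs=1e-9)

    def test_log_log_slope_effect_degenerates_to_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a, b = make_power_pair(
                g_long=rng.uniform(1.1, 3), g_short=1.0,
                r=rng.uniform(0.3, 3), s=rng.uniform(0.3, 3),
                n=int(rng.integers(1, 30)), k=rng.uniform(0.5, 2),
            )
            assert ipg_slope_effect(a, b, "log_log") == pytest.approx(0.0, abs=1e-9)

    def test_ratio_reflects_gain_independent_of_r(self):
        for r in (1.0, 2.0, 7.0):
            a, b = make_power_pair(g_long=2.0, g_short=1.0, r=r)
            assert ipg_slope_ratio(a, b, "lin_lin") == pytest.approx(2.0, rel=1e-9)

    def test_ratio_is_one_for_equal_gain_and_log_log(self):
        a, b = make_power_pair(g_long=1.5, g_short=1.5)
        assert ipg_slope_ratio(a, b, "lin_lin") == pytest.approx(1.0, rel=1e-9)
        a, b = make_power_pair(g_long=2.0, g_short=1.0, k=1.7)
        assert ipg_slope_ratio(a, b, "log_log") == pytest.approx(1.0, rel=1e-9)


class TestOffsetEffect:
    def test_gain_doubling_gives_six_db_any_factors(self):
        # k capped below 2: the 20-80 % amplitude bands of two curves a
        # factor 2^k apart stop overlapping at k = 2 (band width is x4)
        rng = np.random.default_rng(17)
        for _ in range(10):
            a, b = make_power_pair(
                g_long=2.0, g_short=1.0,
                r=rng.uniform(0.3, 3), s=rng.uniform(0.3, 3),
                n=int(rng.integers(1, 30)), k=rng.uniform(0.5, 1.6),
            )
            offset, _ = ipg_offset_effect(a, b)
            assert offset == pytest.approx(DOUBLING_DB, abs=1e-9)

    def test_equal_gain_gives_zero(self):
        a, b = make_power_pair(g_long=1.5, g_short=1.5, r=2.0)
        offset, _ = ipg_offset_effect(a, b)
        assert offset == pytest.approx(0.0, abs=1e-9)

    def test_recording_factor_cancels_exactly(self):
        a1, b1 = make_power_pair(r=1.0, k=1.4)
        a2, b2 = make_power_pair(r=10.0, k=1.4)
        off1, _ = ipg_offset_effect(a1, b1)
        off2, _ = ipg_offset_effect(a2, b2)
        assert abs(off1 - off2) < 1e-9

    def test_antisymmetry(self, power_pair):
        a, b = power_pair
        off_ab, _ = ipg_offset_effect(a, b)
        off_ba, _ = ipg_offset_effect(b, a)
        assert off_ab == pytest.approx(-off_ba, abs=1e-12)
        assert ipg_slope_effect(a, b) == pytest.approx(
            -ipg_slope_effect(b, a), abs=1e-12
        )
        assert ipg_slope_ratio(a, b) == pytest.approx(
            1.0 / ipg_slope_ratio(b, a), rel=1e-12
        )

    def test_unit_invariance_uA_vs_dB(self):
        currents = np.linspace(1.0, 10.0, 30)
        a_uA, b_uA = make_power_pair(currents=currents, k=1.2)
        a_db, b_db = make_power_pair(
            currents=20 * np.log10(currents), current_unit="dB_re_1uA", k=1.2
        )
        off_uA, _ = ipg_offset_effect(a_uA, b_uA)
        off_db, _ = ipg_offset_effect(a_db, b_db)
        assert off_uA == pytest.approx(off_db, abs=1e-9)

    def test_shared_normalisation_leaves_offset_unchanged(self, power_pair):
        a, b = power_pair
        ref = max(a.amplitudes.max(), b.amplitudes.max())
        off_raw, _ = ipg_offset_effect(a, b)
        off_norm, _ = ipg_offset_effect(
            normalize_curve(a, ref), normalize_curve(b, ref)
        )
        assert off_norm == pytest.approx(off_raw, abs=1e-9)

    def test_own_max_normalisation_on_saturated_curves(self):
        """With both curves sampled deep into saturation, own-max
        normalisation is (nearly) the same vertical rescale on both and
        the offset survives."""
        a, b = make_sigmoid_pair(span_db=40.0, n_points=81)
        off_raw, _ = ipg_offset_effect(a, b)
        off_norm, _ = ipg_offset_effect(normalize_curve(a), normalize_curve(b))
        assert off_norm == pytest.approx(off_raw, abs=0.02)

    def test_level_grid_spacing_immaterial(self, power_pair):
        """With a shared output grid the log vs linear spacing of the
        sampled levels does not change the mean offset (exactly so for
        curves that are pure horizontal shifts of each other)."""
        a, b = power_pair
        off_log, diag = ipg_offset_effect(a, b, n_levels=10)
        # manual linear-amplitude grid over the same overlap
        levels = np.linspace(diag.overlap_lo_uv, diag.overlap_hi_uv, 10)
        ia = np.interp(np.log10(levels), np.log10(a.amplitudes), a.currents_db)
        ib = np.interp(np.log10(levels), np.log10(b.amplitudes), b.currents_db)
        assert off_log == pytest.approx(np.mean(ib - ia), abs=1e-9)

    def test_no_overlap_raises(self):
        """A huge gain ratio pushes the linear regions apart in current but
        they still overlap in amplitude; disjoint amplitude ranges instead
        require curves whose region amplitude bands don't intersect."""
        a, _ = make_power_pair(r=1.0)
        _, b = make_power_pair(r=1000.0)  # amplitudes 3 decades apart
        with pytest.raises(NoOverlapError):
            ipg_offset_effect(a, b)

    def test_heterogeneous_population_matches_brute_force(self):
        """Per-neuron factor draws with a common gain ratio: the offset
        equals 20*log10(ratio) and agrees with brute-force numerical
        inversion of the two continuous population curves."""
        rng = np.random.default_rng(23)
        ratio = 1.5
        n = 12
        s = rng.uniform(0.5, 2.0, n)
        k = rng.uniform(0.7, 1.8, n)
        factors = PopulationFactors(r=1.7, n=n, s=s, k=k)
        cond_long, cond_short = make_condition_pair(ratio, 1.0)
        currents = np.geomspace(0.5, 30.0, 60)
        a = simulate_curve(currents, factors, cond_long)
        b = simulate_curve(currents, factors, cond_short)
        offset, diag = ipg_offset_effect(a, b)
        assert offset == pytest.approx(20 * np.log10(ratio), abs=0.05)

        # independent oracle: root-find the continuous model at each level
        def current_at(cond, level):
            def f(log_i):
                cur = simulate_curve(
                    np.array([10.0**log_i]), factors, cond
                )
                return cur.amplitudes[0] - level

            return brentq(f, np.log10(0.05), np.log10(300.0), xtol=1e-12)

        brute = np.mean(
            [
                20.0 * (current_at(cond_short, lv) - current_at(cond_long, lv))
                for lv in diag.levels_uv
            ]
        )
        assert offset == pytest.approx(brute, abs=0.05)

    def test_confound_invariance_headline(self):
        """Across 200 random non-neural draws with a fixed gain ratio the
        offset is constant to < 1e-6 dB while the linear slope effect
        spreads, and spreads more when the r,s,n dispersion grows."""
        rng = np.random.default_rng(99)

        def spread_of(scale):
            offsets, slopes = [], []
            for _ in range(200):
                a, b = make_power_pair(
                    g_long=1.5, g_short=1.0,
                    r=float(np.exp(rng.normal(0, scale))),
                    s=float(np.exp(rng.normal(0, scale / 2))),
                    n=int(rng.integers(1, 30)),
                    k=float(rng.uniform(0.6, 1.8)),
                )
                off, _ = ipg_offset_effect(a, b)
                offsets.append(off)
                slopes.append(ipg_slope_effect(a, b, "lin_lin"))
            return np.std(offsets), np.std(slopes)

        off_sd_small, slope_sd_small = spread_of(0.3)
        off_sd_large, slope_sd_large = spread_of(0.8)
        assert off_sd_small < 1e-6 and off_sd_large < 1e-6
        assert slope_sd_small > 0
        assert slope_sd_large > slope_sd_small


class TestI50Offset:
    def test_identical_fits_give_zero(self, sigmoid_pair):
        fit = fit_sigmoid(sigmoid_pair[1])
        assert i50_offset(fit, fit) == 0.0

    def test_pure_translation_recovered(self):
        a, b = make_sigmoid_pair(g_long=10 ** (3.0 / 20.0), g_short=1.0)
        fit_a, fit_b = fit_sigmoid(a), fit_sigmoid(b)
        assert i50_offset(fit_a, fit_b) == pytest.approx(3.0, abs=1e-6)

    def test_matches_offset_effect_on_sigmoid_data(self):
        a, b = make_sigmoid_pair(g_long=1.6, n_points=61)
        fit_a, fit_b = fit_sigmoid(a), fit_sigmoid(b)
        offset, _ = ipg_offset_effect(a, b, fit_a=fit_a, fit_b=fit_b)
        assert i50_offset(fit_a, fit_b) == pytest.approx(offset, abs=0.01)

    def test_unconverged_fit_rejected(self, sigmoid_pair):
        from dataclasses import replace

        fit = fit_sigmoid(sigmoid_pair[0])
        broken = replace(fit, converged=False)
        with pytest.raises(InvalidFitError):
            i50_offset(broken, fit)


def test_gain_offset_helper_matches_convention():
    assert gain_offset_db(2.0, 1.0) == pytest.approx(DOUBLING_DB, rel=1e-12)
    with pytest.raises(DomainError):
        gain_offset_db(-1.0, 1.0)
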