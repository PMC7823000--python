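# ecapagf

Analysis of ECAP amplitude growth functions (AGFs) for cochlear-implant
neural-health estimation: the differential effects of the interphase gap
(IPG), and the question of which of them actually isolates neural
factors from electrode confounds.

## The problem

The electrically evoked compound action potential (ECAP) is the summed
auditory-nerve response to an electrical pulse, recorded through the
implant itself. Its amplitude growth function — amplitude vs stimulus
current — changes when the IPG of the biphasic pulse is lengthened, and
that change has been used to estimate the health of the local neural
population. But AGFs are also shaped by thoroughly non-neural factors:
recording-electrode position and impedance (*r*), stimulating-electrode
coupling (*s*), and the number of surviving neurons (*n*). Under a
multiplicative growth model

    V = r · n · (s · g · I)^k

where *g* is the IPG-dependent gain and *k* the current-to-activity
exponent, the popular candidate measures behave very differently:

* **IPG slope effect, linear coordinates**: dV₁/dI − dV₂/dI =
  r·s·n·(g₁−g₂) — contaminated by every non-neural factor;
* **IPG slope effect, log-log coordinates**: slopes all equal *k*, so the
  difference is 0 and the ratio 1 — degenerate;
* **IPG offset effect**: the horizontal dB-current shift between the
  linear portions of the two AGFs at equal output,
  log I₂ − log I₁ = log g₁ − log g₂ — independent of r, s, n **and** k,
  a clean readout of the gain factor and hence of neural health.

`ecapagf` implements the generative model (homogeneous and per-neuron
population forms, plus a saturating Boltzmann variant), sigmoid fitting
and linear-region isolation, the complete family of differential
measures, a synthetic-cohort harness that demonstrates the confounding
argument quantitatively, and the supporting statistics (Pearson /
Spearman, Fisher r-to-z comparison, paired slope tests).

## Worked example

Two electrodes with identical neural state, one with a doubled recording
factor; the IPG doubles the gain on both:

```python
import numpy as np
from ecapagf import (PopulationFactors, StimulusCondition, simulate_curve,
                     ipg_slope_effect, ipg_offset_effect)

short = StimulusCondition("IPG8",  ipg_us=8,  phase_duration_us=104, g=1.0)
long_ = StimulusCondition("IPG58", ipg_us=58, phase_duration_us=104, g=2.0)
currents = np.linspace(1, 10, 30)
for r in (1.0, 2.0):
    f = PopulationFactors(r=r)
    a = simulate_curve(currents, f, long_)
    b = simulate_curve(currents, f, short)
    off, _ = ipg_offset_effect(a, b)
    print(f"r={r:.0f}: slope effect (lin) = {ipg_slope_effect(a, b, 'lin_lin'):.3f}, "
          f"offset = {off:.3f} dB")
```

```
r=1: slope effect (lin) = 1.000, offset = 6.021 dB
r=2: slope effect (lin) = 2.000, offset = 6.021 dB
```

The linear slope effect doubles with the recording factor even though
nothing neural changed; the offset stays at 20·log₁₀(2) = 6.021 dB — the
gain ratio in dB — on both electrodes.

The same contrast at cohort scale (10 subjects × 8 electrodes, 2 %
amplitude noise, log-normal non-neural spreads):

```python
from ecapagf import CohortConfig, generate_cohort, evaluate_estimators

summary = evaluate_estimators(generate_cohort(CohortConfig(seed=1)))
```

```
         offset_db vs true gain change: r = 0.974
  slope_effect_lin vs true gain change: r = 0.542
  slope_effect_log vs true gain change: r = -0.058
   slope_ratio_lin vs true gain change: r = 0.580
     i50_offset_db vs true gain change: r = 0.901
offset median |error| = 0.165 dB
```

The offset recovers the planted gain changes almost perfectly; the
linear slope effect is diluted by electrode confounds, and the log-log
slope effect carries no signal at all.

## Command line

```
ecapagf simulate --seed 3 --out agf.csv          # synthetic 2-condition file
ecapagf fit agf.csv --out fits.csv               # sigmoid features per curve
ecapagf offset agf.csv --out offsets.csv         # per-electrode dB offsets
ecapagf report agf.csv --out report.csv          # all measures + exclusions
ecapagf cohort --seed 2 --out run                # cohort + estimator summary
```

Input is a generic long-format CSV (`subject_id, electrode_id,
condition_label, ipg_us, phase_duration_us, current_value, current_unit,
amplitude_uv`), one current unit per file (μA, dB re 1 μA, or Cochlear
CL steps). Electrodes whose curves have no usable linear region or no
amplitude overlap are excluded with logged reasons.

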