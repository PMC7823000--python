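# Methods

## The growth model

The package's generative model treats the ECAP amplitude evoked by a
biphasic pulse of current *I* (μA) as a product of stimulating-side and
recording-side factors:

    V = r · n · (s · g · I)^k

* **r** — recording-electrode factor (position, impedance, orientation).
  Scales the recorded voltage after the neural response exists, so it is
  *not* raised to the power k.
* **n** — number of responding neurons (neural survival).
* **s** — stimulating-electrode factor; scales the effective current at
  the neurons, hence sits inside the power law.
* **g** — stimulus gain set by pulse parameters, chiefly the interphase
  gap (IPG). Longer IPGs allow more charge integration at the membrane
  and act as a proportional increase in effective current. g is an
  *input* to the model; no IPG→g mapping is shipped because that mapping
  is an empirical property of the stimulated tissue — indeed its
  dependence on membrane state is exactly what makes the gain a
  neural-health readout.
* **k** — exponent converting effective current to neural activity,
  shaped by the fibre threshold distribution.

The multiplicative structure encodes standard electrode physics:
electrode–modiolus distance changes current reaching each fibre (and
voltage reaching the recording contact) proportionally.

A population generalisation assigns each neuron its own factors and sums
the per-neuron responses, V = Σᵢ rᵢ·(sᵢ·gᵢ·I)^kᵢ. By default the
implementation applies a scalar r once to the population sum — the
recording electrode is common to all fibres — and accepts a length-n r
for the strict per-neuron form.

### Consequences the package operationalises

With two conditions on one electrode differing only in g (g₁ long IPG,
g₂ short):

* **Linear slope difference** (k = 1): dV₁/dI − dV₂/dI = r·s·n·(g₁−g₂).
  The "IPG slope effect" on linear coordinates inherits every non-neural
  factor multiplicatively; an electrode with doubled r shows a doubled
  effect at identical neural state.
* **Log-log slopes**: d(log V)/d(log I) = k for every condition, so the
  slope difference degenerates to 0 and the ratio to 1 — nothing neural
  survives in the statistic.
* **Equal-output current offset**: log I₂ − log I₁ = log g₁ − log g₂,
  independent of r, s, n *and* k. On the 20·log₁₀ (dB re 1 μA)
  convention the offset is 20·log₁₀(g₁/g₂) dB. This is the quantity the
  package recommends and centres on.

For heterogeneous populations the offset is exact whenever all neurons
share the same gain *ratio* between conditions (the two curves are then
exact horizontal translations of each other); with per-neuron ratios the
offset is approximate and should be read as an effective average.

## Saturating curves and feature extraction

Real growth functions are shallow near threshold and saturate. The
saturating model is a Boltzmann sigmoid on the dB-current axis,

    V(x) = r · Vmax / (1 + exp((I₅₀ − (x + 20·log₁₀(g·s))) / β)),

so g and s enter as a pure horizontal dB shift and r scales the output —
the same separation of roles as in the power-law model. β (dB) sets
steepness; the low-level tail behaves like a power law with exponent
k = 20/(β·ln 10), which is how the cohort simulator maps a drawn k to a
sigmoid shape.

`fit_sigmoid` estimates (Vmax, I₅₀, β) by bounded trust-region least
squares with deterministic initialisation (Vmax₀ = 1.1·max V; I₅₀₀ =
interpolated half-max current; β₀ = dB-range/4; no random restarts).
Threshold is *defined* as the current at 10 % of fitted Vmax — the
literature names a threshold feature without fixing its level, so the
constant is explicit here. A failed optimisation returns the initial
guesses flagged `converged=False`; downstream region selection then
falls back to the observed maximum amplitude (flagged), which is the
right behaviour for truncated human-style data that never reaches
saturation.

**Linear region**: the contiguous run of points whose amplitudes lie in
[frac_lo, frac_hi]·Vmax, defaults 0.2–0.8 (the 20–80 %-of-maximum band
customary in animal work; configurable because the exact band in human
studies varies). Fewer than 3 surviving points ⇒ the curve is declared
unusable, and the electrode is excluded with a recorded reason — the
exclusion bookkeeping is part of the method, since sizeable fractions of
tested electrodes yield no measurable growth function in practice.

## The offset computation

`ipg_offset_effect` restricts both curves to their linear regions,
intersects the amplitude ranges, lays `n_levels = 10` log-spaced output
levels over the overlap, reads the required current at each level off
each curve by piecewise-linear interpolation in (dB current, log₁₀
amplitude) space (duplicate amplitudes have their currents averaged),
and reports the mean of dB(short-IPG) − dB(long-IPG). Sign convention:
healthier (larger) gain ratios give positive dB offsets.

Numerical notes:

* Because the output level grid is shared between curves, the choice of
  log- versus linear-spaced levels is immaterial for curves that are
  horizontal translations of each other (asserted in tests); log spacing
  is the default because the inversion space is log-amplitude.
* For power-law curves the (dB current, log amplitude) relation is
  affine, so interpolation is exact and the offset reproduces
  20·log₁₀(g ratio) to machine precision. For sigmoid curves on the
  default 25-point grids, interpolation bias is ≲ 0.015 dB — an order of
  magnitude below the noise-driven error at realistic noise levels.
* Overlap must span at least 10 % of the narrower region's log-amplitude
  range, else the electrode is rejected (`NoOverlapError`).
* A geometric constraint of the measure: two power-law curves whose
  amplitudes differ by the factor g^k stop sharing any 20–80 % band once
  g^k ≥ frac_hi/frac_lo = 4. Property tests therefore draw k below that
  bound; on saturating curves the constraint is milder because both
  curves approach the same asymptote.

`i50_offset` is the sigmoid-based variant: I₅₀(short) − I₅₀(long) from
two converged fits. On noiseless sigmoid data it coincides with the
interpolation offset to < 0.01 dB.

## Synthetic cohorts

`generate_cohort` builds n_subjects × electrodes_per_subject electrodes,
each carrying a long-IPG/short-IPG sigmoid pair differing only in g.
Defaults emulate a human-style study and are fixed once:

| parameter | default | meaning |
|---|---|---|
| n_subjects × electrodes | 10 × 8 | familiar human-study shape |
| IPGs / phase duration | 8 vs 40 μs / 25 μs | typical measurement pair |
| g_ratio_range | 1.2–2.2 | true offsets ≈ 1.6–6.9 dB |
| r_spread, s_spread | 0.5, 0.3 (log-normal σ) | non-neural dispersion; log-normal because electrode geometry acts multiplicatively |
| k_range | 0.8–2.0 | growth-exponent heterogeneity |
| noise_sigma_frac | 0.02 | amplitude noise, 2 % of each curve's asymptote |
| health_survival_coupling | 0.8 | ties both n and the SGN surrogate to the true Δlog g |
| health_subject_frac | 0.5 | share of latent-health variance at subject level |
| n_base, vmax_per_neuron | 2000, 0.25 μV | asymptotes of a few hundred μV |
| i50_base_db, n_currents | 40 dB re 1 μA, 25 | grid spans both conditions' 20–80 % bands |

Latent neural health is a subject-level plus electrode-level uniform
mixture (subjects differ in deafness duration; degeneration also varies
along the cochlea). The gain ratio is affine in health; the neuron count
and the SGN-density surrogate are tied to health through the coupling
parameter (a knob, deliberately, because how much survival covaries with
health is not something the model asserts). The surrogate is the true
Δlog g standardised, mixed with Gaussian disturbance, and scaled to
density-like units; no histology is modelled.

What the generator does **not** emulate: waveform-level noise and peak
picking (amplitudes are the starting point), saturation roll-off from
overstimulation (the non-monotonic high-level regime is outside the
region of interest by construction), impedance drift, and any real
IPG→g physiology. Passing tests therefore show that the *analysis chain*
recovers planted gain changes under multiplicative confounds and
additive noise — not that any particular physiological effect size will
be observed in vivo.

`evaluate_estimators` correlates every differential measure with the
surrogate and with the planted truth (Pearson and Spearman), computes
the linear-slope-effect vs mean-linear-slope correlation — the signature
of the scale confound: a constant proportional gain change necessarily
produces larger linear slope differences where slopes are larger — and
reports bias/RMSE/median error of the offset in dB. Degenerate-variance
cells (e.g. the offset column in a fixed-gain-ratio cohort, constant to
machine precision) are flagged and left empty rather than reported as
spurious correlations.

## Statistics

Pearson/Spearman with two-sided p from the t transform (scipy), the
Fisher r-to-z comparison of two independent correlation coefficients,
and a paired two-sided t-test on per-electrode slope pairs. The paired
test is a deliberate reduction of a subject-random-factor
repeated-measures design: with two conditions per electrode it answers
the same question without modelling unbalanced electrode-within-subject
nesting. p-values at animal-study sample sizes (n ≈ 9) are large-sample
approximations.

## Units and I/O

Currents convert between μA, dB re 1 μA (20·log₁₀, amplitude-of-current
convention) and Cochlear CL steps (I = 17.5·100^(CL/255), a documented
device convention of this package). All conversions are monotone and
round-trip exactly. One generic long-format CSV dialect is supported;
write/read round trips preserve values to better than 1e-12 relative
(floats serialised at repr precision). Out-of-order rows are sorted with
a logged warning; groups with fewer than 3 points are rejected
individually; duplicate (group, current) rows and non-numeric fields
fail the file with offending line numbers.

## Problem sizes

Defaults throughout (30–60-point curves, 10-level offsets, 80-electrode
cohorts, 200-draw property sweeps) were chosen as the smallest sizes at
which every identity is resolved far below its assertion tolerance;
curve fitting dominates runtime at well under a second per cohort.

## Known limitations

* The sigmoid steepness β is this package's parameterisation; it is not
  unit-comparable to slope parameters printed under other sigmoid
  conventions.
* Heterogeneous per-neuron gain ratios make the offset an effective
  average rather than an identity (see above).
* No polarity- or phase-duration-specific logic: any condition pair is
  accepted, and the differential machinery applies unchanged, but the
  package does not model how those manipulations map to g.
* The offset's independence from non-neural factors is a property of the
  multiplicative model; real data can violate multiplicativity (e.g.
  level-dependent recruitment), in which case the offset retains a
  residual dependence the simulator will not reveal.
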