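# Methods

## The phenomenon being modeled

A small drifting sinusoidal target is easier or harder to detect depending
on where it sits relative to a large, high-contrast drifting grating (the
*inducer*).  At the inducer's **trailing** edge, detection thresholds are
elevated by a roughly constant factor regardless of the target's phase —
ordinary surround suppression.  At the **leading** edge (the border the
pattern drifts toward), the elevation is strongly phase dependent: targets
whose waveform continues the inducer's waveform in space and time are
detected about as well as with no inducer at all, while targets in
antiphase are suppressed about twice as much as at the trailing edge.

The package models this as the superposition of the sensory input with an
internally generated *forward prediction*: a waveform with the inducer's
spatial structure, extrapolated beyond its leading edge, that adds to the
incoming pattern before detection.

## Observer model

For a target of Michelson contrast c (percent) the observer computes

    effective contrast  e = sqrt(c^2 + p^2 + 2 c p cos Δφ) / (1 + s)

where

* `p` is the effective prediction amplitude (zero at the trailing edge and
  in the no-inducer baseline),
* `Δφ` is the phase of the target relative to the extrapolated inducer
  waveform at the target's location (for an inducer rotated by θ it
  includes the positional term 2π·f·sin θ·d),
* `s` is a phase-blind divisive suppression strength (`s_leading` or
  `s_trailing`).

Detection in the 2AFC task follows a logistic in log contrast,

    P(correct) = 1/2 + (1/2 − λ) · logistic(β (log10 e − log10 θ0)),

anchored so that e = θ0 (the baseline threshold) gives 75% correct when
the lapse rate λ = 0.

The prediction amplitude is attenuated multiplicatively:

    p = a_p · (1 − 2^(−L/L50)) · exp(−g/λ_gap) · (1 − 2^(−T/T50)) · g_eye

with inducer length L and gap g in arcmin, duration T in ms, and
g_eye = ι for dichoptic presentation (1 monocularly).  The saturating
terms use the half-life form so the named constant is exactly the
half-point ("semisaturation") abscissa; the gap term uses an e-folding
exponential, the conventional meaning of a "space constant".  Both forms
are isolated behind `observer.prediction_strength`, so alternative shapes
can be substituted without touching anything else.

### Parameters and defaults

| parameter | meaning | default | unit |
|---|---|---|---|
| `baseline_threshold` θ0 | 75%-correct contrast, no inducer | 1.0 | Michelson % |
| `suppression_trailing` | divisive strength, trailing edge | 0.49 | – |
| `suppression_leading` | divisive strength, leading edge | 0.54 | – |
| `prediction_amplitude` a_p | asymptotic prediction amplitude | 0.52 | Michelson % |
| `support_semisat_arcmin` L50 | inducer length at half prediction | 15 | arcmin |
| `projection_constant_arcmin` λ_gap | e-fold of gap attenuation | 25 | arcmin |
| `temporal_semisat_ms` T50 | duration at half prediction | 122 | ms |
| `interocular_transfer` ι | dichoptic prediction fraction | 0.5 | – |
| `psychometric_slope` β | logistic slope on log10 contrast | 10 | – |
| `lapse_rate` | ceiling shortfall | 0 | – |

The three suppression/prediction parameters come from a closed-form
inversion of the phasor model at asymptotic prediction strength, given the
three mean threshold-elevation ratios measured in humans (trailing 1.49,
leading in-phase 1.02, leading antiphase 2.06):

    s_t = r_t − 1,    1 + s_l = (r_in + r_anti)/2,    a_p = θ0 (r_anti − r_in)/2.

Leading and trailing suppression are separate parameters because the data
do not force them equal (the inversion gives 0.54 vs 0.49).

θ0 is not constrained by the measured ratios (everything scales with it);
it defaults to 1% Michelson, a typical parafoveal detection threshold for
a 1 c/° drifting grating.  β = 10 on log10 contrast makes performance rise
from ~55% to ~95% over about a factor of 2.8 in contrast, typical of human
contrast detection; it mainly controls the sampling noise of simulated
thresholds.  ι = 0.5 encodes partial (clearly nonzero, clearly incomplete)
interocular transfer; no measured value constrains it, and by default ι
multiplies only the prediction, not the suppression (a `transfer_suppression`
flag extends it to both — the available observations do not decide this).

### Degenerate regions

For antiphase targets the phasor |c − p| is non-monotone in c below
c = p·|cos Δφ|.  `expected_threshold` always takes the upper (monotone)
branch, and the trial scheduler refuses contrast ranges that dip into the
non-monotone region, since a psychometric fit there would be meaningless.
Durations below one frame are allowed — duration acts only through the
temporal attenuation term, not through rendering.

## Stimulus layer

Gratings are sampled directly from the closed form
L = mean·(1 + c·sin(2π f u − s·2π tf t + φ)) on demand (64 samples per
spatial cycle, 100 Hz frame rate by default; anything coarser than 4
samples per cycle is rejected), so sampled patterns accumulate no phase
error.  Composite displays tile the target against the inducer along the
vertical drift axis; the target's phase is defined **at the shared
border** as the analytic continuation of the inducer's waveform plus the
nominal relative phase, which is what makes "in phase" mean "continuous
across the border in space and time".  The leading edge is resolved
operationally as the border the inducer's pattern drifts toward.  Baseline
displays carry their thin line cues as metadata only — they have no
luminance modulation and the observer model ignores them.

The observer consumes stimulus *parameters* (contrast, phase, geometry),
not rendered pixels; rendered fields exist for visualization and for
verifying the geometry and phase bookkeeping (border continuity, drift
speed, rotation consistency).

## Interference profiles: two routes

The theoretical interference profile is computed two independent ways:

1. **Phasor closed form:** local contrast = √(c_t² + p² + 2 c_t p cos Δφ(d)).
2. **Pixel route:** sample the target grating and the unit-amplitude
   extrapolated inducer, superpose them, and take the Michelson contrast
   (max−min)/(max+min) of the summed luminance in a window at the target
   location.

For two equal-frequency gratings differing in orientation by θ, the sum is
an exact sinusoid along the mean-wavevector direction (angle θ/2), along
which both components share the spatial frequency f·cos(θ/2) and their
relative phase is constant.  The pixel route therefore measures local
contrast in a one-cycle window aligned with that direction; this makes the
brute-force measurement agree with the closed form to numerical precision
rather than only approximately, and the test suite holds the two routes to
1% over a grid of (θ, f, φ, gain).  The implied relative threshold is
taken as target contrast divided by local contrast (threshold inversely
proportional to effective contrast gain) — the observer module realizes
the same monotone mapping explicitly.

## Experiment drivers and estimation

Thresholds are measured by the method of constant stimuli: 7 contrast
levels equally spaced in log10 over 0.6 decades, 120 trials per level (840
per threshold), all conditions of a run randomly interleaved in one
shuffled schedule.  The levels are centered per condition on the
observer's analytically expected threshold; the contrast ranges used for
the human observers are not part of the record, and auto-centering keeps
every level informative (this placement is recorded in output metadata).

Psychometric functions are fitted by binomial maximum likelihood with the
threshold (75% point) as a direct parameter, guess rate fixed at 0.5,
lapse fixed at 0 and overridable.  The optimizer is bounded L-BFGS-B from
a 3×3 grid of starting slopes and thresholds; ties break toward lower
deviance, then lower threshold.  Fits are flagged when data are degenerate
(no finite threshold), perfectly separated (threshold bracketed between
the adjacent levels, slope unidentified), or when the threshold falls
outside the spanned range.  Bootstrap standard errors resample trials
with replacement within each contrast level (1000 resamples by default)
and are flagged unreliable if more than 10% of refits degenerate.

The length/gap/duration sweeps interleave in-phase and antiphase targets,
and the attenuation constants are estimated by least-squares fits of the
saturating (length, duration) or decaying (gap) exponential to the
antiphase-minus-in-phase threshold difference.  Fitting the difference —
rather than the two curves jointly — isolates the interference effect from
the common suppression factor; under the observer model the difference is
exactly 2p, so the fitted constants estimate L50, λ_gap and T50 directly.

## What the simulations do and do not show

The synthetic observer is a *mean observer*: a single parameter set, no
between-observer variability (parameter jitter can emulate it but is not
calibrated), no lapses, no attention, eye-movement or position-shift
effects, and no response-time structure.  Because the default observer is
calibrated by inverting the same phasor model the package implements, the
phase-dependence round trips demonstrate the internal consistency and
statistical calibration of the whole pipeline (stimulus bookkeeping →
trial generation → threshold estimation → summary fits) — they are not an
independent confirmation of the underlying theory, which only the human
data can provide.  The parameter-recovery results for the attenuation
constants show that the estimation machinery recovers known generating
values at realistic trial counts, with their sampling variability.

## Problem sizes

Simulated sessions use the full 840 trials per threshold everywhere a
headline quantity is computed.  Phase-dependence summaries average five
independently seeded simulated observers and the sweep summaries three,
matching the observer counts behind the corresponding human means.
Monte-Carlo studies in the test suite (threshold-recovery coverage,
bootstrap validity, deviance calibration) use 40–500 replicates, chosen to
keep each study's own sampling error well below the tolerance it checks.
The end-to-end `run_all` command defaults to 40 trials per level; it
exists to regenerate every figure-level analysis quickly and
deterministically, not to reproduce the headline precision.
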