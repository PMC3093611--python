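# motion-forecast

Simulation and analysis tools for a classic question in visual
psychophysics: when a region of the visual field contains coherent motion,
does the visual system *predict* the spatial pattern about to appear ahead
of it?

The package implements, end to end and entirely in simulation, the
computational content of that experimental programme:

* **Stimuli** — parametric drifting sinusoidal gratings and composite
  target/inducer displays, with exact closed-form space–time sampling.
* **Forward model** — extrapolation of an inducer grating beyond its
  leading edge, superposition with a test grating, and the resulting
  spatial **interference profile**: with the inducer rotated by θ relative
  to the target, the relative phase between target and prediction varies
  with position *d* along the edge as Δφ(d) = 2π·f·sin θ·d + φ, so local
  contrast (and hence predicted detectability) modulates with period
  1/(f·sin θ).
* **Synthetic observer** — a 2AFC observer whose effective target contrast
  is the phasor sum √(c² + p² + 2cp·cos Δφ) of stimulus and prediction,
  divided by a phase-blind surround-suppression factor (1 + s).  The
  prediction amplitude saturates with inducer length (half point 15
  arcmin) and stimulus duration (half point 122 ms), decays exponentially
  across a gap (e-fold 25 arcmin), and transfers partially between eyes.
* **Experiments** — method-of-constant-stimuli drivers (7 log-spaced
  contrasts × 120 trials = 840 trials per threshold) for the
  phase-dependence, interference-profile, length, gap, duration and
  dichoptic designs.
* **Psychometrics** — binomial maximum-likelihood logistic fits reporting
  the 75%-correct threshold directly, bootstrap standard errors,
  suppression statistics, and saturating/decaying exponential summaries.

The packaged default observer is calibrated by inverting the phasor model
from three mean threshold-elevation ratios (trailing edge 1.49; leading
edge in phase 1.02; leading edge antiphase 2.06), giving s_trailing =
0.49, s_leading = 0.54 and a prediction amplitude of 0.52 × the baseline
threshold.

## Worked example

```python
from motion_forecast import default_observer, experiment_phase_dependence

obs = default_observer()
res = experiment_phase_dependence(obs, seed=1)   # 9 conditions x 840 trials
print(res.summary[["condition", "threshold", "log_suppression"]].round(3))
```

```
   condition  threshold  log_suppression
    baseline      1.021            0.000
   leading_0      1.051            0.013
  leading_90      1.474            0.159
 leading_180      2.039            0.300
 leading_270      1.449            0.152
  trailing_0      1.596            0.194
 trailing_90      1.476            0.160
trailing_180      1.432            0.147
trailing_270      1.623            0.201
```

Thresholds are Michelson percent; `log_suppression` is log10(threshold /
baseline).  The signature of forward prediction is visible directly:
trailing-edge thresholds are elevated by roughly 0.17 log units at every
phase, while leading-edge thresholds swing from baseline (in phase, 0.013)
to a doubling (antiphase, 0.300) — constructive interference cancels the
suppression, destructive interference compounds it.

Fitting the in-phase/antiphase threshold difference from a simulated
inducer-length sweep recovers the spatial support of the prediction:

```python
from motion_forecast import experiment_support, fit_saturating_exponential

sweep = experiment_support(obs, seed=1)
fit = fit_saturating_exponential(sweep.summary["length_arcmin"],
                                 sweep.summary["difference"])
print(f"{fit.constant:.1f} arcmin")   # -> 14.0 arcmin (generating value 15)
```

A command-line interface mirrors the drivers
(`motion-forecast phase|profile|support|projection|timecourse|dichoptic|all`),
writing trial tables (CSV), fit summaries (CSV/JSON) and figure-style PNGs,
e.g.

```sh
motion-forecast all --seed 1 --out out/
```

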