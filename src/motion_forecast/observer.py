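"""A parametric 2AFC observer with surround suppression and forward prediction.

The observer's sensitivity to a small drifting target abutting a
high-contrast drifting inducer is governed by two interacting mechanisms:

* **Divisive surround suppression** — a phase-blind factor ``1 + s`` that
  scales down the target's contrast at either edge of the inducer
  (``s_leading`` at the leading edge, ``s_trailing`` at the trailing edge,
  0 with no inducer).

* **Additive forward prediction** — at the leading edge only, an internally
  generated waveform with the inducer's spatial structure and amplitude
  ``a_p`` (Michelson %) is added to the incoming pattern, so target and
  prediction interfere: the effective contrast is the phasor amplitude
  sqrt(c**2 + p**2 + 2*c*p*cos(dphi)) of the pair.

Prediction strength is attenuated multiplicatively by inducer length
(saturating, half point ``support_semisat_arcmin``), by a spatial gap
(exponential decay, e-fold ``projection_constant_arcmin``), by stimulus
duration (saturating, half point ``temporal_semisat_ms``) and, for
dichoptic presentation, by the interocular transfer fraction.

Detection follows a logistic psychometric function of log10 effective
contrast anchored so that effective contrast equal to the baseline
threshold yields 75% correct in the 2AFC task (chance = 50%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.special import expit

from .forward_model import analytic_interference_amplitude
from .stimulus import DisplayConfig

__all__ = [
    "ObserverParams",
    "EffectiveContrastBreakdown",
    "prediction_strength",
    "effective_contrast",
    "detection_probability",
    "simulate_trial",
    "expected_threshold",
    "calibrate_defaults",
    "default_observer",
]

ARCMIN_PER_DEG = 60.0


class ObserverParams(BaseModel):
    """Parameters of the synthetic observer.

    Contrast-like quantities (``baseline_threshold``, ``prediction_amplitude``)
    are in Michelson percent; spatial constants in arcmin; the temporal
    constant in ms.  ``psychometric_slope`` acts on log10 contrast.
    """

    model_config = ConfigDict(extra="forbid")

    baseline_threshold: float = Field(gt=0, description="75%-correct contrast, no inducer (%)")
    suppression_trailing: float = Field(ge=0)
    suppression_leading: float = Field(ge=0)
    prediction_amplitude: float = Field(ge=0, description="internal waveform amplitude (%)")
    support_semisat_arcmin: float = Field(default=15.0, gt=0)
    projection_constant_arcmin: float = Field(default=25.0, gt=0)
    temporal_semisat_ms: float = Field(default=122.0, gt=0)
    interocular_transfer: float = Field(default=0.5, ge=0, le=1)
    transfer_suppression: bool = False
    psychometric_slope: float = Field(default=10.0, gt=0)
    lapse_rate: float = Field(default=0.0, ge=0, lt=0.5)
    guess_rate: float = 0.5
    rng_seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ObserverParams":
        return cls.model_validate(json.loads(Path(path).read_text()))


@dataclass
class EffectiveContrastBreakdown:
    """Stage-by-stage account of how a target contrast becomes effective."""

    raw_contrast: float
    prediction_effective: float
    delta_phi: float
    phasor_sum: float
    suppression_divisor: float
    effective_contrast: float


def prediction_strength(params: ObserverParams, config: DisplayConfig) -> float:
    """Effective prediction amplitude (Michelson %) for one display.

    Zero at the trailing edge and in the baseline condition.  At the
    leading edge:

        a_p * (1 - 2**(-L/L50)) * exp(-gap/lambda) * (1 - 2**(-T/T50)) * g_eye

    with L the inducer length and gap in arcmin, T the duration in ms, and
    g_eye the interocular transfer fraction for dichoptic displays (1
    monocularly).
    """
    if config.inducer_length < 0 or config.gap < 0 or config.duration < 0:
        raise ValueError("inducer length, gap and duration must be nonnegative")
    if config.edge != "leading":
        return 0.0
    length_arcmin = config.inducer_length * ARCMIN_PER_DEG
    gap_arcmin = config.gap * ARCMIN_PER_DEG
    duration_ms = config.duration * 1000.0
    g_len = 1.0 - 2.0 ** (-length_arcmin / params.support_semisat_arcmin)
    g_gap = np.exp(-gap_arcmin / params.projection_constant_arcmin)
    g_dur = 1.0 - 2.0 ** (-duration_ms / params.temporal_semisat_ms)
    g_eye = params.interocular_transfer if config.dichoptic else 1.0
    return float(params.prediction_amplitude * g_len * g_gap * g_dur * g_eye)


def _suppression(params: ObserverParams, config: DisplayConfig) -> float:
    if config.edge == "leading":
        s = params.suppression_leading
    elif config.edge == "trailing":
        s = params.suppression_trailing
    else:
        return 0.0
    if config.dichoptic and params.transfer_suppression:
        s = s * params.interocular_transfer
    return s


def relative_phase_at_target(config: DisplayConfig) -> float:
    """Target-vs-prediction phase, including the offset term for rotated inducers."""
    f = config.target.spatial_frequency
    theta = np.deg2rad(config.relative_orientation_theta)
    return float(config.relative_phase + 2.0 * np.pi * f * np.sin(theta) * config.target_offset)


def effective_contrast(
    params: ObserverParams, config: DisplayConfig, target_contrast: float
) -> EffectiveContrastBreakdown:
    """Map a physical target contrast (%) to the observer's effective contrast."""
    if target_contrast < 0:
        raise ValueError("target contrast must be nonnegative")
    p = prediction_strength(params, config)
    dphi = relative_phase_at_target(config)
    phasor = analytic_interference_amplitude(target_contrast, p, dphi)
    s = _suppression(params, config)
    return EffectiveContrastBreakdown(
        raw_contrast=target_contrast,
        prediction_effective=p,
        delta_phi=dphi,
        phasor_sum=phasor,
        suppression_divisor=1.0 + s,
        effective_contrast=phasor / (1.0 + s),
    )


def detection_probability(params: ObserverParams, effective: float) -> float:
    """Probability correct in the 2AFC task given an effective contrast (%).

    p = guess + (1 - guess - lapse) * logistic(beta * (log10 e - log10 theta0));
    effective contrast equal to the baseline threshold gives 75% correct when
    the lapse rate is zero, and p tends to chance as contrast vanishes.
    """
    if effective < 0:
        raise ValueError("effective contrast must be nonnegative")
    if effective == 0.0:
        return params.guess_rate
    z = params.psychometric_slope * (
        np.log10(effective) - np.log10(params.baseline_threshold)
    )
    return float(
        params.guess_rate + (1.0 - params.guess_rate - params.lapse_rate) * expit(z)
    )


def simulate_trial(
    params: ObserverParams,
    config: DisplayConfig,
    target_contrast: float,
    rng: np.random.Generator,
) -> dict:
    """One Bernoulli 2AFC trial; reproducible given the generator state."""
    true_side = "left" if rng.random() < 0.5 else "right"
    p = detection_probability(
        params, effective_contrast(params, config, target_contrast).effective_contrast
    )
    correct = bool(rng.random() < p)
    if correct:
        reported = true_side
    else:
        reported = "right" if true_side == "left" else "left"
    return {"correct": correct, "side_reported": reported, "side_true": true_side, "p": p}


def expected_threshold(params: ObserverParams, config: DisplayConfig) -> float:
    """Closed-form 75%-correct contrast (%) for one display condition.

    Solves phasor(c, p, dphi) / (1 + s) = theta0 for c, taking the upper
    (monotone) branch of the phasor:

        c = -p*cos(dphi) + sqrt((theta0*(1+s))**2 - (p*sin(dphi))**2).
    """
    p = prediction_strength(params, config)
    dphi = relative_phase_at_target(config)
    s = _suppression(params, config)
    e = params.baseline_threshold * (1.0 + s)
    disc = e**2 - (p * np.sin(dphi)) ** 2
    if disc < 0:
        raise ValueError("prediction exceeds criterion: no real threshold exists")
    c = -p * np.cos(dphi) + np.sqrt(disc)
    if c <= 0:
        raise ValueError("prediction alone exceeds criterion; threshold is not positive")
    return float(c)


def nonmonotone_bound(params: ObserverParams, config: DisplayConfig) -> float:
    """Contrast (%) below which effective contrast decreases with contrast.

    The phasor amplitude is non-monotone in target contrast when
    cos(dphi) < 0 and c < -p*cos(dphi); stimulus levels for threshold
    measurement must sit above this bound.
    """
    p = prediction_strength(params, config)
    dphi = relative_phase_at_target(config)
    return float(max(0.0, -p * np.cos(dphi)))


def calibrate_defaults(
    r_trailing: float = 1.49,
    r_inphase: float = 1.02,
    r_antiphase: float = 2.06,
    baseline_threshold: float = 1.0,
    **overrides,
) -> ObserverParams:
    """Invert the phasor model from three measured suppression ratios.

    Given threshold ratios relative to baseline for trailing-edge targets
    (phase-blind), leading-edge in-phase targets and leading-edge antiphase
    targets, and assuming asymptotic prediction strength, the model gives in
    closed form

        s_trailing = r_t - 1
        1 + s_leading = (r_in + r_anti) / 2
        a_p = theta0 * (r_anti - r_in) / 2.

    The defaults are the mean suppression ratios of the human observers the
    model emulates (1.49, 1.02 and 2.06, i.e. 49%, 2% and 106% threshold
    elevation).  Spatial and temporal attenuation constants default to the
    fitted values 15 arcmin (length half point), 25 arcmin (gap e-fold) and
    122 ms (duration half point).
    """
    if min(r_trailing, r_inphase, r_antiphase) <= 0:
        raise ValueError("suppression ratios must be positive")
    if r_antiphase < r_inphase:
        raise ValueError("model requires antiphase threshold ratio >= in-phase ratio")
    fields = dict(
        baseline_threshold=baseline_threshold,
        suppression_trailing=r_trailing - 1.0,
        suppression_leading=(r_inphase + r_antiphase) / 2.0 - 1.0,
        prediction_amplitude=baseline_threshold * (r_antiphase - r_inphase) / 2.0,
    )
    fields.update(overrides)
    return ObserverParams(**fields)


def default_observer() -> ObserverParams:
    """The packaged calibrated observer (see ``data/default_observer.json``)."""
    ref = resources.files("motion_forecast").joinpath("data/default_observer.json")
    return ObserverParams.model_validate(json.loads(ref.read_text()))
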