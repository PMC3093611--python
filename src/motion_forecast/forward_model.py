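"""Forward-model superposition and spatial interference profiles.

A region of drifting grating induces a prediction of the pattern ahead of
its leading edge: the analytic continuation of its waveform in space and
time.  Superposing that prediction with a test grating of the same spatial
frequency yields constructive or destructive interference depending on
their relative phase.  When the inducer is rotated by ``theta`` relative to
the target, the relative phase varies with the target's position ``d``
along the inducer edge,

    dphi(d) = 2*pi*f*sin(theta)*d + target_phase,

so the local contrast of the superposition traces a spatial interference
profile that is periodic in ``d`` with period 1/(f*sin(theta)).

Two independent routes compute the profile: a closed-form phasor expression
and a brute-force pixel route (extrapolate -> superpose -> local contrast on
the sampled field).  The pixel route measures local contrast in a window one
carrier cycle long aligned with the interference pattern's constant-phase
direction (the mean-wavevector direction, at angle theta/2), along which the
superposition of the two equal-frequency gratings is an exact sinusoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimulus import GratingParams, SpaceTimePattern, make_grating

__all__ = [
    "InterferenceProfile",
    "extrapolate_inducer",
    "superpose",
    "local_contrast",
    "analytic_interference_amplitude",
    "interference_profile",
    "pixel_interference_profile",
]


@dataclass
class InterferenceProfile:
    """Predicted local contrast versus target offset along the inducer edge.

    ``predicted_threshold_factor`` is the relative detection threshold
    implied by the profile, defined as target contrast divided by local
    contrast (threshold inversely proportional to the local effective
    contrast gain).
    """

    offsets: np.ndarray
    local_contrast: np.ndarray
    predicted_threshold_factor: np.ndarray
    theta: float
    target_phase: float
    spatial_frequency: float

    @property
    def period(self) -> float:
        """Spatial period of the profile along the edge, 1/(f*sin(theta))."""
        s = np.sin(np.deg2rad(self.theta))
        return np.inf if s == 0 else 1.0 / (self.spatial_frequency * abs(s))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset_deg": self.offsets,
                "local_contrast": self.local_contrast,
                "predicted_threshold_factor": self.predicted_threshold_factor,
            }
        )


def analytic_interference_amplitude(c_t: float, c_p: float, delta_phi: float) -> float:
    """Amplitude of the sum of two equal-frequency sinusoids (phasor sum).

    Returns sqrt(c_t**2 + c_p**2 + 2*c_t*c_p*cos(delta_phi)); delta_phi = 0
    gives c_t + c_p (constructive) and pi gives |c_t - c_p| (destructive).
    """
    c_t = np.asarray(c_t, dtype=float)
    c_p = np.asarray(c_p, dtype=float)
    if np.any(c_t < 0) or np.any(c_p < 0):
        raise ValueError("contrasts must be nonnegative")
    sq = c_t**2 + c_p**2 + 2.0 * c_t * c_p * np.cos(delta_phi)
    out = np.sqrt(np.maximum(sq, 0.0))
    return float(out) if out.ndim == 0 else out


def extrapolate_inducer(
    inducer: GratingParams,
    region: tuple[float, float, float, float],
    gap: float = 0.0,
    *,
    inducer_center: tuple[float, float] | None = None,
    phase_origin: tuple[float, float] = (0.0, 0.0),
    grid_spacing: float | None = None,
    duration: float = 0.0,
    time_step: float = 0.01,
) -> SpaceTimePattern:
    """Continue the inducer's waveform beyond its edge, at unit amplitude.

    The continuation keeps the inducer's spatial frequency, orientation,
    drift and phase trajectory and is evaluated over ``region`` =
    (x0, x1, y0, y1); a gap merely displaces the region, since the analytic
    continuation is global.  When ``inducer_center`` is given, the region
    must not overlap the inducer's own rectangle; pass ``None`` for purely
    theoretical profiles in which the inducer patch is not represented.
    """
    if gap < 0:
        raise ValueError("gap must be nonnegative")
    if inducer_center is not None:
        ix0 = inducer_center[0] - inducer.width / 2
        ix1 = inducer_center[0] + inducer.width / 2
        iy0 = inducer_center[1] - inducer.height / 2
        iy1 = inducer_center[1] + inducer.height / 2
        x0, x1, y0, y1 = region
        tol = 1e-9
        if (x0 < ix1 - tol and ix0 < x1 - tol) and (y0 < iy1 - tol and iy0 < y1 - tol):
            raise ValueError("extrapolation region overlaps the inducer patch")
    big = inducer.model_copy(update={"width": 1e9, "height": 1e9, "contrast": 1.0})
    cx = (region[0] + region[1]) / 2
    cy = (region[2] + region[3]) / 2
    pat = make_grating(
        big,
        region,
        duration,
        grid_spacing,
        time_step,
        center=(cx, cy),
        phase_origin=phase_origin,
    )
    pat.meta = {"extrapolated": True, "gap": gap}
    return pat


def superpose(
    target_field: SpaceTimePattern,
    prediction_field: SpaceTimePattern,
    prediction_gain: float = 1.0,
) -> SpaceTimePattern:
    """Pointwise sum of modulation components; mean luminance preserved."""
    a, b = target_field, prediction_field
    if a.luminance.shape != b.luminance.shape:
        raise ValueError("grid mismatch: shapes differ")
    if (
        abs(a.grid_spacing - b.grid_spacing) > 1e-12
        or abs(a.time_step - b.time_step) > 1e-12
        or abs(a.origin[0] - b.origin[0]) > 1e-9
        or abs(a.origin[1] - b.origin[1]) > 1e-9
    ):
        raise ValueError("grid mismatch: spacing or origin differ")
    mod = (a.luminance - a.mean_luminance) + prediction_gain * (
        b.luminance - b.mean_luminance
    )
    return SpaceTimePattern(
        luminance=a.mean_luminance + mod,
        grid_spacing=a.grid_spacing,
        time_step=a.time_step,
        origin=a.origin,
        mean_luminance=a.mean_luminance,
        meta={"superposed": True, "prediction_gain": prediction_gain},
    )


def local_contrast(
    field: SpaceTimePattern,
    window_center: tuple[float, float],
    window_size: tuple[float, float],
    *,
    time_index: int = 0,
    min_period: float | None = None,
) -> float:
    """Michelson contrast (max-min)/(max+min) within a spatial window.

    Evaluated at a fixed time slice; for a pure sinusoid sampled over at
    least one full cycle this equals its Michelson contrast.  If
    ``min_period`` (the longest spatial period present) is given and the
    window is smaller in both dimensions, a warning is raised because the
    result would be phase dependent.
    """
    wx, wy = window_size
    if min_period is not None and wx < min_period and wy < min_period:
        warnings.warn(
            "local-contrast window smaller than one spatial cycle; "
            "result is phase dependent",
            stacklevel=2,
        )
    xs, ys = field.x, field.y
    half = field.grid_spacing / 2
    mx = (xs >= window_center[0] - wx / 2 - half) & (xs <= window_center[0] + wx / 2 + half)
    my = (ys >= window_center[1] - wy / 2 - half) & (ys <= window_center[1] + wy / 2 + half)
    patch = field.luminance[time_index][np.ix_(my, mx)]
    if patch.size == 0:
        raise ValueError("window contains no samples")
    lo, hi = float(patch.min()), float(patch.max())
    if hi + lo == 0:
        return 0.0
    return (hi - lo) / (hi + lo)


def interference_profile(
    theta: float,
    f: float,
    target_phase: float,
    prediction_gain: float,
    offsets: np.ndarray | list[float],
    target_contrast: float = 1.0,
) -> InterferenceProfile:
    """Closed-form (phasor) interference profile along the inducer edge.

    For each offset ``d``, the relative phase between target and prediction
    is 2*pi*f*sin(theta)*d + target_phase and the local contrast is the
    phasor amplitude of the two components.  theta = 0 yields a constant
    profile.
    """
    offsets = np.asarray(offsets, dtype=float)
    if offsets.size == 0:
        raise ValueError("offsets must be non-empty")
    dphi = 2.0 * np.pi * f * np.sin(np.deg2rad(theta)) * offsets + target_phase
    lc = analytic_interference_amplitude(target_contrast, prediction_gain, dphi)
    lc = np.atleast_1d(np.asarray(lc, dtype=float))
    with np.errstate(divide="ignore"):
        factor = np.where(lc > 0, target_contrast / np.where(lc > 0, lc, 1.0), np.inf)
    return InterferenceProfile(
        offsets=offsets,
        local_contrast=lc,
        predicted_threshold_factor=factor,
        theta=theta,
        target_phase=target_phase,
        spatial_frequency=f,
    )


def pixel_interference_profile(
    theta: float,
    f: float,
    target_phase: float,
    prediction_gain: float,
    offsets: np.ndarray | list[float],
    target_contrast: float = 1.0,
    samples_per_cycle: int = 256,
) -> np.ndarray:
    """Brute-force interference profile from sampled luminance fields.

    For each offset the target grating and the unit-amplitude extrapolated
    inducer are sampled on a grid rotated by theta/2 (both then share the
    same frequency along the grid's x axis and their relative phase is
    constant along it), superposed, and reduced to a Michelson local
    contrast over a one-cycle window.  Serves as the independent pixel-level
    route that must agree with :func:`interference_profile`.
    """
    offsets = np.asarray(offsets, dtype=float)
    if offsets.size == 0:
        raise ValueError("offsets must be non-empty")
    psi = np.deg2rad(theta) / 2.0
    f_e = f * np.cos(psi)  # common frequency along the rotated x axis
    period = 1.0 / f_e
    dx = period / samples_per_cycle

    # grating orientations expressed in the rotated frame
    tgt = GratingParams(
        spatial_frequency=f,
        temporal_frequency=0.0,
        orientation=-np.rad2deg(psi),
        phase=0.0,
        contrast=target_contrast,
        width=1e9,
        height=1e9,
    )
    ind = GratingParams(
        spatial_frequency=f,
        temporal_frequency=0.0,
        orientation=np.rad2deg(psi),
        phase=target_phase,
        contrast=1.0,
        width=1.0,
        height=1.0,
    )

    out = np.empty_like(offsets)
    for i, d in enumerate(offsets):
        # window center: the edge point at offset d, in rotated-frame coords
        cx = d * np.sin(psi)
        cy = d * np.cos(psi)
        region = (cx - period / 2, cx + period / 2, cy, cy)
        t_field = make_grating(
            tgt, region, 0.0, dx, center=(cx, cy), phase_origin=(0.0, 0.0)
        )
        p_field = extrapolate_inducer(
            ind, region, inducer_center=None, phase_origin=(0.0, 0.0), grid_spacing=dx
        )
        summed = superpose(t_field, p_field, prediction_gain)
        out[i] = local_contrast(summed, (cx, cy), (period, 0.0))
    return out
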