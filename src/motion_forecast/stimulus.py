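"""Parametric drifting-grating stimuli and composite displays.

Coordinates are degrees of visual angle, x rightward, y upward, with the
origin at fixation.  A grating with orientation 0 has vertical bars and is
modulated along x; orientation is measured counterclockwise, so orientation
90 gives horizontal bars whose modulation (and drift) axis is vertical.

Luminance follows the closed form

    L(x, y, t) = mean * (1 + c * sin(2*pi*f*u - s*2*pi*tf*t + phi))

where ``u`` is the coordinate along the modulation axis measured from the
grating's phase origin, ``s`` the drift sign, and the field equals the mean
luminance outside the patch window.  All sampled patterns are evaluated
directly from this expression (no incremental phase stepping), so they carry
no accumulated phase error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "GratingParams",
    "DisplayConfig",
    "SpaceTimePattern",
    "SpaceTimeSlice",
    "make_grating",
    "compose_display",
    "space_time_profile",
    "grating_luminance",
]


class GratingParams(BaseModel):
    """Full parametric description of one drifting sinusoidal patch.

    ``phase`` is the phase (radians) at the patch's reference point at t = 0;
    by default the reference point is the patch center, but evaluation
    functions accept an explicit ``phase_origin``.
    """

    model_config = ConfigDict(extra="forbid")

    spatial_frequency: float = Field(gt=0, description="cycles per degree")
    temporal_frequency: float = Field(ge=0, description="Hz")
    orientation: float = 0.0
    phase: float = 0.0
    contrast: float = Field(default=1.0, ge=0.0, le=1.0)
    width: float = Field(gt=0)
    height: float = Field(gt=0)
    drift_sign: Literal[1, -1] = 1
    mean_luminance: float = Field(default=1.0, gt=0)


class DisplayConfig(BaseModel):
    """One trial's geometry: target plus inducer(s), edge relation, offsets.

    ``relative_phase`` is the phase advance of the target relative to the
    analytic continuation (extrapolation) of the inducer waveform at the
    border nearest the target.  ``target_offset`` displaces the target along
    the inducer edge (signed, degrees, center-to-center).
    """

    model_config = ConfigDict(extra="forbid")

    target: GratingParams
    inducer: Optional[GratingParams] = None
    edge: Literal["leading", "trailing", "baseline"]
    relative_phase: float = 0.0
    relative_orientation_theta: float = 0.0
    gap: float = Field(default=0.0, ge=0.0)
    inducer_length: float = Field(default=6.67, gt=0)
    duration: float = Field(default=1.0, gt=0)
    target_offset: float = 0.0
    eye_target: Literal["left", "right"] = "left"
    eye_inducer: Literal["left", "right"] = "left"
    target_side: Literal["left", "right"] = "left"
    line_cue_width_arcmin: float = 2.0  # baseline line cues; metadata only

    @model_validator(mode="after")
    def _needs_inducer(self) -> "DisplayConfig":
        if self.edge != "baseline" and self.inducer is None:
            raise ValueError("edge conditions require an inducer grating")
        return self

    @property
    def dichoptic(self) -> bool:
        return self.eye_target != self.eye_inducer


@dataclass
class SpaceTimePattern:
    """A sampled luminance field over (t, y, x).

    ``luminance`` has shape (nt, ny, nx); ``origin`` is the (x, y) position
    of the first spatial sample.
    """

    luminance: np.ndarray
    grid_spacing: float
    time_step: float
    origin: tuple[float, float]
    mean_luminance: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.grid_spacing * np.arange(self.luminance.shape[2])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.grid_spacing * np.arange(self.luminance.shape[1])

    @property
    def t(self) -> np.ndarray:
        return self.time_step * np.arange(self.luminance.shape[0])

    def save(self, path: str | Path) -> None:
        """Write the array as .npy with a JSON sidecar holding grid metadata."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.luminance)
        sidecar = {
            "grid_spacing": self.grid_spacing,
            "time_step": self.time_step,
            "origin": list(self.origin),
            "mean_luminance": self.mean_luminance,
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SpaceTimePattern":
        path = Path(path)
        lum = np.load(path.with_suffix(".npy"))
        side = json.loads(path.with_suffix(".json").read_text())
        return cls(
            luminance=lum,
            grid_spacing=side["grid_spacing"],
            time_step=side["time_step"],
            origin=tuple(side["origin"]),
            mean_luminance=side.get("mean_luminance", 1.0),
            meta=side.get("meta", {}),
        )


@dataclass
class SpaceTimeSlice:
    """A 2-D (time x space) slice of a SpaceTimePattern."""

    values: np.ndarray  # (nt, nspace)
    space: np.ndarray
    t: np.ndarray
    axis: str


def _check_nyquist(params: GratingParams, grid_spacing: float, time_step: float) -> None:
    # >= 4 samples per cycle in space and (for drifting patterns) time
    if grid_spacing > 1.0 / (4.0 * params.spatial_frequency) + 1e-12:
        raise ValueError(
            f"grid spacing {grid_spacing:g} deg undersamples spatial frequency "
            f"{params.spatial_frequency:g} c/deg (need <= {1/(4*params.spatial_frequency):g} deg)"
        )
    if params.temporal_frequency > 0 and time_step > 1.0 / (4.0 * params.temporal_frequency) + 1e-12:
        raise ValueError(
            f"time step {time_step:g} s undersamples temporal frequency "
            f"{params.temporal_frequency:g} Hz (need <= {1/(4*params.temporal_frequency):g} s)"
        )


def grating_luminance(
    params: GratingParams,
    x: np.ndarray,
    y: np.ndarray,
    t: np.ndarray | float,
    *,
    center: tuple[float, float] = (0.0, 0.0),
    phase_origin: tuple[float, float] | None = None,
    amplitude: float | None = None,
    masked: bool = True,
) -> np.ndarray:
    """Evaluate the closed-form grating at arbitrary coordinates.

    ``x``, ``y`` and ``t`` broadcast together.  ``amplitude`` overrides the
    Michelson contrast (used for unit-amplitude extrapolations); with
    ``masked=False`` the sinusoid is evaluated everywhere rather than only
    inside the patch rectangle.
    """
    if phase_origin is None:
        phase_origin = center
    th = np.deg2rad(params.orientation)
    u = (np.asarray(x) - phase_origin[0]) * np.cos(th) + (np.asarray(y) - phase_origin[1]) * np.sin(th)
    amp = params.contrast if amplitude is None else amplitude
    arg = (
        2.0 * np.pi * params.spatial_frequency * u
        - params.drift_sign * 2.0 * np.pi * params.temporal_frequency * np.asarray(t)
        + params.phase
    )
    lum = params.mean_luminance * (1.0 + amp * np.sin(arg))
    if masked:
        eps = 1e-9
        inside = (np.abs(np.asarray(x) - center[0]) <= params.width / 2 + eps) & (
            np.abs(np.asarray(y) - center[1]) <= params.height / 2 + eps
        )
        lum = np.where(inside, lum, params.mean_luminance)
    return lum


def _axis_samples(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def make_grating(
    params: GratingParams,
    extent: tuple[float, float, float, float],
    duration: float,
    grid_spacing: float | None = None,
    time_step: float = 0.01,
    *,
    center: tuple[float, float] = (0.0, 0.0),
    phase_origin: tuple[float, float] | None = None,
) -> SpaceTimePattern:
    """Sample one grating patch over ``extent`` = (x0, x1, y0, y1).

    Default sampling is 64 samples per spatial cycle and a 100 Hz frame
    rate.  Sampling coarser than 4 samples per cycle (space or time) is
    rejected.
    """
    if grid_spacing is None:
        grid_spacing = 1.0 / (64.0 * params.spatial_frequency)
    _check_nyquist(params, grid_spacing, time_step)
    x0, x1, y0, y1 = extent
    xs = _axis_samples(x0, x1, grid_spacing)
    ys = _axis_samples(y0, y1, grid_spacing)
    ts = _axis_samples(0.0, duration, time_step)
    lum = grating_luminance(
        params,
        xs[None, None, :],
        ys[None, :, None],
        ts[:, None, None],
        center=center,
        phase_origin=phase_origin,
    )
    return SpaceTimePattern(
        luminance=lum,
        grid_spacing=grid_spacing,
        time_step=time_step,
        origin=(float(xs[0]), float(ys[0])),
        mean_luminance=params.mean_luminance,
    )


def _rect(center: tuple[float, float], w: float, h: float) -> tuple[float, float, float, float]:
    return (center[0] - w / 2, center[0] + w / 2, center[1] - h / 2, center[1] + h / 2)


def _rects_overlap(a: tuple[float, float, float, float], b: tuple[float, float, float, float]) -> bool:
    tol = 1e-9
    return (a[0] < b[1] - tol and b[0] < a[1] - tol) and (a[2] < b[3] - tol and b[2] < a[3] - tol)


def compose_display(
    config: DisplayConfig,
    grid_spacing: float | None = None,
    time_step: float = 0.01,
) -> SpaceTimePattern:
    """Render one trial's display: target patch plus (optionally) an inducer.

    The patches are tiled along the vertical drift axis (target orientation
    90: horizontal bars drifting up or down).  The leading edge is the
    inducer border its pattern drifts toward; with ``edge='leading'`` the
    target sits beyond that border, separated by ``gap``.  The target's
    phase is set at its border nearest the inducer to equal the analytic
    continuation of the inducer waveform there plus ``relative_phase``, so
    in-phase (0) displays are spatiotemporally continuous across the border
    up to the contrast scaling, and antiphase (pi) displays carry the
    negated waveform.
    """
    tgt = config.target
    if grid_spacing is None:
        grid_spacing = 1.0 / (64.0 * tgt.spatial_frequency)

    if config.edge == "baseline":
        extent = _rect((config.target_offset, 0.0), tgt.width, tgt.height)
        pat = make_grating(
            tgt,
            (extent[0], extent[1], extent[2], extent[3]),
            config.duration,
            grid_spacing,
            time_step,
            center=(config.target_offset, 0.0),
        )
        pat.meta = {
            "edge": "baseline",
            "line_cue_width_arcmin": config.line_cue_width_arcmin,
            "eye_target": config.eye_target,
        }
        return pat

    ind = config.inducer
    assert ind is not None
    if abs((tgt.orientation % 180.0) - 90.0) > 1e-6:
        raise ValueError(
            "compose_display tiles patches along the vertical drift axis; "
            "target orientation must be 90 (horizontal bars, vertical drift)"
        )
    if abs(tgt.mean_luminance - ind.mean_luminance) > 1e-12:
        raise ValueError("target and inducer must share a mean luminance")

    length = config.inducer_length
    # leading border is on top for upward inducer drift
    inducer_above = (config.edge == "leading") == (ind.drift_sign < 0)
    tcx, tcy = config.target_offset, 0.0
    if inducer_above:
        icy = tgt.height / 2 + config.gap + length / 2
        y_border_target = tgt.height / 2
    else:
        icy = -(tgt.height / 2 + config.gap + length / 2)
        y_border_target = -tgt.height / 2
    icx = 0.0

    t_rect = _rect((tcx, tcy), tgt.width, tgt.height)
    i_rect = _rect((icx, icy), ind.width, length)
    if _rects_overlap(t_rect, i_rect):
        raise ValueError("target and inducer patches overlap; patches must tile, not blend")

    # analytic continuation of the inducer phase at the target's near border
    th_i = np.deg2rad(ind.orientation)
    u_border = (tcx - icx) * np.cos(th_i) + (y_border_target - icy) * np.sin(th_i)
    phase_at_border = 2.0 * np.pi * ind.spatial_frequency * u_border + ind.phase
    target_phase = phase_at_border + config.relative_phase

    x0 = min(t_rect[0], i_rect[0])
    x1 = max(t_rect[1], i_rect[1])
    y0 = min(t_rect[2], i_rect[2])
    y1 = max(t_rect[3], i_rect[3])
    # snap the box outward onto the sampling lattice so borders land on samples
    x0 = np.floor(x0 / grid_spacing) * grid_spacing
    y0 = np.floor(y0 / grid_spacing) * grid_spacing
    x1 = np.ceil(x1 / grid_spacing) * grid_spacing
    y1 = np.ceil(y1 / grid_spacing) * grid_spacing

    _check_nyquist(tgt, grid_spacing, time_step)
    _check_nyquist(ind, grid_spacing, time_step)
    xs = _axis_samples(x0, x1, grid_spacing)
    ys = _axis_samples(y0, y1, grid_spacing)
    ts = _axis_samples(0.0, config.duration, time_step)
    X = xs[None, None, :]
    Y = ys[None, :, None]
    T = ts[:, None, None]

    mean = tgt.mean_luminance
    lum = np.full((len(ts), len(ys), len(xs)), mean, dtype=float)

    ind_sized = ind.model_copy(update={"height": length})
    i_field = grating_luminance(ind_sized, X, Y, T, center=(icx, icy))
    i_mask = (np.abs(X - icx) <= ind.width / 2 + 1e-9) & (np.abs(Y - icy) <= length / 2 + 1e-9)
    lum = np.where(i_mask, i_field, lum)

    tgt_shifted = tgt.model_copy(update={"phase": target_phase})
    t_field = grating_luminance(
        tgt_shifted, X, Y, T, center=(tcx, tcy), phase_origin=(tcx, y_border_target)
    )
    t_mask = (np.abs(X - tcx) <= tgt.width / 2 + 1e-9) & (np.abs(Y - tcy) <= tgt.height / 2 + 1e-9)
    lum = np.where(t_mask, t_field, lum)

    return SpaceTimePattern(
        luminance=lum,
        grid_spacing=grid_spacing,
        time_step=time_step,
        origin=(float(xs[0]), float(ys[0])),
        mean_luminance=mean,
        meta={
            "edge": config.edge,
            "relative_phase": config.relative_phase,
            "gap": config.gap,
            "target_center": (tcx, tcy),
            "inducer_center": (icx, icy),
            "border_y": y_border_target,
            "eye_target": config.eye_target,
            "eye_inducer": config.eye_inducer,
        },
    )


def space_time_profile(pattern: SpaceTimePattern, axis: str, position: float) -> SpaceTimeSlice:
    """Extract a (time x space) slice at a fixed position on the other axis.

    ``axis='y'`` returns luminance versus (t, y) at x = position; ``axis='x'``
    returns (t, x) at y = position.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    xs, ys = pattern.x, pattern.y
    half = pattern.grid_spacing / 2 + 1e-9
    if axis == "y":
        if position < xs[0] - half or position > xs[-1] + half:
            raise ValueError(f"position {position:g} outside sampled x extent [{xs[0]:g}, {xs[-1]:g}]")
        ix = int(np.argmin(np.abs(xs - position)))
        return SpaceTimeSlice(pattern.luminance[:, :, ix], ys, pattern.t, "y")
    if position < ys[0] - half or position > ys[-1] + half:
        raise ValueError(f"position {position:g} outside sampled y extent [{ys[0]:g}, {ys[-1]:g}]")
    iy = int(np.argmin(np.abs(ys - position)))
    return SpaceTimeSlice(pattern.luminance[:, iy, :], xs, pattern.t, "x")
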