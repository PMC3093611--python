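"""Simulated psychophysical sessions: constant-stimuli scheduling and the
condition grids for each experiment.

Each driver realizes one experiment as a reproducible simulation: it builds
the display conditions, places seven log-spaced contrast levels around each
condition's analytically expected threshold (the levels used for the human
observers are not part of the record, so every level is kept informative by
construction), runs interleaved Bernoulli trials through the synthetic
observer, and returns the trial table together with fitted summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import psychofit
from .observer import (
    ObserverParams,
    detection_probability,
    effective_contrast,
    expected_threshold,
    nonmonotone_bound,
    prediction_strength,
)
from .forward_model import InterferenceProfile, interference_profile
from .stimulus import DisplayConfig, GratingParams

__all__ = [
    "MOCSDesign",
    "ExperimentResult",
    "make_levels",
    "run_condition",
    "run_conditions",
    "standard_display",
    "profile_display",
    "experiment_phase_dependence",
    "experiment_interference_profile",
    "experiment_support",
    "experiment_projection",
    "experiment_timecourse",
    "experiment_interocular",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = ["experiment_id", "condition", "replicate", "contrast", "correct", "seed_path"]

PHASES = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)
_PHASE_DEG = {0.0: 0, np.pi / 2: 90, np.pi: 180, 3 * np.pi / 2: 270}


class MOCSDesign(BaseModel):
    """A method-of-constant-stimuli design: fixed levels, fixed trial counts."""

    model_config = ConfigDict(extra="forbid")

    contrast_levels: list[float]
    trials_per_level: int = Field(default=120, gt=0)
    interleaving: list[str] = []
    seed: int = 0

    @field_validator("contrast_levels")
    @classmethod
    def _increasing(cls, v: list[float]) -> list[float]:
        arr = np.asarray(v, dtype=float)
        if np.any(arr <= 0) or np.any(np.diff(arr) <= 0):
            raise ValueError("contrast levels must be strictly increasing and positive")
        return v


@dataclass
class ExperimentResult:
    """Trial table plus fitted condition summaries for one experiment."""

    table: pd.DataFrame
    summary: pd.DataFrame
    fits: dict[str, psychofit.PsychometricFit]
    extras: dict = field(default_factory=dict)


def make_levels(center: float, span_log10: float = 0.6, n: int = 7) -> np.ndarray:
    """``n`` contrast levels equally spaced in log10, centered on ``center``."""
    if n < 2:
        raise ValueError("need at least two levels")
    if center <= 0:
        raise ValueError("center must be positive")
    if span_log10 <= 0:
        raise ValueError("span must be positive")
    return center * 10.0 ** np.linspace(-span_log10 / 2, span_log10 / 2, n)


# ---------------------------------------------------------------------------
# standard displays

def standard_display(
    edge: str,
    relative_phase: float = 0.0,
    *,
    inducer_length: float = 6.67,
    gap: float = 0.0,
    duration: float = 1.0,
    dichoptic: bool = False,
    target_offset: float = 0.0,
) -> DisplayConfig:
    """The collinear display: 1 c/deg, 5 Hz, 1x1 deg target, 100%-contrast inducer."""
    target = GratingParams(
        spatial_frequency=1.0, temporal_frequency=5.0, orientation=90.0,
        contrast=0.5, width=1.0, height=1.0,
    )
    inducer = None
    if edge != "baseline":
        inducer = GratingParams(
            spatial_frequency=1.0, temporal_frequency=5.0, orientation=90.0,
            contrast=1.0, width=1.0, height=inducer_length,
        )
    return DisplayConfig(
        target=target, inducer=inducer, edge=edge, relative_phase=relative_phase,
        inducer_length=inducer_length, gap=gap, duration=duration,
        target_offset=target_offset,
        eye_inducer="right" if dichoptic else "left",
    )


def profile_display(
    theta: float,
    target_offset: float,
    relative_phase: float = 0.0,
    duration: float = 1.0,
) -> DisplayConfig:
    """The rotated-inducer display: 0.5 c/deg, 2x2 deg target, 10 deg inducer."""
    target = GratingParams(
        spatial_frequency=0.5, temporal_frequency=5.0, orientation=0.0,
        contrast=0.5, width=2.0, height=2.0,
    )
    inducer = GratingParams(
        spatial_frequency=0.5, temporal_frequency=5.0, orientation=theta,
        contrast=1.0, width=10.0, height=10.0,
    )
    return DisplayConfig(
        target=target, inducer=inducer, edge="leading",
        relative_phase=relative_phase, relative_orientation_theta=theta,
        inducer_length=10.0, duration=duration, target_offset=target_offset,
    )


# ---------------------------------------------------------------------------
# trial scheduling

def run_conditions(
    observer: ObserverParams,
    conditions: dict[str, DisplayConfig],
    levels: dict[str, np.ndarray],
    trials_per_level: int = 120,
    seed: int = 0,
    experiment_id: str = "experiment",
) -> pd.DataFrame:
    """Run interleaved constant-stimuli trials for a set of conditions.

    All (condition, level, repeat) cells share a single shuffled schedule,
    emulating random interleaving within blocks; the same seed reproduces
    the table exactly.  Raises if any condition's levels reach into the
    region where the antiphase phasor makes effective contrast non-monotone
    in physical contrast.
    """
    for label, config in conditions.items():
        lv = np.asarray(levels[label], dtype=float)
        bound = nonmonotone_bound(observer, config)
        if lv.min() <= bound:
            raise ValueError(
                f"condition {label!r}: lowest contrast level {lv.min():.3g}% lies in the "
                f"non-monotone antiphase region (<= {bound:.3g}%); raise the contrast range"
            )

    labels, contrasts, probs = [], [], []
    for label, config in conditions.items():
        for lv in np.asarray(levels[label], dtype=float):
            p = detection_probability(
                observer, effective_contrast(observer, config, lv).effective_contrast
            )
            labels += [label] * trials_per_level
            contrasts += [lv] * trials_per_level
            probs += [p] * trials_per_level

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    labels = np.asarray(labels, dtype=object)[order]
    contrasts = np.asarray(contrasts)[order]
    probs = np.asarray(probs)[order]
    correct = (rng.random(len(probs)) < probs).astype(int)

    df = pd.DataFrame(
        {
            "experiment_id": experiment_id,
            "condition": labels,
            "contrast": contrasts,
            "correct": correct,
            "seed_path": [f"{seed}:{i}" for i in range(len(probs))],
        }
    )
    df["replicate"] = df.groupby(["condition", "contrast"]).cumcount()
    return df[TRIAL_COLUMNS]


def run_condition(
    observer: ObserverParams,
    config: DisplayConfig,
    design: MOCSDesign,
    experiment_id: str = "experiment",
    condition: str = "condition",
) -> pd.DataFrame:
    """Run a single condition under an explicit MOCS design."""
    return run_conditions(
        observer,
        {condition: config},
        {condition: np.asarray(design.contrast_levels, dtype=float)},
        trials_per_level=design.trials_per_level,
        seed=design.seed,
        experiment_id=experiment_id,
    )


def _auto_levels(
    observer: ObserverParams,
    conditions: dict[str, DisplayConfig],
    span_log10: float,
    n_levels: int,
) -> dict[str, np.ndarray]:
    return {
        label: make_levels(expected_threshold(observer, cfg), span_log10, n_levels)
        for label, cfg in conditions.items()
    }


def _fit_all(table: pd.DataFrame, conditions) -> dict[str, psychofit.PsychometricFit]:
    return {label: psychofit.fit_logistic(table, label) for label in conditions}


# ---------------------------------------------------------------------------
# experiment drivers

def experiment_phase_dependence(
    observer: ObserverParams,
    trials_per_level: int = 120,
    n_levels: int = 7,
    span_log10: float = 0.6,
    seed: int = 0,
) -> ExperimentResult:
    """Baseline plus leading/trailing edges at four relative phases.

    Returns per-condition thresholds and suppression (threshold elevation
    re baseline) in log10 units and percent.
    """
    conditions: dict[str, DisplayConfig] = {"baseline": standard_display("baseline")}
    for edge in ("leading", "trailing"):
        for ph in PHASES:
            conditions[f"{edge}_{_PHASE_DEG[ph]}"] = standard_display(edge, ph)
    levels = _auto_levels(observer, conditions, span_log10, n_levels)
    table = run_conditions(
        observer, conditions, levels, trials_per_level, seed, "phase_dependence"
    )
    fits = _fit_all(table, conditions)
    base = fits["baseline"].threshold
    rows = []
    for label, cfg in conditions.items():
        fit = fits[label]
        stats = psychofit.suppression_stats(fit.threshold, base)
        rows.append(
            {
                "condition": label,
                "edge": cfg.edge,
                "relative_phase": cfg.relative_phase,
                "threshold": fit.threshold,
                "slope": fit.slope,
                "log_suppression": stats["log_units"],
                "pct_suppression": stats["percent"],
                "n_trials": fit.n_trials,
            }
        )
    return ExperimentResult(table, pd.DataFrame(rows), fits)


def experiment_interference_profile(
    observer: ObserverParams,
    theta: float = 30.0,
    offsets: Sequence[float] | None = None,
    target_phases: Sequence[float] = (0.0, np.pi),
    trials_per_level: int = 120,
    n_levels: int = 7,
    span_log10: float = 0.6,
    seed: int = 0,
) -> ExperimentResult:
    """Thresholds versus target position along a rotated inducer's edge.

    Conditions differing in target phase by half a cycle are interleaved
    within the same schedule.  The result's ``extras`` carry the matching
    theoretical interference profiles (local contrast of a near-threshold
    target superposed with the prediction, and its implied relative
    threshold).
    """
    if offsets is None:
        offsets = np.arange(-5.0, 5.0 + 1e-9, 0.5)
    offsets = np.asarray(offsets, dtype=float)
    conditions: dict[str, DisplayConfig] = {}
    for ph in target_phases:
        for d in offsets:
            conditions[f"phase{_PHASE_DEG.get(ph, round(np.degrees(ph)))}_offset{d:+.2f}"] = (
                profile_display(theta, d, ph)
            )
    levels = _auto_levels(observer, conditions, span_log10, n_levels)
    table = run_conditions(
        observer, conditions, levels, trials_per_level, seed, f"interference_theta{theta:g}"
    )
    fits = _fit_all(table, conditions)
    rows = []
    for label, cfg in conditions.items():
        rows.append(
            {
                "condition": label,
                "target_phase": cfg.relative_phase,
                "offset": cfg.target_offset,
                "threshold": fits[label].threshold,
                "expected_threshold": expected_threshold(observer, cfg),
            }
        )
    summary = pd.DataFrame(rows)

    theory: dict[float, InterferenceProfile] = {}
    any_cfg = next(iter(conditions.values()))
    gain = prediction_strength(observer, any_cfg)
    f = any_cfg.target.spatial_frequency
    for ph in target_phases:
        theory[ph] = interference_profile(
            theta, f, ph, gain, offsets, target_contrast=observer.baseline_threshold
        )
    return ExperimentResult(table, summary, fits, extras={"theory": theory, "theta": theta})


def _sweep(
    observer: ObserverParams,
    variable: str,
    values: np.ndarray,
    make_config,
    trials_per_level: int,
    n_levels: int,
    span_log10: float,
    seed: int,
    experiment_id: str,
) -> ExperimentResult:
    """Shared machinery for the in-phase/antiphase parameter sweeps."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(values))]
    tables, rows, fits = [], [], {}
    for val, child in zip(values, child_seeds):
        conds = {
            f"inphase_{variable}{val:g}": make_config(val, 0.0),
            f"antiphase_{variable}{val:g}": make_config(val, np.pi),
        }
        levels = _auto_levels(observer, conds, span_log10, n_levels)
        table = run_conditions(observer, conds, levels, trials_per_level, child, experiment_id)
        tables.append(table)
        f_in = psychofit.fit_logistic(table, f"inphase_{variable}{val:g}")
        f_anti = psychofit.fit_logistic(table, f"antiphase_{variable}{val:g}")
        fits[f"inphase_{variable}{val:g}"] = f_in
        fits[f"antiphase_{variable}{val:g}"] = f_anti
        rows.append(
            {
                variable: val,
                "threshold_inphase": f_in.threshold,
                "threshold_antiphase": f_anti.threshold,
                "difference": f_anti.threshold - f_in.threshold,
            }
        )
    return ExperimentResult(pd.concat(tables, ignore_index=True), pd.DataFrame(rows), fits)


DEFAULT_SWEEP_ARCMIN = np.array([4.0, 7.0, 12.0, 20.0, 33.0, 60.0, 110.0, 200.0])
DEFAULT_DURATIONS_MS = np.array([20.0, 40.0, 80.0, 160.0, 320.0, 640.0, 1250.0, 2000.0])


def experiment_support(
    observer: ObserverParams,
    lengths_arcmin: Sequence[float] | None = None,
    trials_per_level: int = 120,
    n_levels: int = 7,
    span_log10: float = 0.6,
    seed: int = 0,
) -> ExperimentResult:
    """Inducer-length sweep (4 arcmin to 3.33 deg), in-phase vs antiphase."""
    vals = np.asarray(lengths_arcmin if lengths_arcmin is not None else DEFAULT_SWEEP_ARCMIN, float)
    return _sweep(
        observer, "length_arcmin", vals,
        lambda v, ph: standard_display("leading", ph, inducer_length=v / 60.0),
        trials_per_level, n_levels, span_log10, seed, "spatial_support",
    )


def experiment_projection(
    observer: ObserverParams,
    gaps_arcmin: Sequence[float] | None = None,
    trials_per_level: int = 120,
    n_levels: int = 7,
    span_log10: float = 0.6,
    seed: int = 0,
) -> ExperimentResult:
    """Gap sweep (4 arcmin to 3.33 deg) with a 6.67-deg inducer."""
    vals = np.asarray(gaps_arcmin if gaps_arcmin is not None else DEFAULT_SWEEP_ARCMIN, float)
    return _sweep(
        observer, "gap_arcmin", vals,
        lambda v, ph: standard_display("leading", ph, gap=v / 60.0),
        trials_per_level, n_levels, span_log10, seed, "spatial_projection",
    )


def experiment_timecourse(
    observer: ObserverParams,
    durations_ms: Sequence[float] | None = None,
    trials_per_level: int = 120,
    n_levels: int = 7,
    span_log10: float = 0.6,
    seed: int = 0,
) -> ExperimentResult:
    """Duration sweep, 20-2000 ms, in-phase vs antiphase."""
    vals = np.asarray(durations_ms if durations_ms is not None else DEFAULT_DURATIONS_MS, float)
    return _sweep(
        observer, "duration_ms", vals,
        lambda v, ph: standard_display("leading", ph, duration=v / 1000.0),
        trials_per_level, n_levels, span_log10, seed, "time_course",
    )


def experiment_interocular(
    observer: ObserverParams,
    trials_per_level: int = 120,
    n_levels: int = 7,
    span_log10: float = 0.6,
    seed: int = 0,
) -> ExperimentResult:
    """Monocular versus dichoptic presentation, in-phase vs antiphase."""
    conditions = {
        "monocular_inphase": standard_display("leading", 0.0),
        "monocular_antiphase": standard_display("leading", np.pi),
        "dichoptic_inphase": standard_display("leading", 0.0, dichoptic=True),
        "dichoptic_antiphase": standard_display("leading", np.pi, dichoptic=True),
    }
    levels = _auto_levels(observer, conditions, span_log10, n_levels)
    table = run_conditions(
        observer, conditions, levels, trials_per_level, seed, "interocular_transfer"
    )
    fits = _fit_all(table, conditions)
    rows = []
    for eye in ("monocular", "dichoptic"):
        diff = fits[f"{eye}_antiphase"].threshold - fits[f"{eye}_inphase"].threshold
        rows.append(
            {
                "presentation": eye,
                "threshold_inphase": fits[f"{eye}_inphase"].threshold,
                "threshold_antiphase": fits[f"{eye}_antiphase"].threshold,
                "difference": diff,
            }
        )
    summary = pd.DataFrame(rows)
    summary.attrs["transfer_ratio"] = float(
        summary.loc[summary.presentation == "dichoptic", "difference"].iloc[0]
        / summary.loc[summary.presentation == "monocular", "difference"].iloc[0]
    )
    return ExperimentResult(table, summary, fits)
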