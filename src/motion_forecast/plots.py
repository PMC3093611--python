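"""Figure-style plots for the simulated experiments."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stimulus import SpaceTimeSlice

__all__ = ["plot_space_time", "plot_experiment"]


def plot_space_time(slc: SpaceTimeSlice, path: str | Path) -> None:
    """Render a (space x time) luminance slice as a PNG."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(
        slc.values.T,
        aspect="auto",
        origin="lower",
        cmap="gray",
        extent=(slc.t[0], slc.t[-1] if len(slc.t) > 1 else 1.0, slc.space[0], slc.space[-1]),
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"{slc.axis} (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_phase(result, ax):
    s = result.summary
    for edge, color in (("leading", "k"), ("trailing", "r")):
        sub = s[s.edge == edge].sort_values("relative_phase")
        ax.plot(sub.relative_phase, sub.threshold, "o-", color=color, label=edge)
    base = s.loc[s.edge == "baseline", "threshold"]
    if len(base):
        ax.axhline(float(base.iloc[0]), ls="--", color="gray", label="baseline")
    ax.set_xlabel("relative phase (rad)")
    ax.set_ylabel("threshold (%)")
    ax.set_yscale("log")
    ax.legend(fontsize=8)


def _plot_profile(result, ax):
    s = result.summary
    for ph, color in zip(sorted(s.target_phase.unique()), ("k", "g", "b", "m")):
        sub = s[s.target_phase == ph].sort_values("offset")
        ax.plot(sub.offset, sub.threshold, "o-", color=color, label=f"phase {ph:.2f}")
    ax.set_xlabel("target offset (deg)")
    ax.set_ylabel("threshold (%)")
    ax.legend(fontsize=8)


def _plot_sweep(result, ax, xlabel):
    s = result.summary
    xcol = s.columns[0]
    ax.plot(s[xcol], s.threshold_inphase, "ko-", label="in phase")
    ax.plot(s[xcol], s.threshold_antiphase, "go-", label="antiphase")
    ax.set_xscale("log")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("threshold (%)")
    ax.legend(fontsize=8)


def _plot_dichoptic(result, ax):
    s = result.summary
    x = np.arange(len(s))
    ax.bar(x - 0.2, s.threshold_inphase, 0.4, color="k", label="in phase")
    ax.bar(x + 0.2, s.threshold_antiphase, 0.4, color="g", label="antiphase")
    ax.set_xticks(x, s.presentation)
    ax.set_ylabel("threshold (%)")
    ax.legend(fontsize=8)


def plot_experiment(name: str, result, path: str | Path) -> None:
    """Dispatch a summary plot for one named experiment driver."""
    fig, ax = plt.subplots(figsize=(5, 4))
    if name == "phase":
        _plot_phase(result, ax)
    elif name == "profile":
        _plot_profile(result, ax)
    elif name == "support":
        _plot_sweep(result, ax, "inducer length (arcmin)")
    elif name == "projection":
        _plot_sweep(result, ax, "gap (arcmin)")
    elif name == "timecourse":
        _plot_sweep(result, ax, "duration (ms)")
    elif name == "dichoptic":
        _plot_dichoptic(result, ax)
    else:
        raise ValueError(f"unknown experiment {name!r}")
    ax.set_title(name)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
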