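"""Configuration loading, trial-table I/O, and the end-to-end runner."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import ValidationError

from . import __version__, experiment, plots, psychofit
from .experiment import TRIAL_COLUMNS, MOCSDesign
from .observer import ObserverParams, default_observer
from .stimulus import DisplayConfig

__all__ = [
    "ConfigBundle",
    "ConfigError",
    "RunManifest",
    "load_config",
    "write_trial_table",
    "read_trial_table",
    "run_all",
]

log = logging.getLogger("motion_forecast")


class ConfigError(ValueError):
    pass


@dataclass
class ConfigBundle:
    observer: ObserverParams | None = None
    display: DisplayConfig | None = None
    design: MOCSDesign | None = None


_SECTIONS = {"observer": ObserverParams, "display": DisplayConfig, "design": MOCSDesign}


def load_config(path: str | Path) -> ConfigBundle:
    """Load and validate a JSON/YAML bundle of observer/display/design.

    Unknown keys (top level or nested) are rejected with the offending key
    named in the error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"{path}: unknown section(s) {sorted(unknown)}")
    bundle = ConfigBundle()
    for key, model in _SECTIONS.items():
        if key in raw:
            try:
                setattr(bundle, key, model.model_validate(raw[key]))
            except ValidationError as exc:
                raise ConfigError(f"{path}: invalid {key!r} section: {exc}") from exc
    return bundle


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV (comma, header, UTF-8, '.' decimal)."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a trial table (missing columns {missing})")
    return df


@dataclass
class RunManifest:
    """Record of one end-to-end run: seeds, outputs and their hashes."""

    package_version: str
    seed: int
    observer_hash: str
    experiment_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    timestamp: str = ""

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_record(fit: psychofit.PsychometricFit) -> dict:
    return {
        "threshold": fit.threshold,
        "slope": fit.slope,
        "n_trials": fit.n_trials,
        "converged": fit.converged,
        "deviance": fit.deviance,
        "flags": fit.flags,
    }


def run_all(
    seed: int,
    out_dir: str | Path,
    observer: ObserverParams | None = None,
    trials_per_level: int = 40,
    make_plots: bool = True,
) -> RunManifest:
    """Regenerate every figure-level analysis from a single seed.

    Runs the six experiment drivers (at a reduced default trial count),
    writing per-experiment trial tables, fit summaries and plots to
    ``out_dir``, plus a manifest listing every output and its hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise ConfigError(f"output directory {out} is not writable")
    obs = observer if observer is not None else default_observer()
    obs_hash = hashlib.sha256(
        json.dumps(obs.model_dump(), sort_keys=True).encode()
    ).hexdigest()

    ss = np.random.SeedSequence(seed)
    drivers = {
        "phase": lambda s: experiment.experiment_phase_dependence(
            obs, trials_per_level=trials_per_level, seed=s
        ),
        "profile": lambda s: experiment.experiment_interference_profile(
            obs, trials_per_level=trials_per_level, seed=s
        ),
        "support": lambda s: experiment.experiment_support(
            obs, trials_per_level=trials_per_level, seed=s
        ),
        "projection": lambda s: experiment.experiment_projection(
            obs, trials_per_level=trials_per_level, seed=s
        ),
        "timecourse": lambda s: experiment.experiment_timecourse(
            obs, trials_per_level=trials_per_level, seed=s
        ),
        "dichoptic": lambda s: experiment.experiment_interocular(
            obs, trials_per_level=trials_per_level, seed=s
        ),
    }
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(drivers, ss.spawn(len(drivers)))
    }

    manifest = RunManifest(
        package_version=__version__,
        seed=seed,
        observer_hash=obs_hash,
        experiment_seeds=seeds,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )

    for name, driver in drivers.items():
        log.info("running %s (seed=%d)", name, seeds[name])
        try:
            result = driver(seeds[name])
        except Exception:
            log.error("stage %r failed", name)
            raise
        paths = {
            "trials": out / f"{name}_trials.csv",
            "summary": out / f"{name}_summary.csv",
            "fits": out / f"{name}_fits.json",
        }
        write_trial_table(result.table, paths["trials"])
        result.summary.to_csv(paths["summary"], index=False)
        paths["fits"].write_text(
            json.dumps({k: _fit_record(v) for k, v in result.fits.items()}, indent=1)
        )
        if make_plots:
            png = out / f"{name}.png"
            plots.plot_experiment(name, result, png)
            paths["plot"] = png
        for p in paths.values():
            if p.exists() and p.stat().st_size > 0:
                manifest.outputs[str(p.relative_to(out))] = _sha256(p)
            else:
                raise RuntimeError(f"stage {name!r} produced missing/empty output {p}")
        n_bad = sum(not f.converged for f in result.fits.values())
        log.info("%s: %d conditions, %d non-converged fits", name, len(result.fits), n_bad)

    manifest.save(out / "manifest.json")
    return manifest
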