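"""Threshold estimation: logistic psychometric fits, bootstrap SEs,
suppression statistics, and saturating/decaying exponential summaries.

Psychometric functions are fitted on log10 contrast with a binomial
likelihood,

    p(c) = guess + (1 - guess - lapse) * logistic(beta * (log10 c - log10 alpha)),

parameterized directly by the threshold ``alpha``: with guess = 0.5 and
lapse = 0 the fitted curve evaluated at ``alpha`` is exactly 75% correct,
the conventional 2AFC threshold criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize
from scipy.special import expit

__all__ = [
    "PsychometricFit",
    "BootstrapSE",
    "ExponentialFit",
    "fit_logistic",
    "bootstrap_se",
    "suppression_stats",
    "fit_saturating_exponential",
    "fit_decaying_exponential",
    "predict_proportion",
]

_LOGB_LO, _LOGB_HI = np.log(0.25), np.log(300.0)


@dataclass
class PsychometricFit:
    """Maximum-likelihood logistic fit of one psychometric function."""

    threshold: float  # Michelson %, 75%-correct point
    slope: float  # on log10 contrast
    n_trials: int
    converged: bool
    deviance: float
    guess_rate: float = 0.5
    lapse_rate: float = 0.0
    bootstrap_se: float | None = None
    flags: list[str] = field(default_factory=list)

    def predict(self, contrast: np.ndarray | float) -> np.ndarray | float:
        return predict_proportion(
            contrast, self.threshold, self.slope, self.guess_rate, self.lapse_rate
        )


@dataclass
class BootstrapSE:
    se: float
    n_boot: int
    n_failed: int
    reliable: bool


@dataclass
class ExponentialFit:
    """Least-squares fit of a saturating or decaying exponential.

    For the saturating form y = A*(1 - 2**(-x/x50)) the ``constant`` is the
    half point (semisaturation constant); for the decaying form
    y = A*exp(-x/lambda) it is the e-folding distance (space constant).
    """

    asymptote: float
    constant: float
    form: str  # 'saturating' | 'decaying'
    units: str
    residual_ss: float
    flags: list[str] = field(default_factory=list)

    def predict(self, x: np.ndarray | float):
        x = np.asarray(x, dtype=float)
        if self.form == "saturating":
            return self.asymptote * (1.0 - 2.0 ** (-x / self.constant))
        return self.asymptote * np.exp(-x / self.constant)


def predict_proportion(contrast, threshold, slope, guess_rate=0.5, lapse_rate=0.0):
    """Proportion correct under the anchored logistic model."""
    x = np.log10(np.asarray(contrast, dtype=float))
    q = expit(slope * (x - np.log10(threshold)))
    return guess_rate + (1.0 - guess_rate - lapse_rate) * q


def _aggregate(table: pd.DataFrame, condition: str | None) -> pd.DataFrame:
    df = table
    if condition is not None:
        df = df[df["condition"] == condition]
        if df.empty:
            raise ValueError(f"no trials for condition {condition!r}")
    if df.empty:
        raise ValueError("empty trial table")
    agg = (
        df.groupby("contrast")["correct"]
        .agg(n="count", k="sum")
        .reset_index()
        .sort_values("contrast")
    )
    return agg


def _nll(params, x, n, k, guess, lapse):
    m, logb = params
    q = expit(np.exp(logb) * (x - m))
    p = guess + (1.0 - guess - lapse) * q
    p = np.clip(p, 1e-10, 1.0 - 1e-10)
    return -np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p))


def _saturated_ll(n, k):
    with np.errstate(divide="ignore", invalid="ignore"):
        ph = k / n
        t1 = np.where(k > 0, k * np.log(np.where(ph > 0, ph, 1.0)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log(np.where(ph < 1, 1.0 - ph, 1.0)), 0.0)
    return float(np.sum(t1 + t2))


def fit_logistic(
    table: pd.DataFrame,
    condition: str | None = None,
    guess_rate: float = 0.5,
    lapse_rate: float = 0.0,
) -> PsychometricFit:
    """Fit one condition's trials; report the 75%-correct threshold directly.

    Uses a bounded quasi-Newton optimizer with a 3 x 3 multi-start grid of
    initial slopes and thresholds; ties are broken by lowest deviance then
    lowest threshold.  Degenerate data (all correct, or responses at chance
    throughout) yield a flagged fit with a NaN threshold; perfect
    separation is flagged and the threshold bracketed between the adjacent
    levels.
    """
    agg = _aggregate(table, condition)
    if len(agg) < 2:
        raise ValueError("need at least two distinct contrast levels")
    x = np.log10(agg["contrast"].to_numpy(dtype=float))
    n = agg["n"].to_numpy(dtype=float)
    k = agg["k"].to_numpy(dtype=float)
    n_trials = int(n.sum())

    if np.all(k == n) or np.all(k == 0):
        return PsychometricFit(
            threshold=np.nan, slope=np.nan, n_trials=n_trials, converged=False,
            deviance=np.nan, guess_rate=guess_rate, lapse_rate=lapse_rate,
            flags=["degenerate"],
        )

    starts_m = np.quantile(x, [0.25, 0.5, 0.75])
    starts_b = np.log([3.0, 10.0, 30.0])
    bounds = [(x.min() - 1.0, x.max() + 1.0), (_LOGB_LO, _LOGB_HI)]
    best = None
    for m0 in starts_m:
        for b0 in starts_b:
            res = minimize(
                _nll,
                np.array([m0, b0]),
                args=(x, n, k, guess_rate, lapse_rate),
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-10},
            )
            key = (res.fun, res.x[0])
            if best is None or key < (best.fun, best.x[0]):
                best = res
    assert best is not None
    m_hat, logb_hat = best.x
    deviance = 2.0 * (_saturated_ll(n, k) + best.fun)

    flags: list[str] = []
    threshold = 10.0**m_hat
    if m_hat <= bounds[0][0] + 1e-6 or m_hat >= bounds[0][1] - 1e-6:
        # threshold ran to the search boundary (e.g. responses at chance
        # throughout): no finite threshold is supported by the data
        return PsychometricFit(
            threshold=np.nan, slope=float(np.exp(logb_hat)), n_trials=n_trials,
            converged=False, deviance=float(2.0 * (_saturated_ll(n, k) + best.fun)),
            guess_rate=guess_rate, lapse_rate=lapse_rate, flags=["degenerate"],
        )
    if logb_hat >= np.log(100.0):
        # effectively perfect separation: the fitted transition is narrower
        # than any level spacing, so the slope (and threshold within the
        # spacing) is not identified; bracket between the adjacent levels
        flags.append("separation")
        below = x[x < m_hat]
        above = x[x >= m_hat]
        if below.size and above.size:
            threshold = 10.0 ** ((below.max() + above.min()) / 2.0)
    if not (x.min() <= m_hat <= x.max()):
        flags.append("extrapolated")
    return PsychometricFit(
        threshold=float(threshold),
        slope=float(np.exp(logb_hat)),
        n_trials=n_trials,
        converged=bool(best.success),
        deviance=float(deviance),
        guess_rate=guess_rate,
        lapse_rate=lapse_rate,
        flags=flags,
    )


def bootstrap_se(
    table: pd.DataFrame,
    condition: str | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    guess_rate: float = 0.5,
    lapse_rate: float = 0.0,
) -> BootstrapSE:
    """Nonparametric bootstrap SE of the threshold (Michelson %).

    Trials are resampled with replacement within each contrast level
    (preserving the constant-stimuli design), the fit repeated, and the
    standard deviation of the bootstrap threshold distribution returned.
    The SE is flagged unreliable if more than 10% of refits are degenerate.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    agg = _aggregate(table, condition)
    rng = np.random.default_rng(seed)
    n = agg["n"].to_numpy(dtype=int)
    k = agg["k"].to_numpy(dtype=int)
    levels = agg["contrast"].to_numpy(dtype=float)
    thresholds = []
    n_failed = 0
    for _ in range(n_boot):
        kb = rng.binomial(n, k / n)
        boot = pd.DataFrame(
            {
                "contrast": np.repeat(levels, n),
                "correct": np.concatenate(
                    [np.r_[np.ones(kk), np.zeros(nn - kk)] for nn, kk in zip(n, kb)]
                ),
            }
        )
        fit = fit_logistic(boot, None, guess_rate, lapse_rate)
        if np.isfinite(fit.threshold):
            thresholds.append(fit.threshold)
        else:
            n_failed += 1
    if not thresholds:
        return BootstrapSE(se=np.nan, n_boot=n_boot, n_failed=n_failed, reliable=False)
    se = float(np.std(thresholds, ddof=1))
    return BootstrapSE(
        se=se, n_boot=n_boot, n_failed=n_failed, reliable=n_failed <= 0.1 * n_boot
    )


def suppression_stats(threshold: float, baseline_threshold: float) -> dict:
    """Threshold elevation re baseline, in log10 units and percent."""
    if threshold <= 0 or baseline_threshold <= 0:
        raise ValueError("thresholds must be positive")
    ratio = threshold / baseline_threshold
    return {"log_units": float(np.log10(ratio)), "percent": float(100.0 * (ratio - 1.0))}


def _exp_fit(x, y, fun, p0, units, form, flag_limit):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    popt, _ = curve_fit(
        fun, x, y, p0=p0, bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=20000
    )
    a, c = popt
    resid = y - fun(x, a, c)
    flags = []
    if c > flag_limit:
        flags.append("non-saturating" if form == "saturating" else "non-decaying")
    return ExponentialFit(
        asymptote=float(a),
        constant=float(c),
        form=form,
        units=units,
        residual_ss=float(np.sum(resid**2)),
        flags=flags,
    )


def fit_saturating_exponential(x, y, units: str = "arcmin") -> ExponentialFit:
    """Fit y = A*(1 - 2**(-x/x50)); reports the half point x50.

    The half-life parameterization makes the reported constant exactly the
    semisaturation point (y(x50) = A/2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a0 = max(float(np.max(y)), 1e-6)
    half = a0 / 2.0
    above = np.nonzero(y >= half)[0]
    x50_0 = float(x[above[0]]) if above.size and x[above[0]] > 0 else max(float(np.median(x)), 1e-3)
    return _exp_fit(
        x, y, lambda x, a, c: a * (1.0 - 2.0 ** (-x / c)), [a0, x50_0],
        units, "saturating", flag_limit=2.0 * float(np.max(x)),
    )


def fit_decaying_exponential(x, y, units: str = "arcmin") -> ExponentialFit:
    """Fit y = A*exp(-x/lambda); reports the e-folding space constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a0 = max(float(np.max(y)), 1e-6)
    below = np.nonzero(y <= a0 / np.e)[0]
    lam0 = float(x[below[0]]) if below.size and x[below[0]] > 0 else max(float(np.median(x)), 1e-3)
    return _exp_fit(
        x, y, lambda x, a, c: a * np.exp(-x / c), [a0, lam0],
        units, "decaying", flag_limit=10.0 * float(np.max(x)),
    )
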