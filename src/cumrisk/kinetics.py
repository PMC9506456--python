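"""First-order dissipation kinetics.

Pesticide residues on growing crops decline approximately exponentially after
the last application:

    C(t) = C0 * exp(-k t),        t_1/2 = ln 2 / k

with C0 the initial deposition (mg/kg), k the degradation rate constant
(day^-1) and t_1/2 the half-life (days).  The conventional fit in dissipation
studies is ordinary least squares of ln C on t (the default here); an optional
nonlinear least-squares refinement on the concentration scale is initialized
from the log-linear estimate.  Both agree exactly on noiseless data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DecaySeries",
    "DecayFit",
    "fit_first_order",
    "degradation_percent",
    "predict_residue",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class DecaySeries:
    """A residue time-series for one analyte at one trial site."""

    analyte: str
    site: str
    times: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations differ in length")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class DecayFit:
    """A fitted first-order decay model.

    ``half_life`` is ln2/k by construction; it is NaN when the fitted series
    does not decay (k <= 0), flagged by ``decaying``.
    """

    analyte: str
    site: str
    c0: float
    k: float
    half_life: float
    r_squared: float
    method: str
    decaying: bool


def _make_fit(analyte: str, site: str, c0: float, k: float, r2: float, method: str) -> DecayFit:
    decaying = k > 0
    return DecayFit(
        analyte=analyte,
        site=site,
        c0=float(c0),
        k=float(k),
        half_life=_LN2 / k if decaying else float("nan"),
        r_squared=float(r2),
        method=method,
        decaying=decaying,
    )


def fit_first_order(series: DecaySeries, method: str = "log-linear") -> DecayFit:
    """Fit C(t) = C0 e^(-kt) to a residue time-series.

    method="log-linear": OLS of ln C on t; k = −slope, C0 = exp(intercept);
    R² reported on the log scale (the fitted scale).
    method="nonlinear": least squares on the exponential itself, initialized
    from the log-linear fit; R² on the concentration scale.

    Raises on fewer than 3 points, or on non-positive concentrations under
    the log-linear method (impute first, or use the nonlinear method).
    A fitted k <= 0 is returned flagged non-decaying with undefined half-life
    rather than raised.
    """
    t = np.asarray(series.times, dtype=float)
    c = np.asarray(series.concentrations, dtype=float)
    if t.size < 3:
        raise ValueError(f"need at least 3 time points to fit, got {t.size}")

    if method == "log-linear":
        if np.any(c <= 0):
            raise ValueError(
                "log-linear fit requires positive concentrations; impute "
                "censored values or use method='nonlinear'"
            )
        res = stats.linregress(t, np.log(c))
        return _make_fit(
            series.analyte, series.site,
            c0=math.exp(res.intercept), k=-res.slope,
            r2=res.rvalue**2, method=method,
        )

    if method == "nonlinear":
        if np.any(c <= 0):
            # initialize from a censored-safe crude slope instead
            c0_init, k_init = float(c.max()), 0.1
        else:
            lin = stats.linregress(t, np.log(c))
            c0_init, k_init = math.exp(lin.intercept), -lin.slope
        popt, _ = optimize.curve_fit(
            lambda tt, c0, k: c0 * np.exp(-k * tt),
            t, c, p0=[c0_init, k_init], maxfev=10000,
        )
        c0_hat, k_hat = popt
        fitted = c0_hat * np.exp(-k_hat * t)
        ss_res = float(np.sum((c - fitted) ** 2))
        ss_tot = float(np.sum((c - c.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot
        return _make_fit(series.analyte, series.site, c0_hat, k_hat, r2, method)

    raise ValueError(f"unknown method {method!r}; choose 'log-linear' or 'nonlinear'")


def degradation_percent(fit: DecayFit, t: float) -> float:
    """Percent of the initial deposition degraded after t days: 100(1 − e^(−kt))."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if not fit.decaying:
        raise ValueError("degradation percent undefined for a non-decaying fit")
    return 100.0 * (1.0 - math.exp(-fit.k * t))


def predict_residue(fit: DecayFit, t: float) -> float:
    """Predicted residue concentration C0·e^(−kt) at t days (mg/kg)."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return fit.c0 * math.exp(-fit.k * t)
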