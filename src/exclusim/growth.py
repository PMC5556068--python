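"""Logistic growth-curve fitting and density-ratio summaries.

The growth model is the three-parameter symmetric logistic
``N(t) = K / (1 + exp(-r (t - tau)))`` with carrying capacity K, growth rate
r (per unit of the time axis) and half-capacity time tau (``N(tau) = K/2``).
Simulation trajectories use Markov step counts as the time axis; these are
not experimental time units and fits on them are labeled accordingly by the
caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .dynamics import Trajectory
from .initial import logistic

__all__ = ["LogisticParams", "fit_logistic", "density_ratio_series", "carrying_capacity_ratio"]


@dataclass
class LogisticParams:
    """Fitted logistic parameters with standard errors from the Jacobian."""

    K: float
    growth_rate: float
    tau: float
    K_se: float
    growth_rate_se: float
    tau_se: float
    rss: float

    def predict(self, t):
        return logistic(t, self.K, self.growth_rate, self.tau)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    k0 = float(y.max())
    tau0 = float(t[int(np.argmin(np.abs(y - k0 / 2)))])
    # early-phase log-linear slope: N ~ K exp(r (t - tau)) while N << K
    early = y < 0.6 * k0
    if early.sum() >= 2 and (y[early] > 0).all():
        r0 = float(np.polyfit(t[early], np.log(y[early]), 1)[0])
        if not (r0 > 0 and np.isfinite(r0)):
            r0 = 1.0
    else:
        r0 = 1.0
    span = t.max() - t.min()
    r0 = min(max(r0, 1e-3 / max(span, 1e-12)), 1e3 / max(span, 1e-12))
    return k0, r0, tau0


def fit_logistic(times, values) -> LogisticParams:
    """Nonlinear least-squares fit of the three-parameter logistic curve.

    Requires at least four time points and a non-degenerate (non-flat,
    positive) response.  Standard errors come from the covariance of the
    Gauss-Newton Jacobian at the optimum.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) != len(y):
        raise ValueError("times and values must have equal length")
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if y.max() <= 0 or np.allclose(y, y[0]):
        raise ValueError("degenerate growth data: flat or non-positive values")
    p0 = _initial_guess(t, y)
    try:
        popt, pcov = curve_fit(logistic, t, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"logistic fit did not converge (start {p0}): {err}") from err
    k, r, tau = (float(v) for v in popt)
    if k <= 0 or r <= 0:
        raise RuntimeError(f"logistic fit converged to a non-growth solution K={k}, r={r}")
    ses = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    resid = y - logistic(t, *popt)
    return LogisticParams(
        K=k,
        growth_rate=r,
        tau=tau,
        K_se=float(ses[0]),
        growth_rate_se=float(ses[1]),
        tau_se=float(ses[2]),
        rss=float((resid**2).sum()),
    )


def density_ratio_series(
    traj: Trajectory,
    smooth_window: Optional[int] = None,
):
    """Type-2 : type-1 density ratio along a trajectory.

    Zero type-1 density yields NaN (a sentinel, not an exception).  With
    ``smooth_window`` the ratio is smoothed by a centered moving average of
    that many records (window echoed in the column name).

    Returns a pandas DataFrame with columns ``step``, ``ratio`` and
    optionally ``ratio_ma{w}``.
    """
    import pandas as pd

    out = pd.DataFrame({"step": traj.steps, "ratio": traj.ratio})
    if smooth_window is not None:
        if smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        out[f"ratio_ma{smooth_window}"] = (
            out["ratio"].rolling(smooth_window, center=True, min_periods=1).mean()
        )
    return out


def carrying_capacity_ratio(fit_a: LogisticParams, fit_b: LogisticParams) -> tuple[float, float]:
    """K_A / K_B with its first-order (delta-method) standard error."""
    ratio = fit_a.K / fit_b.K
    se = abs(ratio) * math.sqrt((fit_a.K_se / fit_a.K) ** 2 + (fit_b.K_se / fit_b.K) ** 2)
    return ratio, se
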