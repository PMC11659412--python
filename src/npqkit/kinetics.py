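"""Hyperbolic NPQ-induction kinetics and relative rates.

Light-phase quenching curves are fit to the rectangular hyperbola

    NPQ(t) = A * t / (t + K)

with amplitude A (asymptotic NPQ) and half-saturation time K (min). The
"NPQ induction rate" is the initial slope of this curve, A/K per minute —
the speed at which photoprotection engages at light-on. Chemical-
infiltration effects are expressed as the rate retained relative to the
solvent control (treated/control x 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateDataError, InsufficientDataError
from .fluor_core import NPQCurve
from .npq_adjust import NPQACurve

__all__ = [
    "HyperbolicFit",
    "RelativeRate",
    "fit_hyperbolic",
    "induction_rate",
    "relative_to_control",
    "fit_table",
]


@dataclass(frozen=True)
class HyperbolicFit:
    """Result of one rectangular-hyperbola fit."""

    amplitude: float          # asymptotic NPQ (dimensionless)
    half_time: float          # minutes to reach amplitude/2
    initial_slope: float      # amplitude/half_time, per minute
    rss: float
    n_points: int
    converged: bool
    degenerate: bool = False
    disc_id: str = ""
    curve_type: str = "npq"

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * t / (t + self.half_time)


@dataclass(frozen=True)
class RelativeRate:
    treated_rate: float
    control_rate: float
    relative_pct: float


def _hyperbola(t, a, k):
    return a * t / (t + k)


def fit_hyperbolic(curve: NPQCurve | NPQACurve, window: str = "light",
                   baseline: float | None = None) -> HyperbolicFit:
    """Least-squares fit of A*t/(t+K) over the selected phase window.

    Times are re-zeroed to light onset. Initialisation: A0 = max(NPQ),
    K0 = time to reach A0/2 by linear interpolation; bounds A in
    [0, 3*max], K in [0.01, 100] min. An all-zero (or non-positive) curve
    yields a degenerate fit with amplitude 0 rather than an optimiser run.

    An adjusted (NPQ_A) curve starts at its dark sustained-quenching value
    rather than at zero, while the through-origin hyperbola models the
    light-induced rise only. By default that offset — the curve's own dark
    point — is therefore subtracted before fitting, which recovers the
    induced amplitude and half-time exactly (the induced component of
    NPQ_A is algebraically a rectangular hyperbola). Pass ``baseline`` to
    override (0.0 fits the raw values).
    """
    if window == "light":
        pts = [p for p in curve.points if p.phase == "light"]
    elif window == "all":
        pts = list(curve.points)
    else:
        raise ValueError(f"unknown window {window!r}")
    if len(pts) < 4:
        raise InsufficientDataError(
            f"disc {curve.disc_id}: {len(pts)} points in window {window!r}; need >= 4"
        )
    if baseline is None:
        baseline = curve.npq_a_dark if isinstance(curve, NPQACurve) else 0.0
    t = np.array([p.time_min for p in pts], dtype=float) - curve.light_on_min
    y = np.array([p.npq for p in pts], dtype=float) - baseline
    curve_type = "npq_a" if isinstance(curve, NPQACurve) else "npq"

    ymax = float(np.max(y))
    if ymax <= 0:
        return HyperbolicFit(amplitude=0.0, half_time=np.inf, initial_slope=0.0,
                             rss=float(np.sum(y**2)), n_points=len(pts),
                             converged=True, degenerate=True,
                             disc_id=curve.disc_id, curve_type=curve_type)

    k0 = _half_rise_time(t, y, ymax)
    try:
        popt, _ = curve_fit(
            _hyperbola, t, y,
            p0=[ymax, k0],
            bounds=([0.0, 0.01], [3.0 * ymax, 100.0]),
            maxfev=10000,
        )
        a, k = float(popt[0]), float(popt[1])
        rss = float(np.sum((y - _hyperbola(t, a, k)) ** 2))
        return HyperbolicFit(amplitude=a, half_time=k, initial_slope=a / k,
                             rss=rss, n_points=len(pts), converged=True,
                             disc_id=curve.disc_id, curve_type=curve_type)
    except RuntimeError:
        return HyperbolicFit(amplitude=np.nan, half_time=np.nan,
                             initial_slope=np.nan, rss=np.nan, n_points=len(pts),
                             converged=False, disc_id=curve.disc_id,
                             curve_type=curve_type)


def _half_rise_time(t: np.ndarray, y: np.ndarray, ymax: float) -> float:
    """Linear-interpolation estimate of the time to reach half the maximum."""
    half = ymax / 2.0
    above = np.nonzero(y >= half)[0]
    if len(above) == 0 or above[0] == 0:
        return max(float(t[1] - t[0]), 0.01) if len(t) > 1 else 1.0
    j = above[0]
    t0, t1 = t[j - 1], t[j]
    y0, y1 = y[j - 1], y[j]
    if y1 == y0:
        return max(float(t1), 0.01)
    return max(float(t0 + (half - y0) * (t1 - t0) / (y1 - y0)), 0.01)


def induction_rate(fit: HyperbolicFit) -> float:
    """Initial slope A/K of the fitted hyperbola (the induction rate).

    Degenerate (flat-zero) fits return 0; unconverged fits raise.
    """
    if fit.degenerate:
        return 0.0
    if not fit.converged:
        raise DegenerateDataError(
            f"disc {fit.disc_id}: fit did not converge; no induction rate"
        )
    return fit.initial_slope


def relative_to_control(treated: HyperbolicFit, control: HyperbolicFit,
                        mode: str = "ratio") -> RelativeRate:
    """Induction rate of a treated disc group relative to its solvent control.

    ``mode="ratio"`` (default) reports the retained fraction,
    100 * treated/control; ``mode="change"`` reports the percent change,
    100 * (treated - control)/control.
    """
    tr = induction_rate(treated)
    cr = induction_rate(control)
    if cr == 0:
        raise ZeroDivisionError("control induction rate is 0; relative rate undefined")
    if mode == "ratio":
        pct = 100.0 * tr / cr
    elif mode == "change":
        pct = 100.0 * (tr - cr) / cr
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return RelativeRate(treated_rate=tr, control_rate=cr, relative_pct=pct)


def fit_table(fits: list[HyperbolicFit]) -> pd.DataFrame:
    """Tidy per-disc fit results (one row per disc and curve type)."""
    return pd.DataFrame(
        [
            {
                "disc_id": f.disc_id,
                "curve_type": f.curve_type,
                "amplitude": f.amplitude,
                "half_time": f.half_time,
                "initial_slope": f.initial_slope,
                "rss": f.rss,
                "n_points": f.n_points,
                "converged": f.converged,
                "degenerate": f.degenerate,
            }
            for f in fits
        ]
    )
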