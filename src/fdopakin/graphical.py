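"""Logan graphical analysis with plasma input or a reference region.

For a reversible tracer the Logan transform

    y_k = int_0^{t_k} C_T(tau) dtau / C_T(t_k)
    x_k = int_0^{t_k} C_in(tau) dtau / C_T(t_k)

becomes linear at late times; its slope estimates the equilibrium volume
of distribution (Ved, with plasma input) or the distribution-volume
ratio (DVR, with a healthy-brain reference region).  The intercept is
reported as Int_Logan (plasma input) or, negated, as the relative
residence time RRT (reference input).  The regression window defaults to
15-30 min post-injection.  Integrals use the trapezoidal rule on the
frame-midpoint grid augmented with the origin (0, 0); the reference-Logan
form omits the population k2' correction term, whose late-window bias is
absorbed into the reported intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import linregress

from .tac import TAC

__all__ = ["LoganResult", "RefLoganResult", "logan_transform", "logan_fit", "logan", "ref_logan"]

DEFAULT_WINDOW_MIN = (15.0, 30.0)


@dataclass(frozen=True)
class LoganResult:
    """Plasma-input Logan estimates: Ved (slope) and Int_Logan (intercept, min)."""

    ved: float
    int_logan: float
    r_squared: float
    window_min: tuple


@dataclass(frozen=True)
class RefLoganResult:
    """Reference-region Logan estimates: DVR (slope) and RRT (minus intercept, min)."""

    dvr: float
    rrt: float
    r_squared: float
    window_min: tuple


def _integrate_with_origin(t_min: np.ndarray, values: np.ndarray) -> np.ndarray:
    t = np.concatenate([[0.0], t_min])
    v = np.concatenate([[0.0], values])
    return cumulative_trapezoid(v, t)


def logan_transform(tumor: TAC, plasma, window_min=DEFAULT_WINDOW_MIN):
    """Logan coordinates (x_k, y_k, t_k) at tumor frame midpoints.

    ``plasma`` is a continuous input curve (callable of minutes) or an
    array of values already sampled at the tumor frame midpoints.
    """
    t = tumor.midpoints_min
    ct = tumor.values
    in_window = (t >= window_min[0]) & (t <= window_min[1])
    if np.any(ct[in_window] <= 0):
        frame = int(np.flatnonzero(in_window & (ct <= 0))[0])
        raise ValueError(f"non-positive tumor value in the regression window at frame {frame}")
    cp = np.asarray(plasma(t) if callable(plasma) else plasma, dtype=float)
    int_ct = _integrate_with_origin(t, ct)
    int_cp = _integrate_with_origin(t, cp)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = int_ct / ct
        x = int_cp / ct
    return x, y, t


def logan_fit(x, y, t_min, window_min=DEFAULT_WINDOW_MIN) -> LoganResult:
    """OLS of y on x restricted to frame midpoints inside the window."""
    t = np.asarray(t_min, dtype=float)
    mask = (t >= window_min[0]) & (t <= window_min[1])
    if int(mask.sum()) < 3:
        raise ValueError(f"need >= 3 regression points in window {window_min}, got {int(mask.sum())}")
    xs, ys = np.asarray(x)[mask], np.asarray(y)[mask]
    if np.ptp(xs) == 0:
        # degenerate abscissa: slope undefined; flag with NaN r^2
        return LoganResult(0.0, float(np.mean(ys)), float("nan"), tuple(window_min))
    res = linregress(xs, ys)
    return LoganResult(float(res.slope), float(res.intercept), float(res.rvalue) ** 2, tuple(window_min))


def logan(tumor: TAC, plasma, window_min=DEFAULT_WINDOW_MIN) -> LoganResult:
    """Plasma-input Logan analysis of a tumor TAC."""
    x, y, t = logan_transform(tumor, plasma, window_min)
    return logan_fit(x, y, t, window_min)


def ref_logan(tumor: TAC, reference: TAC, window_min=DEFAULT_WINDOW_MIN) -> RefLoganResult:
    """Reference-region Logan analysis (DVR = slope, RRT = -intercept)."""
    if tumor.schedule != reference.schedule:
        raise ValueError("tumor and reference TACs must share the same frame schedule")
    x, y, t = logan_transform(tumor, reference.values, window_min)
    fit = logan_fit(x, y, t, window_min)
    return RefLoganResult(fit.ved, -fit.int_logan, fit.r_squared, fit.window_min)
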