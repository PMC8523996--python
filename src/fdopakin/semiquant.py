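"""Semiquantitative dynamic analysis (SQ, SQ Fit, Ref SQ).

Tumor (and healthy-brain reference) TACs are first denoised by fitting a
parametric vascularization curve

    SUV(t) = 0                                   for t <  t*
    SUV(t) = a0 + (a1 - a0) (A + x^p)/(B + x^q)  for t >= t*,  x = (t - t*)/a2

with t* the tracer-arrival delay, a0 the baseline fixed at 0, a1 the
uptake scale, a2 a time scale in seconds ("time to peak intensity"),
p/q shape exponents of the rising/declining limbs and A, B arbitrary
constants (B > 0).  From the fitted curve the model extracts

* TTP  — time from acquisition start to the curve maximum (minutes,
  argmax on a dense 1-s grid, earliest time on ties);
* slope — ordinary-least-squares slope of the curve over the 10-30-min
  window, reported in SUV/h.

The Ref SQ variant applies the same two read-outs to the ratio of the
fitted tumor and reference curves (TTP_ratio in minutes, slope_ratio in
1/h).  SQ Fit exports the six free fit parameters (a1, a2, p, q, A, B)
as candidate predictors in their own right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .tac import TAC, dense_grid_minutes, tac_ratio

__all__ = [
    "VascFitParams",
    "SQResult",
    "RefSQResult",
    "vasc_function",
    "fit_vascularization",
    "compute_ttp",
    "compute_slope",
    "sq_result",
    "ref_sq",
]


@dataclass(frozen=True)
class VascFitParams:
    """Parameters of the tumor vascularization fit (a0 fixed at 0)."""

    t_star_min: float
    a1: float
    a2_s: float
    p: float
    q: float
    A: float
    B: float
    rss: float = float("nan")  # residual sum of squares of the fit

    def __post_init__(self) -> None:
        if self.a2_s <= 0 or self.p <= 0 or self.q <= 0 or self.B <= 0 or self.t_star_min < 0:
            raise ValueError("require a2 > 0, p > 0, q > 0, B > 0 and t_star >= 0")

    def __call__(self, t_min):
        return vasc_function(t_min, self)


def vasc_function(t_min, params: VascFitParams):
    """Evaluate the vascularization curve at ``t_min`` (minutes)."""
    t = np.asarray(t_min, dtype=float)
    x = np.clip((t - params.t_star_min) * 60.0, 0.0, None) / params.a2_s
    with np.errstate(over="ignore"):
        value = params.a1 * (params.A + x**params.p) / (params.B + x**params.q)
    out = np.where(t < params.t_star_min, 0.0, value)
    return out if out.shape else float(out)


def _pack(x):
    t_star, a1, log_a2, log_p, log_q, A, log_B = x
    return VascFitParams(t_star, a1, np.exp(log_a2), np.exp(log_p), np.exp(log_q), A, np.exp(log_B))


def fit_vascularization(tac: TAC, n_starts: int = 12, seed: int = 0) -> VascFitParams:
    """Multistart nonlinear least-squares fit of the vascularization curve.

    Starts combine a1 = max observed SUV and a2 = observed peak time with
    shape exponents p, q in {0.5, 1, 2}, A = 0, B = 1, plus seeded jitter.
    Positivity of a2, p, q, B is enforced by optimizing their logarithms.
    The surface is degenerate in parameter space, so downstream checks
    should be made at the curve level, not the parameter level.
    """
    t = tac.midpoints_min
    obs = tac.values
    scale = max(float(np.max(np.abs(obs))), 1e-9)

    def residuals(x):
        return vasc_function(t, _pack(x)) - obs

    peak_t_s = max(60.0 * t[int(np.argmax(obs))], 30.0)
    rng = np.random.default_rng(seed)
    starts = []
    for p0 in (0.5, 1.0, 2.0):
        for q0 in (0.5, 1.0, 2.0):
            starts.append([0.25, max(np.max(obs), 1e-3), np.log(peak_t_s), np.log(p0), np.log(q0), 0.0, 0.0])
    while len(starts) < max(n_starts, 9):
        starts.append(
            [
                rng.uniform(0.0, 1.0),
                max(np.max(obs), 1e-3) * rng.uniform(0.5, 2.0),
                np.log(peak_t_s * rng.uniform(0.3, 3.0)),
                rng.uniform(np.log(0.3), np.log(3.0)),
                rng.uniform(np.log(0.3), np.log(3.0)),
                rng.normal(0.0, 0.1),
                rng.normal(0.0, 0.5),
            ]
        )

    lower = np.array([0.0, 0.0, np.log(1.0), np.log(1e-2), np.log(1e-2), -50.0, np.log(1e-6)])
    upper = np.array([5.0, 10.0 * scale, np.log(3600.0 * 10), np.log(10.0), np.log(10.0), 50.0, np.log(1e3)])
    best = None
    diagnostics = []
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lower, upper)
        try:
            sol = least_squares(residuals, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception as exc:  # pragma: no cover
            diagnostics.append(str(exc))
            continue
        diagnostics.append(f"cost {sol.cost:.6g} status {sol.status}")
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("vascularization fit failed from every start:\n" + "\n".join(diagnostics))
    params = _pack(best.x)
    return VascFitParams(
        params.t_star_min, params.a1, params.a2_s, params.p, params.q, params.A, params.B,
        rss=2.0 * float(best.cost),
    )


def compute_ttp(curve, grid_min: np.ndarray | None = None) -> float:
    """Time-to-peak: argmax of the curve on the dense grid, minutes.

    ``curve`` is a callable of time in minutes or a pre-evaluated array on
    ``grid_min``.  Ties resolve to the earliest time.
    """
    t = dense_grid_minutes() if grid_min is None else np.asarray(grid_min, dtype=float)
    values = np.asarray(curve(t) if callable(curve) else curve, dtype=float)
    return float(t[int(np.argmax(values))])


def compute_slope(curve, grid_min: np.ndarray | None = None, window_min=(10.0, 30.0)) -> float:
    """OLS slope of the curve over the late window, in per-hour units."""
    t = dense_grid_minutes() if grid_min is None else np.asarray(grid_min, dtype=float)
    values = np.asarray(curve(t) if callable(curve) else curve, dtype=float)
    mask = (t >= window_min[0]) & (t <= window_min[1])
    tw, vw = t[mask], values[mask]
    slope_per_min = np.polyfit(tw, vw, 1)[0]
    return float(slope_per_min * 60.0)


@dataclass(frozen=True)
class SQResult:
    """TTP (min) and late slope (SUV/h) of a fitted tumor curve."""

    ttp: float
    slope: float


@dataclass(frozen=True)
class RefSQResult:
    """TTP_ratio (min) and slope_ratio (1/h) of the tumor/brain ratio curve."""

    ttp_ratio: float
    slope_ratio: float


def sq_result(fit: VascFitParams, use_fit: bool = True, tac: TAC | None = None) -> SQResult:
    """SQ read-outs from a fitted curve (default) or raw frames.

    With ``use_fit=False`` the TTP/slope are taken directly from the frame
    values of ``tac`` (noise-sensitive fallback).
    """
    if use_fit:
        return SQResult(ttp=compute_ttp(fit), slope=compute_slope(fit))
    if tac is None:
        raise ValueError("raw-frame read-out requires the TAC")
    t = tac.midpoints_min
    return SQResult(ttp=compute_ttp(tac.values, t), slope=compute_slope(tac.values, t))


def ref_sq(tumor_fit: VascFitParams, reference_fit: VascFitParams) -> RefSQResult:
    """SQ read-outs applied to the fitted tumor/reference ratio curve.

    The reference curve is zero before its arrival delay (and may cross
    zero just after it when the fitted A is slightly negative), so the
    ratio is evaluated from the point where the reference first exceeds
    1% of its maximum; it must stay strictly positive from there on.
    """
    t_full = dense_grid_minutes()
    ref_values = np.asarray(reference_fit(t_full), dtype=float)
    if np.max(ref_values) <= 0:
        raise ValueError("reference curve is non-positive everywhere")
    start = int(np.argmax(ref_values > 0.01 * np.max(ref_values)))
    grid = t_full[start:]
    t, ratio = tac_ratio(tumor_fit, reference_fit, grid)
    return RefSQResult(ttp_ratio=compute_ttp(ratio, t), slope_ratio=compute_slope(ratio, t))
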