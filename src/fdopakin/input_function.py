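"""Image-derived input function for dynamic 18F-FDOPA PET.

The internal-carotid blood TAC is converted into the plasma 18F-FDOPA
input function in four steps:

1. parametric fit of the blood curve — linear interpolation up to the
   peak, tri-exponential decay afterwards, continuous at the junction;
2. spill-out (partial-volume) correction by a scalar recovery
   coefficient (default 0.51): the measured carotid curve under-recovers
   true activity, so the fitted curve is divided by the coefficient;
3. whole-blood to plasma conversion by division by (1 - hematocrit)
   (default hematocrit 0.40), i.e. assuming the tracer resides in plasma;
4. metabolite correction: the plasma parent fraction f_DOPA(t) from
   published population curves for Carbidopa-premedicated subjects
   multiplies the plasma curve, removing OMFD and other labelled
   metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .tac import TAC

__all__ = [
    "BloodFitModel",
    "InputFunctionConfig",
    "PlasmaInputModel",
    "fit_blood_tac",
    "spill_out_correct",
    "metabolite_fractions",
    "build_plasma_input",
]

# Population plasma-fraction model coefficients (t in minutes).
_FD_AMP = 0.36902735
_FD_L1 = 0.03915133
_FD_L2 = 0.03915214
_FO_A1 = 0.24080881
_FO_L1 = 0.03251229
_FO_A2 = 0.43768904
_FO_L2 = 0.03251228


def metabolite_fractions(t_min):
    """Plasma fractions (f_DOPA, f_OMFD, f_METS) at time ``t_min`` (minutes).

    The parent fraction decays from 1 at injection toward
    1 - 2 x 0.36902735 = 0.2619453; the OMFD fraction rises from 0 toward
    0.67849785; f_METS is defined as the complement so the three fractions
    sum to one exactly.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("metabolite fractions are defined for t >= 0 only")
    f_dopa = 1.0 - _FD_AMP * (2.0 - np.exp(-_FD_L1 * t) - np.exp(-_FD_L2 * t))
    f_omfd = _FO_A1 * (1.0 - np.exp(-_FO_L1 * t)) + _FO_A2 * (1.0 - np.exp(-_FO_L2 * t))
    f_mets = 1.0 - f_omfd - f_dopa
    return f_dopa, f_omfd, f_mets


@dataclass(frozen=True)
class BloodFitModel:
    """Fitted carotid blood curve (uncorrected SUV scale).

    Piecewise: linear interpolation through the pre-peak nodes up to
    ``peak_time_min``, then ``sum_i amplitudes[i] * exp(-rates[i] * (t - peak))``.
    The junction node value equals the amplitude sum, so the curve is
    continuous at the peak by construction.
    """

    peak_time_min: float
    node_times_min: np.ndarray  # ascending, last == peak_time_min
    node_values: np.ndarray
    amplitudes: np.ndarray  # SUV, >= 0, shape (3,)
    rates: np.ndarray  # min^-1, > 0, shape (3,)

    def __post_init__(self) -> None:
        for name in ("node_times_min", "node_values", "amplitudes", "rates"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.rates <= 0):
            raise ValueError("tri-exponential decay rates must be positive")
        if np.any(self.amplitudes < 0):
            raise ValueError("tri-exponential amplitudes must be non-negative")
        if abs(self.node_times_min[-1] - self.peak_time_min) > 1e-12:
            raise ValueError("last linear node must sit at the peak time")
        if abs(self.node_values[-1] - self.amplitudes.sum()) > 1e-9 * max(1.0, self.amplitudes.sum()):
            raise ValueError("curve is discontinuous at the peak")

    def __call__(self, t_min):
        t = np.asarray(t_min, dtype=float)
        pre = np.interp(t, self.node_times_min, self.node_values, left=0.0)
        post = np.exp(-np.outer(t - self.peak_time_min, self.rates)) @ self.amplitudes
        out = np.where(t <= self.peak_time_min, pre, post)
        return out if out.shape else float(out)

    def cumulative_integral(self, t_min):
        """Exact integral of the curve from 0 to ``t_min`` (SUV * min)."""
        t = np.atleast_1d(np.asarray(t_min, dtype=float))
        nodes_t = self.node_times_min
        nodes_v = self.node_values
        # cumulative trapezoid over the linear nodes
        seg = np.concatenate([[0.0], np.cumsum(0.5 * (nodes_v[1:] + nodes_v[:-1]) * np.diff(nodes_t))])
        # exact partial trapezoid inside a segment
        idx = np.clip(np.searchsorted(nodes_t, t, side="right") - 1, 0, len(nodes_t) - 2)
        t0, t1 = nodes_t[idx], nodes_t[idx + 1]
        v0, v1 = nodes_v[idx], nodes_v[idx + 1]
        frac = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
        inside = seg[idx] + (t - t0) * (v0 + 0.5 * frac * (v1 - v0))
        pre_part = np.where(t <= nodes_t[-1], np.where(t >= nodes_t[0], inside, 0.0), seg[-1])
        tau = np.clip(t - self.peak_time_min, 0.0, None)
        post_part = (-np.expm1(-np.outer(tau, self.rates)) / self.rates) @ self.amplitudes
        out = pre_part + post_part
        return out if np.ndim(t_min) else float(out[0])

    def frame_averages(self, schedule) -> np.ndarray:
        """Exact frame-averaged values of the continuous curve."""
        upper = self.cumulative_integral(schedule.frame_end / 60.0)
        lower = self.cumulative_integral(schedule.frame_start / 60.0)
        return (upper - lower) / (schedule.frame_duration / 60.0)


@dataclass(frozen=True)
class InputFunctionConfig:
    """Scalar corrections applied to the fitted blood curve."""

    spill_out_coefficient: float = 0.51
    hematocrit: float = 0.40
    n_multistarts: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.spill_out_coefficient <= 1):
            raise ValueError("spill_out_coefficient must be in (0, 1]")
        if not (0 < self.hematocrit < 1):
            raise ValueError("hematocrit must be in (0, 1)")


def spill_out_correct(values, config: InputFunctionConfig):
    """Divide measured carotid activity by the recovery coefficient."""
    if config.spill_out_coefficient <= 0:
        raise ValueError("spill-out coefficient must be positive")
    return np.asarray(values, dtype=float) / config.spill_out_coefficient


def _triexp_frame_avg(params: np.ndarray, peak_min: float, start_min: np.ndarray, end_min: np.ndarray) -> np.ndarray:
    """Frame averages of sum_i A_i exp(-l_i (t - peak)) over [start, end]."""
    amps, rates = params[:3], params[3:]
    t0 = start_min[:, None] - peak_min
    t1 = end_min[:, None] - peak_min
    integral = (np.exp(-rates * t0) - np.exp(-rates * t1)) / rates
    return (integral @ amps) / (end_min - start_min)


def fit_blood_tac(blood: TAC, n_starts: int = 8, seed: int = 0) -> BloodFitModel:
    """Fit linear-to-peak / tri-exponential-after-peak model to a blood TAC.

    The peak is the maximum observed frame value (earliest frame on ties).
    Tri-exponential amplitudes and rates are estimated by multistart
    nonlinear least squares on frame-averaged model values over the
    post-peak frames; the pre-peak curve interpolates the observed frame
    midpoints, with the junction node at the peak midpoint set to the
    fitted amplitude sum (continuity by construction).
    """
    values = blood.values
    if np.all(values <= 0):
        raise ValueError("blood TAC has no peak (all values <= 0)")
    mid = blood.midpoints_min
    peak_idx = int(np.argmax(values))
    n_post = values.size - peak_idx - 1
    if n_post < 6:
        raise ValueError(
            f"peak in frame {peak_idx} leaves only {n_post} descending frames; "
            "need at least 6 after the peak"
        )
    peak_min = float(mid[peak_idx])
    peak_val = float(values[peak_idx])
    start_min = blood.schedule.frame_start[peak_idx + 1 :] / 60.0
    end_min = blood.schedule.frame_end[peak_idx + 1 :] / 60.0
    obs = values[peak_idx + 1 :]

    def residuals(x):
        return _triexp_frame_avg(np.abs(x), peak_min, start_min, end_min) - obs

    rng = np.random.default_rng(seed)
    base_rates = np.array([3.0, 0.3, 0.03])
    starts = [np.concatenate([peak_val * np.array([0.5, 0.3, 0.2]), base_rates])]
    for _ in range(max(0, n_starts - 1)):
        fracs = rng.dirichlet(np.ones(3))
        rates = np.sort(10 ** rng.uniform(-2, 1, size=3))[::-1]
        starts.append(np.concatenate([peak_val * fracs, rates]))

    lower = np.concatenate([np.zeros(3), np.full(3, 1e-5)])
    upper = np.concatenate([np.full(3, 10 * max(peak_val, 1e-6)), np.full(3, 100.0)])
    best = None
    diagnostics = []
    for x0 in starts:
        x0 = np.clip(x0, lower + 1e-12, upper - 1e-12)
        try:
            sol = least_squares(residuals, x0, bounds=(lower, upper), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception as exc:  # pragma: no cover - scipy failures are rare
            diagnostics.append(f"start {x0}: {exc}")
            continue
        diagnostics.append(f"start cost {sol.cost:.6g} (status {sol.status})")
        if sol.status > 0 and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("tri-exponential blood fit did not converge from any start:\n" + "\n".join(diagnostics))

    amps, rates = np.abs(best.x[:3]), best.x[3:]
    order = np.argsort(rates)[::-1]
    amps, rates = amps[order], np.maximum(rates[order], 1e-12)

    node_t = np.concatenate([[0.0], mid[:peak_idx], [peak_min]])
    node_v = np.concatenate([[0.0], values[:peak_idx], [amps.sum()]])
    keep = np.concatenate([[True], np.diff(node_t) > 0])
    return BloodFitModel(peak_min, node_t[keep], node_v[keep], amps, rates)


@dataclass(frozen=True)
class PlasmaInputModel:
    """Continuous corrected blood curve and plasma parent-tracer curve.

    ``whole_blood(t)`` is the spill-out-corrected fitted carotid curve;
    ``plasma_fdopa(t) = whole_blood(t) / (1 - hematocrit) * f_DOPA(t)``.
    """

    blood_fit: BloodFitModel
    config: InputFunctionConfig

    def whole_blood(self, t_min):
        return spill_out_correct(self.blood_fit(t_min), self.config)

    def plasma_total(self, t_min):
        """Total plasma activity (parent + metabolites)."""
        return self.whole_blood(t_min) / (1.0 - self.config.hematocrit)

    def plasma_fdopa(self, t_min):
        f_dopa, _, _ = metabolite_fractions(t_min)
        return self.plasma_total(t_min) * f_dopa


def build_plasma_input(blood_fit: BloodFitModel, config: InputFunctionConfig | None = None) -> PlasmaInputModel:
    """Assemble the plasma 18F-FDOPA input model from a fitted blood curve."""
    return PlasmaInputModel(blood_fit, config or InputFunctionConfig())
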