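"""Forward simulation of fitted local-model families and model comparison.

The dynamic family is simulated per cell as a one-state ODE driven by the
(smoothed, continuous-time) factor trajectories: within each measurement
interval the cell's local model is held fixed, and beyond a chosen freeze
index the last fitted model is reused — matching the convention of deriving
the model from early time points only and predicting the remainder. The
static baseline predicts the target level directly from measured factor
concentrations at each time. Both are compared through an L1 error map
against the measured pattern and a percent-improvement summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embryo import ModelBundle, VirtualEmbryo
from .presmooth import presmooth_embryo

__all__ = [
    "SimulationResult",
    "rk4_integrate",
    "simulate_node",
    "simulate_linear_model",
    "predict_spatial_corr",
    "total_error",
    "percent_improvement",
    "compare_models",
]


@dataclass
class SimulationResult:
    """Simulated target pattern and its deviation from the measured one."""

    times: np.ndarray               # (T,) measurement times
    y_sim: np.ndarray               # (T, E)
    y_measured: np.ndarray | None   # (T, E)
    error_map: np.ndarray | None    # (T, E) absolute differences
    integrator_log: dict = field(default_factory=dict)


def rk4_integrate(rhs, y0, t0: float, t1: float, n_steps: int):
    """Classical fixed-step RK4 from t0 to t1; rhs(t, y) may be vectorized."""
    y = np.asarray(y0, dtype=float).copy()
    h = (t1 - t0) / n_steps
    t = t0
    for _ in range(n_steps):
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2, y + h / 2 * k1)
        k3 = rhs(t + h / 2, y + h / 2 * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y


def simulate_linear_model(A, b, xi, y0, t0: float, t1: float,
                          n_steps: int = 100) -> np.ndarray:
    """Integrate dx/dt = A (x - xi) + b with RK4 (general linearized form)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    xi = np.atleast_1d(np.asarray(xi, dtype=float))

    def rhs(t, x):
        return A @ (x - xi) + b

    return rk4_integrate(rhs, np.atleast_1d(y0), t0, t1, n_steps)


def _model_arrays_by_time(bundle: ModelBundle, E: int):
    """Per-fit-time (E, p) coefficient arrays; bundle must cover all cells."""
    p = len(bundle.factors)
    Tf = bundle.fit_times.size
    A = np.full((Tf, E, p), np.nan)
    B = np.full((Tf, E), np.nan)
    X0 = np.full((Tf, E, p), np.nan)
    A[bundle.anchor_t, bundle.anchor_e] = bundle.coeffs
    B[bundle.anchor_t, bundle.anchor_e] = bundle.intercept
    X0[bundle.anchor_t, bundle.anchor_e] = bundle.anchor_x
    if np.isnan(B).any():
        raise ValueError("bundle does not cover the full (fit time, cell) grid; "
                         "simulation needs one local model per cell and fit time")
    return A, B, X0


def simulate_node(bundle: ModelBundle, embryo: VirtualEmbryo,
                  t0_index: int = 0, freeze_after: int | None = None,
                  steps_per_unit: int = 100,
                  factor_source: str = "smoothed") -> SimulationResult:
    """Simulate the target pattern from measured factors and a dynamic bundle.

    Initial condition: the measured target at ``embryo.times[t0_index]``
    (recorded exactly in the output). For continuous t in the interval
    [t_k, t_{k+1}) each cell uses the local model of fit-time index
    min(k, freeze_after); ``freeze_after`` defaults to the last fitted time,
    reproducing the frozen-model convention when the model was fit on early
    times only. Factor inputs are the presmoothed polynomial trajectories
    evaluated at continuous t ('smoothed') or linear interpolation of the
    raw measurements ('interp'). Simulated concentrations are not clipped
    at zero; negativity is reported in the integrator log.
    """
    if bundle.response_kind != "derivative":
        raise ValueError("simulate_node requires a dynamic (derivative) bundle")
    times = embryo.times
    T, E = embryo.n_times, embryo.n_cells
    y_meas = embryo.get(bundle.target)
    A, B, X0 = _model_arrays_by_time(bundle, E)
    # map embryo time index -> fit-time index (largest fitted time <= t_k)
    fit_idx_of = np.searchsorted(bundle.fit_times, times + 1e-12) - 1
    fit_idx_of = np.clip(fit_idx_of, 0, bundle.fit_times.size - 1)
    if freeze_after is None:
        freeze_after = int(bundle.fit_times.size - 1)

    if factor_source == "smoothed":
        r = min(bundle.tuning.r, T - 1)
        smoothed = presmooth_embryo(embryo, bundle.target, bundle.factors, r=r)

        def factors_at(t):
            return smoothed.eval_factors(t)          # (p, E)
    elif factor_source == "interp":
        x_raw = np.stack([embryo.get(f) for f in bundle.factors])  # (p, T, E)

        def factors_at(t):
            # piecewise-linear interpolation of the raw measurements
            k = int(np.clip(np.searchsorted(times, t) - 1, 0, T - 2))
            frac = (t - times[k]) / (times[k + 1] - times[k])
            frac = min(max(frac, 0.0), 1.0)
            return (1 - frac) * x_raw[:, k, :] + frac * x_raw[:, k + 1, :]
    else:
        raise ValueError(f"unknown factor_source {factor_source!r}")

    y_sim = np.full((T, E), np.nan)
    y_sim[t0_index] = y_meas[t0_index]
    y = y_meas[t0_index].copy()
    freeze_schedule = []
    for k in range(t0_index, T - 1):
        model_idx = min(int(fit_idx_of[k]), int(freeze_after))
        freeze_schedule.append({"interval": [float(times[k]), float(times[k + 1])],
                                "model_time_index": model_idx,
                                "model_time": float(bundle.fit_times[model_idx])})
        a_k = A[model_idx]                           # (E, p)
        b_k = B[model_idx]                           # (E,)
        x0_k = X0[model_idx]                         # (E, p)

        def rhs(t, yv, a_k=a_k, b_k=b_k, x0_k=x0_k):
            x_t = factors_at(t).T                    # (E, p)
            return np.einsum("ep,ep->e", a_k, x_t - x0_k) + b_k

        n_steps = max(1, int(np.ceil(steps_per_unit * (times[k + 1] - times[k]))))
        y = rk4_integrate(rhs, y, float(times[k]), float(times[k + 1]), n_steps)
        y_sim[k + 1] = y
    filled = ~np.isnan(y_sim).any(axis=1)
    error_map = np.abs(y_sim - y_meas)
    log = {"method": "rk4", "steps_per_unit": steps_per_unit,
           "freeze_after": int(freeze_after), "freeze_schedule": freeze_schedule,
           "factor_source": factor_source,
           "min_value": float(np.nanmin(y_sim[filled])) if filled.any() else None,
           "n_negative": int((y_sim[filled] < 0).sum())}
    return SimulationResult(times=times, y_sim=y_sim, y_measured=y_meas,
                            error_map=error_map, integrator_log=log)


def predict_spatial_corr(bundle: ModelBundle, embryo: VirtualEmbryo,
                         times=None) -> SimulationResult:
    """Predict target levels from measured factors with frozen static models.

    Each cell uses its local model from the last fitted time, evaluated at
    the measured factor concentrations of each requested time.
    """
    if bundle.response_kind != "level":
        raise ValueError("predict_spatial_corr requires a static (level) bundle")
    if times is None:
        times = embryo.times
    times = np.atleast_1d(np.asarray(times, dtype=float))
    E = embryo.n_cells
    A, B, X0 = _model_arrays_by_time(bundle, E)
    last = bundle.fit_times.size - 1
    x_raw = np.stack([embryo.get(f) for f in bundle.factors])  # (p, T_all, E)
    y_meas_all = embryo.get(bundle.target)
    T = times.size
    y_pred = np.empty((T, E))
    y_meas = np.empty((T, E))
    for ti, t in enumerate(times):
        k = int(np.flatnonzero(np.isclose(embryo.times, t))[0])
        x_t = x_raw[:, k, :].T                       # (E, p)
        y_pred[ti] = np.einsum("ep,ep->e", A[last], x_t - X0[last]) + B[last]
        y_meas[ti] = y_meas_all[k]
    return SimulationResult(times=times, y_sim=y_pred, y_measured=y_meas,
                            error_map=np.abs(y_pred - y_meas),
                            integrator_log={"method": "static",
                                            "model_time_index": last})


def total_error(error_map: np.ndarray, times_subset=None,
                metric: str = "l1") -> float:
    """Aggregate |simulated - measured| over cells and the selected times.

    ``times_subset`` is an index array into the map's time axis (None = all
    rows). metric 'l1' sums absolute errors; 'rmse' is available as a
    config alternative.
    """
    error_map = np.asarray(error_map, dtype=float)
    rows = error_map if times_subset is None else \
        error_map[np.asarray(times_subset, dtype=int)]
    if rows.size == 0:
        raise ValueError("empty time subset")
    if metric == "l1":
        return float(np.abs(rows).sum())
    if metric == "rmse":
        return float(np.sqrt(np.mean(rows ** 2)))
    raise ValueError(f"unknown metric {metric!r}")


def percent_improvement(err_a: float, err_b: float) -> float:
    """100 * (err_b - err_a) / err_b: how much smaller err_a is than err_b."""
    if err_b <= 0:
        raise ValueError("reference error must be positive")
    return 100.0 * (err_b - err_a) / err_b


def compare_models(node_bundle: ModelBundle, sc_bundle: ModelBundle,
                   embryo: VirtualEmbryo, eval_time_indices=None,
                   steps_per_unit: int = 100, metric: str = "l1") -> dict:
    """Head-to-head dynamic-vs-static comparison on held-out times.

    Simulates the dynamic bundle from the first time point, predicts with
    the static bundle at every time, and reports per-time errors plus the
    percent improvement of the dynamic model over the requested evaluation
    times (default: all times after the fitted ones).
    """
    sim = simulate_node(node_bundle, embryo, steps_per_unit=steps_per_unit)
    pred = predict_spatial_corr(sc_bundle, embryo)
    if eval_time_indices is None:
        n_fit = node_bundle.fit_times.size
        eval_time_indices = np.arange(n_fit, embryo.n_times)
    eval_time_indices = np.asarray(eval_time_indices, dtype=int)
    err_node = total_error(sim.error_map, eval_time_indices, metric=metric)
    err_sc = total_error(pred.error_map, eval_time_indices, metric=metric)
    return {
        "eval_times": embryo.times[eval_time_indices].tolist(),
        "per_time_error_node": np.abs(sim.error_map).sum(axis=1).tolist(),
        "per_time_error_spatial": np.abs(pred.error_map).sum(axis=1).tolist(),
        "total_error_node": err_node,
        "total_error_spatial": err_sc,
        "percent_improvement": percent_improvement(err_node, err_sc),
        "metric": metric,
    }
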