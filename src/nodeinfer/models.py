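"""Local-model families: dynamic (NODE), static spatial-correlation, and
general time-series variants, plus factor-activity maps and the four-way
activation/repression classification.

The dynamic family regresses the smoothed target derivative on factor
concentration deviations from each (time, cell) anchor; the static baseline
uses the same local machinery with the target *level* as response. Both
yield one linearized model per anchor:

    response = sum_f a_f,[t,e] (x_f - xhat_f[t,e]) + b[t,e].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nede
from .embryo import ModelBundle, VirtualEmbryo
from .nede import TuningParams, build_window
from .presmooth import SmoothedTrajectories, presmooth_embryo

__all__ = [
    "LocalModel",
    "ActivityMap",
    "GeneralNODEModel",
    "fit_node_model",
    "fit_spatial_correlation_model",
    "fit_local_models",
    "fit_general_timeseries",
    "factor_activity",
    "classify_activity",
    "write_activity_csv",
    "render_activity_map",
]

LABELS = ("type_I_repression", "type_II_repression",
          "type_I_activation", "type_II_activation", "null")


@dataclass
class LocalModel:
    """One linearization: response = coeffs . (x - anchor_x) + intercept."""

    anchor_t: int
    anchor_e: int
    anchor_x: np.ndarray
    coeffs: np.ndarray
    intercept: float
    response_kind: str = "derivative"

    def predict(self, x) -> float:
        x = np.asarray(x, dtype=float)
        return float(self.coeffs @ (x - self.anchor_x) + self.intercept)


def local_model(bundle: ModelBundle, i: int) -> LocalModel:
    return LocalModel(anchor_t=int(bundle.anchor_t[i]), anchor_e=int(bundle.anchor_e[i]),
                      anchor_x=bundle.anchor_x[i], coeffs=bundle.coeffs[i],
                      intercept=float(bundle.intercept[i]),
                      response_kind=bundle.response_kind)


def _resolve_fit_times(embryo: VirtualEmbryo, fit_times):
    if fit_times is None or (isinstance(fit_times, str) and fit_times == "all"):
        return embryo.times
    return np.atleast_1d(np.asarray(fit_times, dtype=float))


def fit_local_models(embryo: VirtualEmbryo, target: str, factors: list[str],
                     tuning: TuningParams | list[TuningParams],
                     fit_times=None, response_kind: str = "derivative",
                     response: np.ndarray | None = None,
                     smooth_method: str = "polynomial",
                     anchor_subset: np.ndarray | None = None,
                     window_mode: str = "concentration",
                     spatial_radius_cells: float = 3.0,
                     cv_folds: int = 5, cv_seed: int = 0) -> ModelBundle:
    """Shared fitting path for the dynamic and static model families.

    The candidate data set is the full (fit_times x cells) grid of smoothed
    factor vectors. For every anchor on that grid an Epanechnikov window in
    concentration space (or a fixed circular window in physical space when
    ``window_mode='spatial'``) weights the local linear solve. ``tuning``
    may be a list of candidates, in which case K-fold cross-validation on
    out-of-fold response prediction picks one first. ``response`` overrides
    the response vector (flattened time-major), which makes the machinery
    equivalence between the two families directly checkable.
    """
    if target in factors:
        raise ValueError("factor set and target must be disjoint")
    ft = _resolve_fit_times(embryo, fit_times)
    if ft.size < 2 and response_kind == "derivative":
        raise ValueError("at least 2 fit times are required for a dynamic fit")
    sub = embryo.subset_times(ft)
    tuning_list = tuning if isinstance(tuning, (list, tuple)) else [tuning]
    r = min(tuning_list[0].r, sub.n_times - 1)
    smoothed = presmooth_embryo(sub, target, factors, r=r, method=smooth_method)
    points = smoothed.points_matrix()                # (N, p), time-major
    if response is None:
        y = smoothed.response_vector(
            response_kind, raw_y=sub.get(target) if response_kind == "level" else None)
    else:
        y = np.asarray(response, dtype=float).reshape(-1)
        if y.size != points.shape[0]:
            raise ValueError("response override has wrong length")

    cv_report = None
    if len(tuning_list) > 1:
        chosen, cv_report = nede.cross_validate(points, y, list(tuning_list),
                                                folds=cv_folds, seed=cv_seed)
    else:
        chosen = tuning_list[0]
        cv_report = {"selected": chosen.to_dict(), "candidates":
                     [chosen.to_dict()], "scores": None}

    N, p = points.shape
    T, E = sub.n_times, sub.n_cells
    anchors = np.arange(N) if anchor_subset is None else np.asarray(anchor_subset, int)
    K = anchors.size
    coeffs = np.empty((K, p))
    intercept = np.empty(K)
    h_used = np.empty(K)
    n_escalations = 0
    global_h = None
    if chosen.h_mode in ("quantile", "absolute"):
        global_h = nede.resolve_bandwidth(points, chosen)
    time_index = np.repeat(np.arange(T), E)
    cell_index = np.tile(np.arange(E), T)
    coords_rep = None
    if window_mode == "spatial":
        if sub.coords is None:
            raise ValueError("spatial windows require cell coordinates")
        coords_rep = np.tile(sub.coords, (T, 1))
    d = min(chosen.d, p)
    for j, n0 in enumerate(anchors):
        try:
            if window_mode == "spatial":
                win = nede.build_spatial_window(
                    coords_rep, time_index, (int(time_index[n0]), int(cell_index[n0])),
                    spatial_radius_cells, anchor_x=points[n0],
                    distances_x=np.sqrt(((points - points[n0]) ** 2).sum(axis=1)))
                design = nede.build_local_design(points, y, win, d)
                beta = nede.nede_solve(design, chosen.lam)
            else:
                beta, win = nede.local_fit(points, y, points[n0], chosen, h=global_h)
        except nede.NedeError as exc:
            t0, e0 = divmod(int(n0), E)
            raise nede.NedeError(
                f"local fit failed at anchor (t={sub.times[t0]:g}, "
                f"cell={sub.cell_ids[e0]}): {exc}") from exc
        intercept[j] = beta[0]
        coeffs[j] = beta[1:]
        h_used[j] = win.h
        n_escalations += win.n_escalations
    kind = "node" if response_kind == "derivative" else "spatial_corr"
    meta = {"cv": cv_report, "n_candidates": int(N), "n_escalations": int(n_escalations),
            "window_mode": window_mode, "smooth_method": smooth_method,
            "degree_used": int(smoothed.degree)}
    if window_mode == "spatial":
        meta["spatial_radius_cells"] = float(spatial_radius_cells)
    return ModelBundle(kind=kind, tuning=chosen, target=target, factors=list(factors),
                       fit_times=sub.times, anchor_t=time_index[anchors],
                       anchor_e=cell_index[anchors], anchor_x=points[anchors],
                       coeffs=coeffs, intercept=intercept, h_used=h_used,
                       anchor_dydt=smoothed.dy_dt.reshape(-1)[anchors],
                       response_kind=response_kind, meta=meta)


def fit_node_model(embryo, target, factors, tuning, fit_times=None, **kw) -> ModelBundle:
    """Dynamic family: response is the smoothed target time derivative."""
    return fit_local_models(embryo, target, factors, tuning, fit_times=fit_times,
                            response_kind="derivative", **kw)


def fit_spatial_correlation_model(embryo, target, factors, tuning,
                                  fit_times=None, **kw) -> ModelBundle:
    """Static baseline: same machinery, response is the raw target level."""
    return fit_local_models(embryo, target, factors, tuning, fit_times=fit_times,
                            response_kind="level", **kw)


# ---------------------------------------------------------------------------
# factor activity


@dataclass
class ActivityMap:
    """Signed factor-activity values and labels over the fitted grid.

    activity[k, f] = a_f,[t,e] * sqrt(M_ff / n) where M = Xi^T W Xi is the
    weighted local second-moment matrix of the anchor's window and n the
    number of candidate points; the square-root term measures typical local
    factor deviation, so activity vanishes where a factor is locally
    constant however large its coefficient.
    """

    anchor_t: np.ndarray            # (K,)
    anchor_e: np.ndarray            # (K,)
    fit_times: np.ndarray
    cell_ids: np.ndarray
    factors: list[str]
    values: np.ndarray              # (K, p)
    labels: np.ndarray              # (K, p) strings from LABELS
    derivative_sign_source: str = "model_intercept"


def classify_activity(coefficient_sign: int, derivative_sign: int) -> str:
    """Four-way label from sign(a_f) x sign(d[target]/dt); any zero -> null.

    (-, -) type I repression: the target is falling and more factor makes it
    fall faster. (-, +) type II repression: the target is rising and more
    factor slows the rise. (+, +) type I activation; (+, -) type II
    activation, symmetrically.
    """
    cs, ds = int(np.sign(coefficient_sign)), int(np.sign(derivative_sign))
    if cs == 0 or ds == 0:
        return "null"
    table = {(-1, -1): "type_I_repression", (-1, 1): "type_II_repression",
             (1, 1): "type_I_activation", (1, -1): "type_II_activation"}
    return table[(cs, ds)]


def factor_activity(bundle: ModelBundle, embryo: VirtualEmbryo,
                    factor: str | list[str] | None = None,
                    derivative_sign_source: str = "model_intercept",
                    null_percentile: float | None = None) -> ActivityMap:
    """Recompute windows at every anchor and scale coefficients to activities.

    The windows are rebuilt with each anchor's stored realized bandwidth, so
    the map is exactly reproducible from a saved bundle plus the data. The
    derivative sign for classification comes from the model's own intercept
    (the local mean derivative) by default, or from the smoothed derivative
    stored at fit time. ``null_percentile`` optionally masks entries whose
    |activity| falls below that percentile (off by default).
    """
    factors = bundle.factors if factor is None else \
        ([factor] if isinstance(factor, str) else list(factor))
    f_idx = []
    for f in factors:
        if f not in bundle.factors:
            raise ValueError(f"factor {f!r} not in bundle factors {bundle.factors}")
        f_idx.append(bundle.factors.index(f))
    sub = embryo.subset_times(bundle.fit_times)
    r = min(bundle.tuning.r, sub.n_times - 1)
    smoothed = presmooth_embryo(sub, bundle.target, bundle.factors, r=r,
                                method=bundle.meta.get("smooth_method", "polynomial"))
    points = smoothed.points_matrix()
    n = points.shape[0]
    K = bundle.n_models
    values = np.empty((K, len(f_idx)))
    for k in range(K):
        win = build_window(points, bundle.anchor_x[k], h=bundle.h_used[k])
        keep = win.weights > 0
        Xi = points[keep] - bundle.anchor_x[k]
        w = win.weights[keep]
        Mdiag = (w[:, None] * Xi ** 2).sum(axis=0)
        values[k] = bundle.coeffs[k, f_idx] * np.sqrt(Mdiag[f_idx] / n)

    if derivative_sign_source == "model_intercept":
        if bundle.response_kind != "derivative":
            derivative_sign_source = "smoothed_derivative"
    if derivative_sign_source == "model_intercept":
        dsign = np.sign(bundle.intercept)
    elif derivative_sign_source == "smoothed_derivative":
        if bundle.anchor_dydt is None:
            raise ValueError("bundle has no stored smoothed derivatives")
        dsign = np.sign(bundle.anchor_dydt)
    else:
        raise ValueError(f"unknown derivative_sign_source {derivative_sign_source!r}")

    labels = np.empty((K, len(f_idx)), dtype=object)
    csign = np.sign(bundle.coeffs[:, f_idx])
    for k in range(K):
        for j in range(len(f_idx)):
            labels[k, j] = classify_activity(csign[k, j], dsign[k])
    if null_percentile is not None:
        thresh = np.percentile(np.abs(values), null_percentile)
        labels[np.abs(values) < thresh] = "null"
    return ActivityMap(anchor_t=bundle.anchor_t, anchor_e=bundle.anchor_e,
                       fit_times=bundle.fit_times, cell_ids=sub.cell_ids,
                       factors=factors, values=values, labels=labels,
                       derivative_sign_source=derivative_sign_source)


def write_activity_csv(amap: ActivityMap, path) -> None:
    """Long CSV export: cell_id, time, factor, activity, label."""
    import pandas as pd

    rows = {"cell_id": [], "time": [], "factor": [], "activity": [], "label": []}
    for j, f in enumerate(amap.factors):
        rows["cell_id"].extend(amap.cell_ids[amap.anchor_e])
        rows["time"].extend(amap.fit_times[amap.anchor_t])
        rows["factor"].extend([f] * amap.anchor_t.size)
        rows["activity"].extend(amap.values[:, j])
        rows["label"].extend(amap.labels[:, j])
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def render_activity_map(amap: ActivityMap, embryo: VirtualEmbryo, factor: str,
                        time_value: float, path) -> None:
    """Quick-look cylindrical-projection map (AP position vs azimuth) as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if embryo.coords is None:
        raise ValueError("rendering requires cell coordinates")
    j = amap.factors.index(factor)
    ti = int(np.flatnonzero(np.isclose(amap.fit_times, time_value))[0])
    sel = amap.anchor_t == ti
    cells = amap.anchor_e[sel]
    xyz = embryo.coords[cells]
    ap = xyz[:, 0]
    azimuth = np.arctan2(xyz[:, 2], xyz[:, 1])
    fig, ax = plt.subplots(figsize=(7, 3))
    vmax = np.abs(amap.values[:, j]).max() or 1.0
    sc = ax.scatter(ap, azimuth, c=amap.values[sel, j], cmap="RdBu_r",
                    vmin=-vmax, vmax=vmax, s=8)
    ax.set_xlabel("AP position")
    ax.set_ylabel("azimuth (rad)")
    ax.set_title(f"{factor} activity, t={time_value:g}")
    fig.colorbar(sc, ax=ax, label="activity")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# general time-series form


@dataclass
class GeneralNODEModel:
    """Per-linearization-point Jacobian/drift estimates for state ODEs.

    At each user-chosen point xi[n] the estimator returns A_xi (an estimate
    of the Jacobian Df(xi)) and b_xi (an estimate of the drift f(xi)) of the
    underlying dx/dt = f(x), so dx/dt ~= A_xi (x - xi) + b_xi nearby.
    """

    lin_points: np.ndarray          # (N, S)
    A: np.ndarray                   # (N, S, S)
    b: np.ndarray                   # (N, S)
    species: list[str]
    tuning: TuningParams


def fit_general_timeseries(series, lin_points, tuning: TuningParams,
                           species: list[str] | None = None) -> GeneralNODEModel:
    """Column-wise local linear fits of multi-experiment state trajectories.

    ``series`` is a sequence of experiments, each a (times, states) pair
    with states of shape (T_i, S). Every experiment's trajectories are
    presmoothed per species; the pooled smoothed states and their analytic
    derivatives form the candidate set, and at each linearization point one
    local solve per state species gives a row pair of (A, b).
    """
    from .presmooth import fit_time_polynomial, eval_derivative, eval_polynomial

    lin_points = np.atleast_2d(np.asarray(lin_points, dtype=float))
    pts_list, der_list = [], []
    S = None
    for times, states in series:
        times = np.asarray(times, dtype=float)
        states = np.asarray(states, dtype=float)
        if states.ndim != 2 or states.shape[1] < 2:
            raise ValueError("each experiment needs >= 2 state species")
        if times.size < 2:
            raise ValueError("each experiment needs >= 2 time points")
        S = states.shape[1]
        r = min(tuning.r, times.size - 1)
        sm = np.empty_like(states)
        dm = np.empty_like(states)
        for s in range(S):
            fit = fit_time_polynomial(states[:, s], times, r)
            sm[:, s] = eval_polynomial(fit, times)
            dm[:, s] = eval_derivative(fit, times)
        pts_list.append(sm)
        der_list.append(dm)
    points = np.concatenate(pts_list)               # (sum T_i, S)
    derivs = np.concatenate(der_list)               # (sum T_i, S)
    if lin_points.shape[1] != S:
        raise ValueError("linearization points must match the state dimension")
    N = lin_points.shape[0]
    A = np.empty((N, S, S))
    b = np.empty((N, S))
    for n in range(N):
        win = nede.build_window(points, lin_points[n], tuning=tuning,
                                min_support=S + 2)
        for s in range(S):
            design = nede.build_local_design(points, derivs[:, s], win,
                                             min(tuning.d, S))
            beta = nede.nede_solve(design, tuning.lam)
            b[n, s] = beta[0]
            A[n, s] = beta[1:]
    names = species if species is not None else [f"x{i + 1}" for i in range(S)]
    return GeneralNODEModel(lin_points=lin_points, A=A, b=b, species=list(names),
                            tuning=tuning)
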