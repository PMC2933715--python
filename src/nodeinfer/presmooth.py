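"""Per-cell temporal smoothing and derivative estimation.

Fitting a local ODE to expression data needs the target's time derivative,
which is never observed directly. Each cell's trajectory is therefore fit
with a low-degree polynomial in time (ordinary least squares, or a
tricube-weighted local-polynomial variant) and the derivative is taken
analytically from the fit. Factor trajectories are replaced by their
smoothed values so the regression anchors live on the same smooth surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

__all__ = [
    "PolynomialFit",
    "SmoothedTrajectories",
    "PresmoothError",
    "fit_time_polynomial",
    "eval_polynomial",
    "eval_derivative",
    "presmooth_embryo",
    "select_degree_loo",
]


class PresmoothError(ValueError):
    pass


@dataclass
class PolynomialFit:
    """Least-squares polynomial c0 + c1 t + ... + cr t^r over a time range."""

    coeffs: np.ndarray          # ascending powers, length r+1
    degree: int
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.size != self.degree + 1:
            raise PresmoothError("coefficient count != degree + 1")

    def __call__(self, t):
        return eval_polynomial(self, t)

    def derivative(self, t):
        return eval_derivative(self, t)


def fit_time_polynomial(values, times, r: int) -> PolynomialFit:
    """Ordinary least-squares polynomial of degree r through (times, values).

    Exact interpolation when r == T - 1; r >= T is an error (the system
    would be underdetermined).
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape != times.shape:
        raise PresmoothError("values and times must have equal length")
    T = times.size
    if r < 0 or r >= T:
        raise PresmoothError(f"degree r={r} must satisfy 0 <= r <= T-1 = {T - 1}")
    if not (np.all(np.isfinite(values)) and np.all(np.isfinite(times))):
        raise PresmoothError("non-finite values or times")
    coeffs = npoly.polyfit(times, values, r)
    return PolynomialFit(coeffs=coeffs, degree=r,
                         domain=(float(times.min()), float(times.max())))


def eval_polynomial(fit: PolynomialFit, t):
    return npoly.polyval(np.asarray(t, dtype=float), fit.coeffs)


def eval_derivative(fit: PolynomialFit, t):
    """Power-rule derivative k1 + 2 k2 t + ... + r kr t^(r-1); 0 for degree 0."""
    if fit.degree == 0:
        return np.zeros_like(np.asarray(t, dtype=float)) + 0.0
    dcoef = npoly.polyder(fit.coeffs)
    return npoly.polyval(np.asarray(t, dtype=float), dcoef)


def select_degree_loo(values_2d: np.ndarray, times: np.ndarray,
                      candidates=(1, 2, 3)) -> int:
    """One global degree minimizing pooled leave-one-out squared error.

    values_2d: (T, n_series) stack of every (cell, species) trajectory.
    Uses the closed-form LOO residual e_i / (1 - H_ii) of linear smoothers;
    the hat matrix depends only on the time grid, so the whole pool is
    scored at once. Candidates exceeding T - 1 are dropped; a degree whose
    leverage reaches 1 (interpolation) is scored infinite.
    """
    times = np.asarray(times, dtype=float)
    T = times.size
    feasible = [r for r in candidates if r <= T - 1]
    if not feasible:
        raise PresmoothError(f"no feasible degree among {candidates} for T={T}")
    best_r, best_score = feasible[0], np.inf
    for r in feasible:
        V = npoly.polyvander(times, r)
        H = V @ np.linalg.solve(V.T @ V, V.T)
        hii = np.diag(H)
        if np.any(hii > 1 - 1e-10):
            continue
        resid = values_2d - H @ values_2d
        score = float((resid.T ** 2 / (1 - hii) ** 2).sum())
        if score < best_score:
            best_r, best_score = r, score
    return best_r


_TRICUBE = lambda u: np.where(np.abs(u) < 1, (1 - np.abs(u) ** 3) ** 3, 0.0)


def _local_poly_eval(times, values_2d, t0, bw, r):
    """Tricube-weighted degree-r fit around t0; returns (value, derivative) rows."""
    if np.isinf(bw):
        w = np.ones_like(times)
    else:
        w = _TRICUBE((times - t0) / bw)
    use = w > 0
    if use.sum() < r + 1:        # widen until the local system is determined
        order = np.argsort(np.abs(times - t0))
        need = times[order[r]]
        bw = abs(need - t0) * 1.001
        w = _TRICUBE((times - t0) / bw)
        use = w > 0
    V = npoly.polyvander(times[use] - t0, r)
    Vw = V * w[use, None]
    beta = np.linalg.solve(V.T @ Vw, Vw.T @ values_2d[use])
    val = beta[0]
    der = beta[1] if r >= 1 else np.zeros_like(beta[0])
    return val, der


@dataclass
class SmoothedTrajectories:
    """Smoothed factor values and target derivatives over a (T, E) grid."""

    times: np.ndarray               # (T,)
    factors: list[str]
    target: str
    x_hat: np.ndarray               # (p, T, E) smoothed factor concentrations
    y_hat: np.ndarray               # (T, E) smoothed target concentrations
    dy_dt: np.ndarray               # (T, E) smoothed target derivative
    factor_coeffs: np.ndarray | None    # (p, r+1, E), polynomial method only
    target_coeffs: np.ndarray | None    # (r+1, E)
    degree: int
    method: str = "polynomial"

    @property
    def n_cells(self) -> int:
        return self.x_hat.shape[2]

    def eval_factors(self, t: float) -> np.ndarray:
        """Smoothed factor concentrations at continuous time t, shape (p, E)."""
        if self.factor_coeffs is None:
            raise PresmoothError("continuous evaluation requires polynomial method")
        p, _, E = self.x_hat.shape
        out = np.empty((p, E))
        for f in range(p):
            out[f] = npoly.polyval(t, self.factor_coeffs[f])
        return out

    def points_matrix(self) -> np.ndarray:
        """(T*E, p) matrix of smoothed factor vectors, time-major order."""
        p, T, E = self.x_hat.shape
        return self.x_hat.reshape(p, T * E).T

    def response_vector(self, kind: str, raw_y: np.ndarray | None = None) -> np.ndarray:
        """Flattened response in the same (time-major) order as points_matrix."""
        if kind == "derivative":
            return self.dy_dt.reshape(-1)
        if kind == "level":
            y = self.y_hat if raw_y is None else np.asarray(raw_y, float)
            return y.reshape(-1)
        raise PresmoothError(f"unknown response kind {kind!r}")


def presmooth_embryo(embryo, target: str, factors: list[str], r: int | None = None,
                     method: str = "polynomial",
                     bandwidth: float | None = None) -> SmoothedTrajectories:
    """Smooth all species per cell and differentiate the target trajectory.

    r=None selects one global degree from {1, 2, 3} (capped at T - 1) by
    pooled leave-one-out cross-validation over every trajectory.
    method='local_polynomial' uses tricube-weighted local fits of degree
    min(r, 2) at each time point, with the bandwidth (in time units) chosen
    by the same LOO criterion from a small grid when not given; an infinite
    bandwidth reduces it to the plain polynomial fit.
    """
    if target in factors:
        raise PresmoothError("target and factor sets must be disjoint")
    times = embryo.times
    T, E = embryo.n_times, embryo.n_cells
    if T < 2:
        raise PresmoothError("at least 2 time points are required")
    y_raw = embryo.get(target)                       # (T, E)
    x_raw = np.stack([embryo.get(f) for f in factors])   # (p, T, E)
    p = len(factors)

    stacked = np.concatenate([x_raw.reshape(p, T, E).transpose(1, 0, 2).reshape(T, -1),
                              y_raw], axis=1)        # (T, p*E + E)
    if r is None:
        r = select_degree_loo(stacked, times)
    r = int(min(r, T - 1))
    if T <= 3 and r < T - 1:
        warnings.warn("sparse time grid: smoothing may remove genuine temporal "
                      "trends", stacklevel=2)

    if method == "polynomial":
        all_coef = npoly.polyfit(times, stacked, r)  # (r+1, p*E+E)
        V = npoly.polyvander(times, r)               # (T, r+1)
        vals = V @ all_coef                          # (T, p*E+E)
        if r >= 1:
            dcoef = all_coef[1:] * np.arange(1, r + 1)[:, None]
            dvals = npoly.polyvander(times, r - 1) @ dcoef
        else:
            dvals = np.zeros_like(vals)
        x_hat = vals[:, :p * E].reshape(T, p, E).transpose(1, 0, 2)
        y_hat = vals[:, p * E:]
        dy_dt = dvals[:, p * E:]
        factor_coeffs = all_coef[:, :p * E].reshape(r + 1, p, E).transpose(1, 0, 2)
        target_coeffs = all_coef[:, p * E:]
    elif method == "local_polynomial":
        r_loc = min(r, 2) if r >= 1 else 1
        if bandwidth is None:
            bandwidth = _select_lpr_bandwidth(times, stacked, r_loc)
        x_hat = np.empty((p, T, E))
        y_hat = np.empty((T, E))
        dy_dt = np.empty((T, E))
        for ti, t0 in enumerate(times):
            val, der = _local_poly_eval(times, stacked, t0, bandwidth, r_loc)
            x_hat[:, ti, :] = val[:p * E].reshape(p, E)
            y_hat[ti] = val[p * E:]
            dy_dt[ti] = der[p * E:]
        factor_coeffs = target_coeffs = None
    else:
        raise PresmoothError(f"unknown smoothing method {method!r}")

    return SmoothedTrajectories(times=times, factors=list(factors), target=target,
                                x_hat=x_hat, y_hat=y_hat, dy_dt=dy_dt,
                                factor_coeffs=factor_coeffs,
                                target_coeffs=target_coeffs, degree=r, method=method)


def _select_lpr_bandwidth(times, stacked, r_loc):
    """LOO bandwidth selection over a small grid of time spans (incl. inf)."""
    span = float(times.max() - times.min())
    grid = [0.4 * span, 0.6 * span, np.inf]
    best_bw, best_score = grid[-1], np.inf
    for bw in grid:
        err = 0.0
        ok = True
        for i in range(times.size):
            rest = np.ones(times.size, dtype=bool)
            rest[i] = False
            if rest.sum() < r_loc + 1:
                ok = False
                break
            try:
                val, _ = _local_poly_eval(times[rest], stacked[rest], times[i],
                                          bw, r_loc)
            except np.linalg.LinAlgError:
                ok = False
                break
            err += float(((stacked[i] - val) ** 2).sum())
        if ok and err < best_score:
            best_bw, best_score = bw, err
    return best_bw
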