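"""Kernel-weighted local linear regression with a manifold (exterior-derivative) penalty.

This module implements the NEDE estimator: for an anchor concentration vector
x0, data points within an Epanechnikov window in concentration space are fit
by weighted linear regression, with a ridge penalty restricted to the span of
the minor principal components of the weighted local second-moment matrix.
Expression data in a blastoderm-like setting lives near a low-dimensional
manifold (cells are parameterized by a few spatial coordinates plus time), so
the unpenalized weighted design is typically ill-conditioned; penalizing only
the directions of least local variance shrinks the unidentifiable normal
components of the gradient while leaving the tangent-plane components free.

Everything here operates on plain arrays: ``points`` is the (N, p) matrix of
(smoothed) factor concentration vectors for all candidate data points, and
``y`` the (N,) response (target derivative for dynamic models, target level
for the static spatial-correlation baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TuningParams",
    "KernelWindow",
    "LocalDesign",
    "NedeError",
    "NedeSingularError",
    "epanechnikov_weight",
    "build_window",
    "build_spatial_window",
    "minor_principal_components",
    "build_local_design",
    "nede_solve",
    "cross_validate",
]


class NedeError(ValueError):
    """Invalid input to the local regression machinery."""


class NedeSingularError(NedeError):
    """The penalized normal matrix is numerically singular at an anchor."""


@dataclass(frozen=True)
class TuningParams:
    """Tuning parameters of the local model family.

    h
        Bandwidth. Interpretation depends on ``h_mode``:
        ``knn_frac`` (default) — per-anchor adaptive bandwidth equal to the
        distance from the anchor to its ceil(h*N)-th nearest candidate point;
        ``quantile`` — one global bandwidth equal to the h-quantile of the
        pairwise distance distribution of the candidate points;
        ``absolute`` — h is the bandwidth in concentration-distance units.
    lam
        Weight of the minor-principal-component ridge penalty (>= 0).
    d
        Assumed intrinsic dimension of the local data manifold, 0 <= d <= p.
        The penalty acts on the p - d minor components; d = p disables it.
    r
        Presmoothing polynomial degree (carried here so one object describes
        a full fit; the smoothing module consumes it).
    """

    h: float = 0.1
    lam: float = 0.0
    d: int = 0
    r: int = 2
    h_mode: str = "knn_frac"

    def __post_init__(self) -> None:
        if self.h is not None and self.h <= 0:
            raise NedeError(f"bandwidth h must be > 0, got {self.h}")
        if self.lam < 0:
            raise NedeError(f"lambda must be >= 0, got {self.lam}")
        if self.d < 0:
            raise NedeError(f"intrinsic dimension d must be >= 0, got {self.d}")
        if self.h_mode not in ("knn_frac", "quantile", "absolute"):
            raise NedeError(f"unknown h_mode {self.h_mode!r}")

    def to_dict(self) -> dict:
        return {"h": self.h, "lam": self.lam, "d": self.d, "r": self.r,
                "h_mode": self.h_mode}

    @classmethod
    def from_dict(cls, data: dict) -> "TuningParams":
        return cls(**data)


@dataclass
class KernelWindow:
    """Weights over all candidate data points for one anchor."""

    anchor_x: np.ndarray        # (p,)
    distances: np.ndarray       # (N,) Euclidean distances in concentration space
    weights: np.ndarray         # (N,) kernel weights, 0 outside the window
    h: float                    # bandwidth actually used (after escalation)
    n_escalations: int = 0

    @property
    def support_count(self) -> int:
        return int(np.count_nonzero(self.weights))

    @property
    def n_candidates(self) -> int:
        return self.distances.size


def epanechnikov_weight(distance, h):
    """Epanechnikov kernel weight 3(1-(n/h)^2)/4 for n <= h, else 0.

    Vectorized over ``distance``. The weight is exactly 0 on the window
    boundary n = h and attains its maximum 3/4 at n = 0.
    """
    if h <= 0:
        raise NedeError(f"bandwidth h must be > 0, got {h}")
    n = np.asarray(distance, dtype=float)
    if np.any(n < 0):
        raise NedeError("distances must be nonnegative")
    u = n / h
    w = np.where(u <= 1.0, 0.75 * (1.0 - u * u), 0.0)
    # n == h lands on the boundary: 1 - 1 = 0 already, but guard roundoff
    w = np.maximum(w, 0.0)
    if np.isscalar(distance) or np.ndim(distance) == 0:
        return float(w)
    return w


def _knn_bandwidth(dist: np.ndarray, k: int) -> float:
    """Distance to the k-th nearest candidate (anchor's own zero excluded)."""
    n = dist.size
    k = min(max(k, 1), n - 1)
    h = float(np.partition(dist, k)[k])
    while h <= 0.0 and k < n - 1:
        k += 1
        h = float(np.partition(dist, k)[k])
    if h <= 0.0:
        h = max(float(dist.max()), np.finfo(float).tiny)
    return h


def resolve_bandwidth(points: np.ndarray, tuning: TuningParams) -> float | None:
    """Global bandwidth for 'quantile'/'absolute' modes; None for per-anchor knn."""
    if tuning.h_mode == "absolute":
        return float(tuning.h)
    if tuning.h_mode == "quantile":
        return _quantile_bandwidth(points, tuning.h)
    return None


def _quantile_bandwidth(points: np.ndarray, q: float) -> float:
    """Deterministic h-quantile of pairwise distances (evenly-spaced subsample)."""
    from scipy.spatial.distance import pdist

    n = points.shape[0]
    if n > 1500:
        idx = np.linspace(0, n - 1, 1500).astype(int)
        points = points[idx]
    dists = pdist(points)
    h = float(np.quantile(dists, q))
    if h <= 0:
        h = float(dists.max()) or np.finfo(float).tiny
    return h


def build_window(points: np.ndarray, anchor_x: np.ndarray, h: float | None = None,
                 tuning: TuningParams | None = None, min_support: int | None = None,
                 max_escalations: int = 5) -> KernelWindow:
    """Epanechnikov window over all candidate points around one anchor.

    Distances are Euclidean in concentration space over the full candidate
    set (all fitted times, all cells), so cells with similar regulatory
    input — including mirror-symmetric cells on the other side of the
    embryo — enter the window regardless of physical position.

    If fewer than ``min_support`` (default p + 2) points receive positive
    weight, the bandwidth is doubled up to ``max_escalations`` times before
    erroring.
    """
    points = np.asarray(points, dtype=float)
    anchor_x = np.asarray(anchor_x, dtype=float)
    N, p = points.shape
    dist = np.sqrt(((points - anchor_x) ** 2).sum(axis=1))
    if h is None:
        if tuning is None:
            raise NedeError("either h or tuning must be given")
        if tuning.h_mode == "knn_frac":
            k = max(int(np.ceil(tuning.h * N)), (min_support or p + 2) + 1)
            h = _knn_bandwidth(dist, k)
        else:
            h = resolve_bandwidth(points, tuning)
    if min_support is None:
        min_support = p + 2
    n_esc = 0
    w = epanechnikov_weight(dist, h)
    while np.count_nonzero(w) < min_support:
        if n_esc >= max_escalations:
            raise NedeError(
                f"window support {int(np.count_nonzero(w))} < {min_support} "
                f"after {max_escalations} bandwidth escalations (h={h:g})")
        h *= 2.0
        n_esc += 1
        w = epanechnikov_weight(dist, h)
    return KernelWindow(anchor_x=anchor_x, distances=dist, weights=w, h=float(h),
                        n_escalations=n_esc)


def build_spatial_window(coords: np.ndarray, time_index: np.ndarray, anchor: tuple[int, int],
                         radius_cells: float, anchor_x: np.ndarray | None = None,
                         distances_x: np.ndarray | None = None) -> KernelWindow:
    """Fixed circular window in physical space at the anchor's own time point.

    A diagnostic alternative to concentration windows: uniform weight 1 on
    cells whose physical distance to the anchor cell is at most
    ``radius_cells`` times the median nearest-neighbour spacing, restricted
    to candidate points at the anchor's time. ``time_index`` gives each
    candidate point's time index; ``coords`` the candidate points' (x, y, z)
    cell positions (one row per candidate point).
    """
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise NedeError("coords must be an (N, 3) array; are coordinates present?")
    t0, i0 = anchor
    time_index = np.asarray(time_index)
    at_t = time_index == t0
    cell_xyz = coords[at_t]
    tree = cKDTree(np.unique(cell_xyz, axis=0))
    nn = tree.query(tree.data, k=2)[0][:, 1]
    spacing = float(np.median(nn))
    anchor_rows = np.flatnonzero(at_t)
    anchor_pos = coords[anchor_rows[i0]] if i0 < anchor_rows.size else coords[i0]
    dist_phys = np.sqrt(((coords - anchor_pos) ** 2).sum(axis=1))
    w = np.where(at_t & (dist_phys <= radius_cells * spacing + 1e-12), 1.0, 0.0)
    if distances_x is None:
        distances_x = dist_phys
    ax = anchor_pos if anchor_x is None else np.asarray(anchor_x, float)
    return KernelWindow(anchor_x=ax, distances=np.asarray(distances_x, float),
                        weights=w, h=radius_cells * spacing)


def minor_principal_components(M: np.ndarray, d: int, sym_tol: float = 1e-8,
                               tie_tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the (p - d) smallest-eigenvalue eigenvectors of M.

    M is the weighted local second-moment matrix Xi^T W Xi. The returned
    p x (p - d) matrix spans the directions of least local variance — the
    estimated normal space of the data manifold. Deterministic output: the
    eigenvalues are sorted ascending, each eigenvector's sign is fixed so
    its first non-negligible component is positive, and within eigenvalue
    ties vectors are ordered lexicographically.
    """
    M = np.asarray(M, dtype=float)
    p = M.shape[0]
    if M.shape != (p, p):
        raise NedeError("M must be square")
    scale = max(1.0, float(np.abs(M).max()))
    if np.abs(M - M.T).max() > sym_tol * scale:
        raise NedeError("M must be symmetric")
    if not 0 <= d <= p:
        raise NedeError(f"intrinsic dimension d={d} outside [0, {p}]")
    if d == p:
        return np.zeros((p, 0))
    evals, evecs = np.linalg.eigh((M + M.T) / 2.0)  # ascending
    k = p - d
    vecs = evecs[:, :k].copy()
    vals = evals[:k]
    # sign convention
    for j in range(k):
        v = vecs[:, j]
        nz = np.flatnonzero(np.abs(v) > 1e-12)
        if nz.size and v[nz[0]] < 0:
            vecs[:, j] = -v
    # lexicographic order within (near-)ties
    tol = tie_tol * max(float(np.trace(M)), 1.0)
    order = np.arange(k)
    j = 0
    while j < k:
        grp = [j]
        while grp[-1] + 1 < k and abs(vals[grp[-1] + 1] - vals[j]) < tol:
            grp.append(grp[-1] + 1)
        if len(grp) > 1:
            keys = [tuple(np.round(vecs[:, g], 10)) for g in grp]
            order[grp[0]:grp[-1] + 1] = np.array(grp)[np.argsort(
                np.arange(len(grp))[np.lexsort(np.array(keys).T[::-1])])]
        j = grp[-1] + 1
    return vecs[:, order]


@dataclass
class LocalDesign:
    """Centered local design around one anchor.

    X = [1 Xi] with Xi the matrix of concentration deviations from the
    anchor (only rows with positive kernel weight are kept); Y the matching
    response values; M = Xi^T W Xi the weighted second-moment matrix; P the
    minor-principal-component basis used by the penalty.
    """

    X: np.ndarray           # (m, p+1)
    Xi: np.ndarray          # (m, p)
    Y: np.ndarray           # (m,)
    w: np.ndarray           # (m,) positive kernel weights
    M: np.ndarray           # (p, p)
    P: np.ndarray           # (p, p-d)
    anchor_x: np.ndarray    # (p,)


def build_local_design(points: np.ndarray, y: np.ndarray, window: KernelWindow,
                       d: int) -> LocalDesign:
    """Assemble the centered, weighted local design for one anchor."""
    points = np.asarray(points, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = window.weights > 0
    Xi = points[keep] - window.anchor_x
    w = window.weights[keep]
    M = (Xi * w[:, None]).T @ Xi
    M = (M + M.T) / 2.0
    P = minor_principal_components(M, d)
    X = np.column_stack([np.ones(Xi.shape[0]), Xi])
    return LocalDesign(X=X, Xi=Xi, Y=y[keep], w=w, M=M, P=P,
                       anchor_x=np.asarray(window.anchor_x, float))


def nede_solve(design: LocalDesign, lam: float, cond_tol: float = 1e-12) -> np.ndarray:
    """Penalized weighted local linear solve.

    Minimizes ||W^{1/2}(Y - X beta)||^2 + lam * ||P^T a||^2 over
    beta = (b, a_1..a_p), where a is the slope subvector. Closed form:
    (X^T W X + lam * blockdiag(0, P P^T))^{-1} X^T W Y. The intercept is
    never penalized. Raises :class:`NedeSingularError` when the penalized
    normal matrix is numerically singular.
    """
    X, Y, w = design.X, design.Y, design.w
    p = design.Xi.shape[1]
    A = (X * w[:, None]).T @ X
    if lam > 0 and design.P.shape[1] > 0:
        A[1:, 1:] += lam * (design.P @ design.P.T)
    A = (A + A.T) / 2.0
    rhs = (X * w[:, None]).T @ Y
    evals = np.linalg.eigvalsh(A)
    if evals[0] <= cond_tol * max(evals[-1], np.finfo(float).tiny):
        raise NedeSingularError(
            f"penalized normal matrix singular (min/max eigenvalue "
            f"{evals[0]:.3e}/{evals[-1]:.3e}); p={p}, support={X.shape[0]}")
    return np.linalg.solve(A, rhs)


def local_fit(points: np.ndarray, y: np.ndarray, anchor_x: np.ndarray,
              tuning: TuningParams, h: float | None = None,
              min_support: int | None = None) -> tuple[np.ndarray, KernelWindow]:
    """Window + design + solve for one anchor; returns (beta, window)."""
    win = build_window(points, anchor_x, h=h, tuning=tuning, min_support=min_support)
    beta = None
    for _ in range(6):
        design = build_local_design(points, y, win, min(tuning.d, points.shape[1]))
        try:
            beta = nede_solve(design, tuning.lam)
            break
        except NedeSingularError:
            if win.n_escalations >= 5:
                raise
            prev_esc = win.n_escalations
            win = build_window(points, anchor_x, h=win.h * 2.0, tuning=tuning,
                               min_support=min_support)
            win.n_escalations += prev_esc + 1
    if beta is None:  # pragma: no cover - loop always breaks or raises
        raise NedeSingularError("local fit failed")
    return beta, win


def cross_validate(points: np.ndarray, y: np.ndarray,
                   candidates: list[TuningParams], folds: int = 5,
                   seed: int = 0) -> tuple[TuningParams, dict]:
    """K-fold selection of tuning parameters by out-of-fold prediction error.

    Data points (rows of ``points``) are partitioned uniformly at random
    into ``folds`` folds with the given seed. For each candidate, every
    held-out point is predicted by a local model anchored at that point and
    fit from the training folds only; the prediction at the point's own
    anchor is the intercept (the centered design vanishes there). The
    candidate with the smallest summed squared error wins; infeasible
    candidates (d > p) are skipped with a warning, and candidates hitting a
    singular local solve score infinity.
    """
    points = np.asarray(points, dtype=float)
    y = np.asarray(y, dtype=float)
    N, p = points.shape
    if not candidates:
        raise NedeError("candidate grid is empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    fold_id = np.empty(N, dtype=int)
    for f in range(folds):
        fold_id[perm[f::folds]] = f
    scores = []
    for cand in candidates:
        if cand.d > p:
            warnings.warn(f"skipping infeasible candidate d={cand.d} > p={p}")
            scores.append(np.inf)
            continue
        err = 0.0
        try:
            for f in range(folds):
                test = np.flatnonzero(fold_id == f)
                train = np.flatnonzero(fold_id != f)
                pts_tr, y_tr = points[train], y[train]
                for i in test:
                    # prediction at the held-out point's own anchor: Xi row
                    # is zero there, so the local prediction is the intercept
                    beta, _ = local_fit(pts_tr, y_tr, points[i], cand)
                    err += (y[i] - beta[0]) ** 2
        except NedeError:
            err = np.inf
        scores.append(float(err))
    best = int(np.argmin(scores))
    report = {"scores": scores,
              "candidates": [c.to_dict() for c in candidates],
              "selected": candidates[best].to_dict(),
              "folds": folds, "seed": seed}
    return candidates[best], report
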