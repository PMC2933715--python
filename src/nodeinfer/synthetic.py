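"""Synthetic virtual embryos with known regulatory ground truth.

Emulates the structure of a blastoderm expression atlas: a few thousand
cells quasi-uniformly covering a prolate ellipsoid surface (axis ratio
2.5:1:1), six time points, five transcription-factor species laid out as
smooth anterior-posterior gradients and stripes with slow temporal change,
and one target mRNA whose trajectory per cell follows a known regulatory
law (Hill or linear terms plus basal production and linear decay). Because
the law and the factor patterns are analytic, every derived quantity —
the target's true derivative and the true Jacobian of the law with respect
to each factor at every (time, cell) — is available exactly, which is what
every estimator test in this package is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embryo import VirtualEmbryo

__all__ = [
    "FactorSpec",
    "HillTerm",
    "LinearTerm",
    "RegulatoryLaw",
    "SyntheticConfig",
    "GroundTruth",
    "make_geometry",
    "make_factor_patterns",
    "generate_target_dynamics",
    "make_embryo",
    "linear_suite",
    "hill_suite",
]

_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class FactorSpec:
    """One factor's spatial pattern and temporal drift.

    kind 'gradient': amplitude * sigmoid(steepness * (s - center)) along the
    normalized AP coordinate s in [0, 1]; kind 'stripe': a Gaussian bump of
    the given width at center. ``center_drift`` moves the feature along AP
    per unit time; ``amp_drift`` ramps the amplitude linearly in time
    (amplitude * (1 + amp_drift * (t - t_mid))); ``dv_mod`` modulates the
    amplitude with cos(azimuth) around the dorsoventral circumference.
    """

    name: str
    kind: str = "gradient"          # gradient | stripe
    center: float = 0.5
    steepness: float = 10.0         # gradient only; sign sets direction
    width: float = 0.1              # stripe only (Gaussian sigma in AP units)
    amplitude: float = 1.0
    center_drift: float = 0.0
    amp_drift: float = 0.0
    dv_mod: float = 0.0
    baseline: float = 0.0
    wiggle_amp: float = 0.0         # factor-specific smooth spatial variation


@dataclass(frozen=True)
class HillTerm:
    """V * x^n / (K^n + x^n) (activation) or V / (1 + (x/K)^n) (repression)."""

    factor: str
    V: float
    K: float
    n: float = 2.0
    repressor: bool = False

    def value(self, x):
        x = np.maximum(np.asarray(x, dtype=float), 0.0)
        u = (x / self.K) ** self.n
        if self.repressor:
            return self.V / (1.0 + u)
        return self.V * u / (1.0 + u)

    def derivative(self, x):
        x = np.maximum(np.asarray(x, dtype=float), 1e-12)
        u = (x / self.K) ** self.n
        du = self.n * u / x
        if self.repressor:
            return -self.V * du / (1.0 + u) ** 2
        return self.V * du / (1.0 + u) ** 2


@dataclass(frozen=True)
class LinearTerm:
    factor: str
    coef: float

    def value(self, x):
        return self.coef * np.asarray(x, dtype=float)

    def derivative(self, x):
        return np.full_like(np.asarray(x, dtype=float), self.coef)


@dataclass(frozen=True)
class RegulatoryLaw:
    """dy/dt = basal + sum_terms(term(x_f)) - decay * y."""

    terms: tuple = ()
    basal: float = 0.0
    decay: float = 0.0

    def rate(self, x_by_factor: dict, y):
        out = np.full_like(np.asarray(y, dtype=float), self.basal)
        for term in self.terms:
            out = out + term.value(x_by_factor[term.factor])
        return out - self.decay * np.asarray(y, dtype=float)

    def jacobian_factor(self, factor: str, x_by_factor: dict):
        """d(rate)/d(x_factor) holding everything else fixed."""
        x = np.asarray(x_by_factor[factor], dtype=float)
        out = np.zeros_like(x)
        for term in self.terms:
            if term.factor == factor:
                out = out + term.derivative(x)
        return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic embryo realization."""

    n_cells: int = 1000
    n_times: int = 6
    factor_specs: tuple = ()
    law: RegulatoryLaw = field(default_factory=RegulatoryLaw)
    target: str = "eve"
    noise_sigma: float = 0.0
    noise_on: str = "all"           # "all" | "target" (factors noiseless)
    seed: int = 0
    mirror_symmetric: bool = False
    y0: float = 0.0                 # initial target level, all cells
    axis_ratio: tuple = (2.5, 1.0, 1.0)

    @property
    def times(self) -> np.ndarray:
        return np.arange(1.0, self.n_times + 1.0)

    @property
    def factor_names(self) -> list:
        return [f.name for f in self.factor_specs]


@dataclass
class GroundTruth:
    """Noiseless values and analytic derivatives behind a synthetic embryo."""

    y_true: np.ndarray              # (T, E) noiseless target
    dy_dt: np.ndarray               # (T, E) true derivative at measurement times
    jacobian: np.ndarray            # (T, E, p) d(rate)/d(x_f) at the true state
    x_true: np.ndarray              # (p, T, E) noiseless factor patterns


def make_geometry(n_cells: int, seed: int = 0,
                  axis_ratio=(2.5, 1.0, 1.0), mirror_symmetric: bool = False):
    """Quasi-uniform points on a prolate ellipsoid surface (Fibonacci lattice).

    Deterministic per seed (the seed sets a random azimuthal phase). With
    ``mirror_symmetric`` the first half of the cells is reflected across the
    left-right (y) axis to form exact mirror pairs: cell i and cell
    i + n/2 coincide up to y -> -y.
    """
    if n_cells < 8:
        raise ValueError("need at least 8 cells")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    if mirror_symmetric:
        half = (n_cells + 1) // 2
        i = np.arange(half)
        z = 1.0 - 2.0 * (i + 0.5) / half
        theta = (_GOLDEN * i + phase) % (2 * np.pi)
        rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
        ux, uy, uz = z, np.abs(rho * np.cos(theta)), rho * np.sin(theta)
        pts = np.column_stack([ux, uy, uz])
        mirrored = pts * np.array([1.0, -1.0, 1.0])
        unit = np.vstack([pts, mirrored])[:n_cells]
    else:
        i = np.arange(n_cells)
        z = 1.0 - 2.0 * (i + 0.5) / n_cells
        theta = (_GOLDEN * i + phase) % (2 * np.pi)
        rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
        unit = np.column_stack([z, rho * np.cos(theta), rho * np.sin(theta)])
    a, b, c = axis_ratio
    return unit * np.array([a, b, c])


def _ap_and_dv(coords: np.ndarray, axis_ratio):
    a, _, c = axis_ratio
    s = (coords[:, 0] / a + 1.0) / 2.0              # normalized AP in [0, 1]
    zn = coords[:, 2] / c                           # normalized DV height in [-1, 1]
    return s, zn


def _wiggle_fields(config: "SyntheticConfig", s, zn) -> np.ndarray:
    """Static per-factor smooth harmonic fields over (AP, DV), shape (p, E).

    Emulates factor-specific spatial variability (embryo-to-embryo and
    patterning variation not shared between factors); without it all factor
    patterns would be exact functions of two surface coordinates and the
    per-factor gradient of the regulatory law would not be identifiable
    entrywise. Fields depend only on (s, z), so they respect the embryo's
    left-right mirror symmetry. Deterministic per (config seed, factor).
    """
    p = len(config.factor_specs)
    fields = np.zeros((p, s.size))
    for fi, spec in enumerate(config.factor_specs):
        if spec.wiggle_amp == 0.0:
            continue
        rng = np.random.default_rng(config.seed * 7919 + 81 + fi)
        m = 6
        amps = rng.normal(0, 1, m)
        amps /= np.sqrt((amps ** 2).sum())
        fs = rng.uniform(0.5, 3.0, m)
        fz = rng.uniform(0.5, 2.0, m)
        ph = rng.uniform(0, 2 * np.pi, m)
        w = np.zeros_like(s)
        for j in range(m):
            w += amps[j] * np.cos(2 * np.pi * fs[j] * s + np.pi * fz[j] * zn + ph[j])
        fields[fi] = spec.wiggle_amp * w
    return fields


def _pattern_value(spec: FactorSpec, s, zn, t, t_mid, wiggle=0.0):
    c = spec.center + spec.center_drift * (t - t_mid)
    if spec.kind == "gradient":
        core = 1.0 / (1.0 + np.exp(-spec.steepness * (s - c)))
    elif spec.kind == "stripe":
        core = np.exp(-0.5 * ((s - c) / spec.width) ** 2)
    else:
        raise ValueError(f"unknown pattern kind {spec.kind!r}")
    amp = spec.amplitude * (1.0 + spec.amp_drift * (t - t_mid))
    if spec.dv_mod:
        amp = amp * (1.0 + spec.dv_mod * zn) / (1.0 + abs(spec.dv_mod))
    return np.clip(spec.baseline + amp * core + wiggle, 0.0, 1.0)


def make_factor_patterns(config: SyntheticConfig, coords: np.ndarray) -> np.ndarray:
    """Noiseless factor concentrations, shape (p, T, E), values in [0, 1]."""
    s, zn = _ap_and_dv(coords, config.axis_ratio)
    times = config.times
    t_mid = float(times.mean())
    p, T, E = len(config.factor_specs), times.size, coords.shape[0]
    wig = _wiggle_fields(config, s, zn)
    x = np.empty((p, T, E))
    for fi, spec in enumerate(config.factor_specs):
        for ti, t in enumerate(times):
            x[fi, ti] = _pattern_value(spec, s, zn, t, t_mid, wig[fi])
    return x


def _factors_at_continuous(config, s, zn, t, t_mid, wig):
    return {spec.name: _pattern_value(spec, s, zn, t, t_mid, wig[fi])
            for fi, spec in enumerate(config.factor_specs)}


def generate_target_dynamics(config: SyntheticConfig, coords: np.ndarray,
                             steps_per_unit: int = 200):
    """Integrate the regulatory law per cell with fine-step RK4.

    Returns (y_true (T, E), dy_dt (T, E), jacobian (T, E, p)) at the
    measurement times, all noiseless and analytic. Factors are evaluated at
    continuous time from their pattern functions, so the integration is
    exact up to RK4 error. Non-finite dynamics raise with the offending
    cell named.
    """
    s, zn = _ap_and_dv(coords, config.axis_ratio)
    times = config.times
    t_mid = float(times.mean())
    T, E = times.size, coords.shape[0]
    p = len(config.factor_specs)
    wig = _wiggle_fields(config, s, zn)
    law = config.law
    y = np.full(E, float(config.y0))
    y_true = np.empty((T, E))
    dy_dt = np.empty((T, E))
    jac = np.empty((T, E, p))

    def record(ti, y_now):
        xf = _factors_at_continuous(config, s, zn, times[ti], t_mid, wig)
        y_true[ti] = y_now
        dy_dt[ti] = law.rate(xf, y_now)
        for fi, spec in enumerate(config.factor_specs):
            jac[ti, :, fi] = law.jacobian_factor(spec.name, xf)

    record(0, y)
    for k in range(T - 1):
        t0, t1 = times[k], times[k + 1]
        n = max(1, int(np.ceil(steps_per_unit * (t1 - t0))))
        h = (t1 - t0) / n
        t = t0
        for _ in range(n):
            def rhs(tt, yy):
                return law.rate(
                    _factors_at_continuous(config, s, zn, tt, t_mid, wig), yy)
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise FloatingPointError(
                f"non-finite target dynamics at cell index {bad} by time {t1:g}")
        record(k + 1, y)
    return y_true, dy_dt, jac


def make_embryo(config: SyntheticConfig,
                steps_per_unit: int = 200) -> tuple[VirtualEmbryo, GroundTruth]:
    """Full synthetic embryo: geometry, factors, target, noise, ground truth.

    Noise is additive i.i.d. Gaussian truncated at zero (concentrations stay
    nonnegative), applied independently to factors and target (or to the
    target only with ``noise_on='target'`` — the classical regression-noise
    setting; noise in the regressors is an errors-in-variables regime where
    local linear estimates carry an attenuation bias that no sample size
    removes). sigma = 0 reproduces the noiseless truth bitwise. The
    returned embryo is fully determined by the config (seed included).
    """
    coords = make_geometry(config.n_cells, seed=config.seed,
                           axis_ratio=config.axis_ratio,
                           mirror_symmetric=config.mirror_symmetric)
    x_true = make_factor_patterns(config, coords)
    y_true, dy_dt, jac = generate_target_dynamics(config, coords, steps_per_unit)
    rng = np.random.default_rng(config.seed + 1)
    if config.noise_sigma > 0:
        if config.noise_on == "all":
            x_obs = np.maximum(
                x_true + rng.normal(0, config.noise_sigma, x_true.shape), 0.0)
        elif config.noise_on == "target":
            x_obs = x_true.copy()
        else:
            raise ValueError(f"unknown noise_on mode {config.noise_on!r}")
        y_obs = np.maximum(
            y_true + rng.normal(0, config.noise_sigma, y_true.shape), 0.0)
    else:
        x_obs, y_obs = x_true.copy(), y_true.copy()
    conc = np.concatenate([x_obs, y_obs[None]], axis=0)
    embryo = VirtualEmbryo(cell_ids=np.arange(1, config.n_cells + 1),
                           times=config.times,
                           species=config.factor_names + [config.target],
                           conc=conc, coords=coords)
    return embryo, GroundTruth(y_true=y_true, dy_dt=dy_dt, jacobian=jac,
                               x_true=x_true)


def write_truth_sidecar(embryo: VirtualEmbryo, truth: GroundTruth,
                        config: SyntheticConfig, path) -> None:
    """Ground-truth sidecar table: *_truth and *_jac_<factor> species columns."""
    from .embryo import write_embryo_table

    species = [f"{config.target}_truth", f"d{config.target}_dt_truth"]
    mats = [truth.y_true, truth.dy_dt]
    for fi, name in enumerate(config.factor_names):
        species.append(f"{config.target}_jac_{name}")
        mats.append(truth.jacobian[:, :, fi])
    side = VirtualEmbryo(cell_ids=embryo.cell_ids, times=embryo.times,
                         species=species, conc=np.stack(mats),
                         coords=embryo.coords)
    write_embryo_table(side, path, dialect="wide")


# ---------------------------------------------------------------------------
# preset suites — these define the study conditions used throughout the tests


def linear_suite(n_cells: int = 200, noise_sigma: float = 0.0, seed: int = 0,
                 amp_drift: tuple = (0.05, -0.04),
                 mirror_symmetric: bool = False,
                 noise_on: str = "all") -> SyntheticConfig:
    """Two factors, globally linear law dy/dt = 2 x1 - x2 + 0.3, no decay.

    Factor 1 is a posterior-rising sigmoid gradient, factor 2 a mid-embryo
    stripe with dorsoventral modulation; both amplitudes ramp linearly in
    time so trajectories are exactly polynomial (degree 1) in t and the
    target exactly quadratic — the noiseless case is solvable exactly by a
    degree-2 presmoother and an unpenalized local linear fit. The target
    starts at 0.2 and the law's rate is nonnegative over the pattern range,
    so the zero-truncated measurement noise stays effectively unbiased
    (truncating at a level several noise SDs below every true value).
    """
    specs = (
        FactorSpec(name="f1", kind="gradient", center=0.45, steepness=6.0,
                   amplitude=0.85, amp_drift=amp_drift[0]),
        FactorSpec(name="f2", kind="stripe", center=0.55, width=0.16,
                   amplitude=0.8, amp_drift=amp_drift[1], dv_mod=0.3),
    )
    law = RegulatoryLaw(terms=(LinearTerm("f1", 2.0), LinearTerm("f2", -1.0)),
                        basal=0.3, decay=0.0)
    return SyntheticConfig(n_cells=n_cells, factor_specs=specs, law=law,
                           noise_sigma=noise_sigma, noise_on=noise_on,
                           seed=seed, y0=0.2,
                           mirror_symmetric=mirror_symmetric)


def hill_suite(n_cells: int = 1000, noise_sigma: float = 0.02,
               seed: int = 0) -> SyntheticConfig:
    """Five gap-gene-like factors, nonlinear Hill law, the default test suite.

    bcd-like anterior gradient (Hill activator), kr-like central stripe
    (Hill repressor), hb-like step (weak linear activator), plus two
    low-amplitude non-regulating patterns (kni-, gt-like). The law has no
    target auto-decay: the fitted model family regresses the target's rate
    of change on factor concentrations only, so a -gamma*y term would make
    the target level an omitted confounder and per-factor gradients would
    not be recoverable by any estimator of that family (decay remains
    available through :class:`RegulatoryLaw` for experiments). Each
    factor carries its own smooth harmonic field on top of its canonical
    pattern (see :func:`_wiggle_fields`), so the local factor covariance is
    full rank and the law's per-factor gradient is identifiable; the two
    weak factors vary least, which is what the minor-component penalty
    (d = 3) shrinks.
    """
    specs = (
        FactorSpec(name="bcd", kind="gradient", center=0.55, steepness=-7.0,
                   amplitude=0.88, center_drift=-0.01, wiggle_amp=0.08),
        FactorSpec(name="kr", kind="stripe", center=0.5, width=0.13,
                   amplitude=0.85, center_drift=0.012, dv_mod=0.25,
                   wiggle_amp=0.08),
        FactorSpec(name="hb", kind="gradient", center=0.35, steepness=9.0,
                   amplitude=0.8, amp_drift=0.03, wiggle_amp=0.08),
        FactorSpec(name="kni", kind="stripe", center=0.68, width=0.09,
                   amplitude=0.05, center_drift=0.008, wiggle_amp=0.02),
        FactorSpec(name="gt", kind="stripe", center=0.3, width=0.1,
                   amplitude=0.05, amp_drift=-0.02, wiggle_amp=0.02),
    )
    law = RegulatoryLaw(
        terms=(HillTerm("bcd", V=1.0, K=0.4, n=2.0),
               HillTerm("kr", V=0.8, K=0.3, n=2.0, repressor=True),
               LinearTerm("hb", 0.5)),
        basal=0.05, decay=0.0)
    return SyntheticConfig(n_cells=n_cells, factor_specs=specs, law=law,
                           noise_sigma=noise_sigma, seed=seed, y0=0.1)
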