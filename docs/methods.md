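# Methods

This note records the model, the estimator, the synthetic study conditions,
and the numerical and design choices behind `nodeinfer`, in enough detail
that a maintainer can judge what the tests do and do not establish.

## Model family

The package treats a target mRNA's rate of change as an unknown smooth
function of transcription-factor concentrations, dy/dt = f(x), and
estimates its linearization at every anchor on the (time × cell) grid:

    dy/dt = Σ_f a_f,[t,e] (x_f − x̂_f[t,e]) + b[t,e].

There is one such equation per (t, e); the collection — not any single
equation — is the model. The intercept b[t,e] is the model's own estimate
of the local mean derivative at the anchor concentrations; the slope
a_f,[t,e] is the local partial effect of factor f in the presence of all
other factors. The static spatial-correlation baseline is the identical
construction with the target *level* as response; it shares every line of
fitting code (a property the suite asserts by injecting level values
through the dynamic path). A general time-series variant applies the same
estimator column-wise to multi-species state derivatives, returning a
Jacobian estimate A_ξ ≈ Df(ξ) and drift b_ξ ≈ f(ξ) per user-chosen
linearization point ξ.

Assumptions inherited from the ODE framing: concentrations are large
enough for deterministic rate laws; the measured factors are the
rate-limiting species; the target does not appear on the right-hand side
(no auto-regulation or explicit decay term — see Limitations).

## Estimation pipeline

**Presmoothing (degree r).** Per cell and species, ordinary least-squares
polynomials in time; the target derivative is the analytic derivative of
its fitted polynomial. Degree default: one global r chosen from {1, 2, 3}
by pooled leave-one-out CV (closed form via the hat matrix, which depends
only on the time grid). With T time points, r is capped at T − 1; fitting
on two time points therefore uses r = 1 and the derivative estimate is the
per-cell secant slope. A tricube-weighted local-polynomial variant
(`method='local_polynomial'`) is provided for longer series; with infinite
bandwidth it reduces exactly to the polynomial fit. On grids of T ≤ 3 with
r < T − 1 the module warns (genuine temporal trends can be smoothed away)
but proceeds.

**Windows (bandwidth h).** Distances are Euclidean in smoothed factor
concentration space over the full candidate grid (all fitted times × all
cells), weighted by the Epanechnikov kernel 3(1 − (n/h)²)/4 on n ≤ h.
Three bandwidth modes:

- `knn_frac` (default, h = 0.1): per-anchor adaptive bandwidth equal to the
  distance to the ⌈h·N⌉-th nearest candidate. Adapts to local density, which
  real expression data needs.
- `quantile`: one global bandwidth at the h-quantile of the pairwise
  distance distribution (computed on a deterministic evenly-spaced
  subsample above 1,500 points). Preferred when a fixed estimand across
  sample sizes matters, e.g. consistency experiments: kNN windows collapse
  in regions where many cells share nearly identical concentrations,
  making the local variance sample-size-independent there.
- `absolute`: h in concentration units.

If fewer than p + 2 candidates get positive weight, h is doubled, at most
5 times, then the fit errors naming the anchor. A fixed *physical*
circular window (uniform weights on cells within a radius measured in
multiples of the median nearest-neighbour spacing, anchor's time slice
only) is available as the diagnostic alternative; the suite checks that
activity maps from both window types agree in sign on strong entries.

**Penalized solve (λ, d).** β̂ = (XᵀWX + λ·blockdiag(0, PPᵀ))⁻¹XᵀWY, with
P the orthonormal basis of the p − d smallest-eigenvalue eigenvectors of
M = ΞᵀWΞ. The intercept is never penalized, and the penalty applies to the
slope subvector only — the exterior-derivative reading: estimated local
gradients are pushed toward the tangent space of the data manifold, whose
dimension is the tuning parameter d (d = p disables the penalty; λ = 0
reduces to weighted least squares, asserted against an independent
normal-equations oracle). Eigenpairs are ordered ascending; sign fixed by
making the first non-negligible component positive; near-ties (relative
gap < 1e-10 of the trace) ordered lexicographically, so output is
deterministic. The penalized normal matrix is rejected as singular when
its smallest eigenvalue is below 1e-12 of its largest.

Weights are used exactly as the kernel produces them (not normalized to
sum to one); β is invariant to a global weight rescaling at λ = 0, and at
λ > 0 a rescaling is equivalent to rescaling λ, which CV absorbs.

**Cross-validation.** K-fold (default K = 5, seeded) over data points;
each held-out point is predicted by a local model anchored at itself and
fit from training folds only, so the prediction is simply the intercept;
the candidate minimizing summed squared error wins. Candidates with d > p
are skipped with a warning; a singular solve scores the candidate
infinite. CV optimizes response prediction error — the quantity the
estimator fits — not downstream simulation error.

**Factor activity and classification.** activity = a_f · √(M_ff / n) with
n the total number of candidate points of the fit; the square-root term is
the weighted RMS deviation of factor f inside the window, so activity
vanishes where a factor is locally constant regardless of its coefficient,
and its sign always equals the coefficient's. Classification crosses
sign(a_f) with sign(dy/dt): (−,−) type I repression, (−,+) type II
repression, (+,+) type I activation, (+,−) type II activation; any zero
sign is labelled null. The derivative sign defaults to the model's own
intercept (the fit's local mean derivative); the smoothed-derivative
estimate is available as an alternative source, and is the automatic
fallback for static bundles. An optional percentile mask for map rendering
(suppress |activity| below the q-th percentile) is off by default.

**Simulation.** Per cell, fixed-step RK4 (default 100 steps per unit time)
on dy/dt given by the cell's local model, driven by the presmoothed factor
polynomials evaluated at continuous time (raw linear interpolation is a
config alternative). Within [t_k, t_{k+1}) the model of time index
min(k, freeze_after) applies; freeze_after defaults to the last fitted
time, so a model fit on the first two time points uses the second time
point's equations for all later intervals. The initial condition is the
raw measured target at t₀, recorded exactly. Simulated concentrations are
*not* clipped at zero — negativity is model misfit and is reported in the
integrator log instead of being masked. Error maps are |simulated −
measured| per (t, e); the comparison statistic aggregates by L1 over cells
and selected times (RMSE available) and reports
100·(err_static − err_dynamic)/err_static.

## Synthetic study conditions

The generator emulates a blastoderm expression atlas: cells on a prolate
ellipsoid (axis ratio 2.5:1:1, Fibonacci lattice, seeded azimuthal phase;
optional exact left-right mirror pairs), six unit-spaced time points,
factors as sigmoid AP gradients and Gaussian stripes with slow temporal
drift and optional dorsoventral modulation, and a target integrated per
cell by fine-step RK4 from a known law of Hill and linear terms. Noise is
additive i.i.d. Gaussian truncated at zero, applied to all species or to
the target only. The law's rate, gradient, and the noiseless trajectories
are returned analytically, so estimator output is always checked against
exact ground truth. Defaults: E ∈ {200, 1000} cells for the two preset
suites, T = 6; the full-atlas scale (6,078 cells) is exercised by the
bookkeeping check only.

Two presets define the study conditions used throughout the tests:

- **Linear suite** (p = 2): dy/dt = 2x₁ − x₂ + 0.3, no decay, y(1) = 0.2.
  Amplitudes ramp linearly in time, so factor trajectories are degree-1
  polynomials, the target exactly quadratic, and a degree-2 presmoother
  plus unpenalized local fit solves the noiseless problem exactly — this
  suite grounds the machine-tolerance recovery checks. The rate is
  nonnegative over the pattern range and the initial level sits several
  noise SDs above zero, so truncated noise is effectively unbiased.
- **Hill suite** (p = 5): Hill activation by a BCD-like gradient
  (V = 1, K = 0.4, n = 2), Hill repression by a KR-like stripe (V = 0.8,
  K = 0.3, n = 2), a weak linear HB-like term (0.5), two low-amplitude
  non-regulating patterns, basal 0.05, σ = 0.02 noise. Each factor carries
  a small factor-specific smooth harmonic field over (AP, DV): without it,
  the five factor patterns are exact functions of three surface/time
  coordinates, the local factor covariance has rank 3, and the law's
  per-factor gradient is not identifiable entrywise (coefficients split
  arbitrarily between collinear factors). The fields emulate
  factor-specific biological variability and make the gradient
  identifiable; the two weak factors vary least, which is exactly what the
  minor-component penalty (d = 3, λ = 0.1) shrinks.

**What the passing tests do and do not show.** The synthetic suites have
smooth, well-separated patterns, independent truncated-Gaussian noise and
a target with no auto-regulation. Real atlas data differs in at least
three ways that the tests deliberately do not claim to cover:

1. *Regressor noise.* Measurement error in factor concentrations is an
   errors-in-variables regime: local linear fits then carry an attenuation
   bias that no sample size removes. The consistency experiment therefore
   uses response noise only; sign recovery (which is robust to moderate
   attenuation) is still demonstrated with noise on all species.
2. *Target feedback.* If the true law contains a −γy term (mRNA decay),
   the target level is an omitted confounder for any regression of dy/dt
   on factors alone, and entrywise gradients are unrecoverable in
   principle (replacing 99% sign agreement with ~50% at γ = 0.3 in our
   experiments). Fitted coefficients on real data estimate the *net*
   factor–derivative association, not a mechanistic partial derivative.
3. *Manifold degeneracy.* Where factors co-vary exactly, only the
   tangential component of the gradient is identifiable; the penalty makes
   the normal component small rather than correct.

## Numerical choices

- Polynomial fits via Vandermonde least squares (`numpy.polynomial`);
  residuals orthogonal to the basis to 1e-10 relative, interpolation exact
  at r = T − 1.
- RK4 is exact for the linear-growth and polynomial-rate cases used as
  oracles; the exponential-relaxation benchmark (dy/dt = −y + 1) is
  reproduced to < 1e-8 at 100 steps/unit, with step-halving changes
  < 1e-6 relative.
- CSV I/O round-trips float64 exactly (17 significant digits out,
  round-trip parsing in); model bundles serialize to JSON or HDF5 with a
  format version string checked on load.
- Constant species under min–max normalization map to zero (a constant
  carries no regression information); normalization is off by default
  since concentration units are arbitrary to begin with.
- Degenerate windows: support below p + 2 triggers bandwidth doubling
  (≤ 5×); exact duplicate anchors give the anchor weight 0.75 at zero
  distance, as the kernel prescribes.

## Known limitations

Beyond the three synthetic/real gaps above: the estimator is O(K·N) in
distance computations (K anchors, N candidate points) and fits the full
grid serially — the full-atlas scale is minutes, not seconds; the
spatial-correlation baseline inherits whatever frozen local models the
last fitted time provides and is expected to fail on strongly dynamic
targets (that failure is the point of the comparison); and no attempt is
made to distinguish direct from indirect regulation — coefficients
quantify net local association between factor deviations and target
dynamics.
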