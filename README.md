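# nodeinfer

Nonparametric ODE models of transcriptional regulation from spatio-temporal
gene expression data.

`nodeinfer` is for researchers who have per-cell, per-time measurements of
transcription-factor concentrations and a target mRNA — the structure of a
*Drosophila* blastoderm virtual embryo (thousands of cells on an ellipsoid
surface, a handful of developmental time points, gap-gene proteins such as
KR, GT, KNI, HB, BCD and a pair-rule target such as *eve*) — and want to ask:
**where, when, and in which direction does each factor influence the
target's rate of change?**

## The model

The target's dynamics are assumed to follow an unknown smooth ODE
dy/dt = f(x), with x the vector of factor concentrations. Rather than
positing a functional form for f, the package estimates its first-order
Taylor expansion separately at every (time, cell) anchor:

    dy/dt = Σ_f a_f,[t,e] · (x_f − x̂_f[t,e]) + b[t,e]

- **Presmoothing.** Each cell's trajectories are fit with low-degree
  polynomials in time; the target's derivative dŷ/dt is taken analytically
  from the fit (a tricube-weighted local-polynomial variant is available).
- **Concentration windows.** For each anchor x̂[t,e], all (time, cell) data
  points are weighted by an Epanechnikov kernel
  w = 3(1 − (n/h)²)/4 on their Euclidean distance n in *concentration*
  space — so cells anywhere on the embryo with similar regulatory input
  (including mirror-image cells) inform the local fit.
- **Manifold-penalized solve.** The local weighted linear regression is
  regularized by a ridge penalty restricted to the span of the p − d minor
  principal components of the windowed second-moment matrix ΞᵀWΞ:
  β̂ = argmin ‖W½(Y − Xβ)‖² + λ‖Pᵀa‖². Expression data concentrates near a
  low-dimensional manifold; the penalty shrinks the unidentifiable normal
  components of the local gradient while leaving tangential ones free.
- **Factor activity.** Each coefficient is scaled by the local RMS factor
  deviation, activity = a_f·√(M_ff/n), and classified by
  sign(a_f) × sign(dy/dt) into type I/II activation/repression.
- **Validation by simulation.** The fitted model family is integrated
  forward (RK4) from the measured initial pattern, driving it with measured
  factor trajectories, and compared against a static spatial-correlation
  baseline (identical machinery, response = target *level*) via an L1 error
  map and a percent-improvement statistic.

A synthetic virtual-embryo generator (`nodeinfer.synthetic`) provides
gap-gene-like patterns with a known regulatory law, exact derivatives and
analytic Jacobians, and is the ground truth behind the test suite.

## Worked example

Generate a 300-cell synthetic embryo with the 5-factor Hill-law suite, fit
the dynamic model and the static baseline on the first two time points
only, then simulate and compare on the remaining four:

```
$ nodeinfer synth --suite hill --n-cells 300 --seed 7 --out embryo.csv
wrote embryo.csv (300 cells x 6 times)

$ nodeinfer fit --data embryo.csv --target eve --factors bcd,kr,hb,kni,gt \
      --kind node --fit-times 1,2 --h 0.08 --lam 0.1 --d 3 --out node.json
fit 600 local models (selected tuning {'h': 0.08, 'lam': 0.1, 'd': 3, 'r': 2, 'h_mode': 'knn_frac'})

$ nodeinfer fit --data embryo.csv --target eve --factors bcd,kr,hb,kni,gt \
      --kind spatial_corr --fit-times 1,2 --h 0.08 --lam 0.1 --d 3 --out sc.json
fit 600 local models (selected tuning {'h': 0.08, 'lam': 0.1, 'd': 3, 'r': 2, 'h_mode': 'knn_frac'})

$ nodeinfer activity --bundle node.json --data embryo.csv --out activity.csv
wrote activity.csv (3000 activity values)

$ nodeinfer simulate --bundle node.json --data embryo.csv --out sim.csv
total L1 error 77.6258

$ nodeinfer compare --node-bundle node.json --spatial-bundle sc.json \
      --data embryo.csv --out compare.json
percent improvement 98.46%
```

`activity.csv` is a long table `cell_id,time,factor,activity,label`, e.g.

```
cell_id,time,factor,activity,label
1,1,bcd,-2.664861213e-05,type_II_repression
2,1,bcd,0.0004937064193,type_I_activation
```

The simulate step reports the summed absolute difference between the
simulated and measured target pattern over all cells and times (77.6 here,
i.e. ≈0.04 concentration units per cell-time). The compare step scores
both models on the four time points *after* the fitting window: the
dynamic model's 71.1 total error versus the static baseline's 4611.7 gives
a 98.5% error reduction — on this synthetic suite the target keeps rising,
which a static level model cannot extrapolate by construction.

The same workflow is available as library calls (`fit_node_model`,
`fit_spatial_correlation_model`, `simulate_node`, `compare_models`,
`factor_activity`); `fit_general_timeseries` applies the estimator to
multi-experiment time-series of arbitrary state vectors, returning a
Jacobian/drift pair (A_ξ, b_ξ) per linearization point.

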