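# Methods

## Problem and model class

`intflux` estimates kinetic parameters of ODE models of biochemical
reaction networks,

    dX/dt = S v(X, p),    X(0) = X0,

where `X` are species concentrations (m species), `S` is the m×n
stoichiometric matrix and `v` the vector of n reaction rates.  Two
rate-law families are supported:

* **generalized mass action (GMA / power law)** — `v_j = a_j ∏_i X_i^{g_ji}`
  with rate constant `a_j ≥ 0` and real-valued kinetic orders `g_ji`
  (negative orders encode inhibition);
* **lin-log** — rates linear in the logarithms of concentrations.  The
  package uses the simplified parameterization `v_j = a_j + ∑_i g_ji ln X_i`:
  reference-state fluxes, enzyme levels and elasticities are folded into
  `a` and `g`, which therefore carry no direct physical interpretation.
  The law is linear in its parameters for fixed concentrations, which the
  inner estimation exploits.

## Integrated fluxes

The integral form of the mass balance,

    X(t_k) − X(0) = S η(t_k),      η_j(t_k) = ∫_0^{t_k} v_j dt,

connects concentration changes to the *integrated fluxes* (IFs) — the
per-volume extents of reaction.  When `S` has full column rank, `η(t_k) =
S⁺ (X_M(t_k) − X_M(0))` follows directly from the measured data, with no
smoothing or differentiation.  In cellular networks `S` is usually
column-rank deficient (species participate in several reactions, m < n);
the rank deficiency `n − rank(S)` counts the degrees of freedom in the IF
calculation.  The reactions are then partitioned into an *independent*
subset of exactly that size and a *dependent* remainder, chosen so that
the dependent column block `S_D` has full column rank.  Given candidate
parameters for the independent reactions, their IFs `η_I` are integrated
from the measured concentrations, and the dependent IFs follow uniquely:

    η_D(t_k) = S_D⁺ (X_M(t_k) − X_M(0) − S_I η_I(t_k)).

Partition selection guidelines (implemented in `rank_partitions`): the
pseudo-inverse of `S_D` must exist; among valid partitions prefer the
fewest independent free parameters (outer search cost grows with that
dimension), then the smallest total width of their bound ranges, with a
lexicographic tie-break for determinism.  Exhaustive enumeration of
candidate subsets is capped at n ≤ 12; larger networks require
user-supplied candidates.

## Nested estimation (IFPE)

The estimation is a nested optimization.  The **outer** problem searches
the independent parameters `p_I` within bounds, minimizing the
concentration-prediction error

    Φ = sqrt( (1/mK) Σ_k ‖X(t_k; p_I) − X_M(t_k)‖² ).

For each candidate `p_I` the **inner** problem fits the dependent
parameters `p_D` to the data-derived dependent IFs by minimizing the same
RMS form on IF tables (`Φ_in`, normalized by mK as a matter of convention —
the constant does not move the argmin).  Because each free parameter
belongs to exactly one rate law, the inner fit decomposes one reaction at
a time:

* lin-log laws: the predicted IF is `a_j (t_k − t_0) + ∑ g_ji ∫ ln X_i dt`,
  linear in `(a, g)`; the integrals of `ln X_i` are computed once per
  dataset and the problem is solved by bounded linear least squares
  (`scipy.optimize.lsq_linear`).
* GMA laws: bounded trust-region nonlinear least squares with an analytic
  Jacobian, multi-started from the box midpoint plus 4 seeded
  Latin-hypercube draws (the per-reaction landscape can be multimodal).

The concentration prediction is then formed either from the integral form
itself (`ifpe`: `X = X0 + S η(X_M, p)`, cheap, no ODE solve) or by
simulating the ODEs at the assembled parameters (`ifpe-ode`).

Positivity: reaction fluxes and IFs must be non-negative.  Candidates
violating this incur an additive penalty of 10⁶ per violating entry
rather than hard rejection, keeping the outer search informative near the
constraint boundary; the violation count is reported in diagnostics.

## Baselines

* **IPE (incremental)** — the data are smoothed by least-squares
  piecewise polynomials; dependent flux *values* are solved from the
  spline derivatives, `v_D(t_k) = S_D⁺ (dX_M/dt − S_I v_I)`, and the
  inner fit regresses each rate law on those values.  For GMA laws the
  log transform `ln v = ln a + ∑ g ln X` makes this a bounded linear
  least-squares problem (non-positive flux estimates are dropped with a
  logged count); lin-log laws are linear as-is.  The outer objective is
  either the slope error (`ipe-slope`, no integration at all) or the
  simulated concentration error (`ipe-ode`).
* **SPE (simultaneous)** — a single bounded global search over *all* free
  parameters with the concentration objective (`spe-ode`) or the slope
  objective (`spe-slope`).

The recovery accuracy of the IPE/SPE-slope baselines depends on the
smoothing setting `(s, o)`; IFPE uses no smoothing and has no such
dependence (offline-species input trajectories are the one exception, see
below).

## Identifiability of lin-log offsets

Lin-log rates are affine in their parameters, which has a structural
consequence: shifting the offset vector `a` by any right-null vector of
`S` leaves `S v` — and therefore every concentration trajectory and
every objective in this package — exactly invariant.  Whenever
`n − rank(S) > 0` and all offsets are free, absolute offset levels are
unidentifiable from concentration data; only the combinations orthogonal
to the null space are determined.  (Power-law rates do not suffer this:
a constant flux shift is not representable within the GMA family.)  The
packaged lin-log toy fixes one offset per null direction (the inflow
offset, treated as known), making the remaining parameters identifiable;
for lin-log fits with free offsets the meaningful report is the fit
quality Φ and identifiable combinations, not per-parameter errors.

## Quadrature

Integrals on the measurement grid use a half-panel Simpson scheme: the
increment over `[t_{k−1}, t_k]` is the exact integral of the quadratic
through `(t_{k−2}, t_{k−1}, t_k)`; the first panel uses the quadratic
through the first three points.  The scheme needs no grid uniformity or
point-count parity, is linear in the integrand values (it is precomputed
as a lower-triangular weight matrix per grid) and is exact for
polynomials of degree ≤ 2.  On 50-point grids over the benchmark
transients the relative error against dense-grid oracles is below 10⁻³
away from the first panel (where the integral itself is near zero, the
error is bounded relative to the IF scale instead).

## Smoothing splines

Least-squares piecewise polynomials of degree `o` on `s` equal-width
sections, built as B-splines with interior knots of multiplicity `o − 1`
— continuity of value and first derivative at the breakpoints, so
`dX_M/dt` is defined everywhere.  Equal-width sections and C¹ continuity
are this package's choices (common smoothing defaults); knot placement is
not optimized.  K ≥ s(o+1) observations are recommended (a warning is
emitted below that).  No smoothing-parameter auto-selection is provided.

## Optimization

The outer search is a compact scatter-search-style metaheuristic: a
seeded Latin-hypercube population (size 10·dim by default — population
scales linearly with search dimension), a reference set of elite plus
max-min-diverse members, random pairwise combination steps, and periodic
local polish of the incumbent.  The polish uses Powell's bounded
derivative-free method (budget 3 iterations, every 10th iteration):
penalty cliffs and inner-solver noise make finite-difference gradients
unreliable, which rules out quasi-Newton polish here.  Termination: the
relative best-so-far improvement stays below 10⁻⁵ for 50 successive
iterations, or iteration/evaluation budgets run out.  Identical seeds
reproduce identical traces.  Failed evaluations (exceptions, non-finite
values) become a large sentinel objective.  The published enhanced
scatter-search internals are not reproduced; the implementation satisfies
the same contract (population metaheuristic, reference set, combination,
local polish, the stagnation rule above).

ODE integration uses LSODA with rtol 10⁻⁸, atol 10⁻¹⁰ and a work budget
of 10×5000 right-hand-side evaluations per solve; budget overruns and
non-finite states surface as errors that the estimators convert into the
sentinel objective.

## Synthetic benchmarks

The generator simulates a fixture model at its ground-truth parameters
and optionally adds independent additive Gaussian noise, zero mean, 10%
coefficient of variation (sd = 0.1·X per cell), as five technical
replicates by default.  Noisy values falling below a positive floor
(10⁻⁶ × the maximum concentration) are clipped there, because power-law
and lin-log rates need X > 0.  Replicates are always fitted
independently and summarized as mean ± sd of the error metric — never
averaged before fitting.  The default sampling grid is 50 uniform points
across the transient.

Fixtures:

* **branched** — generic branched GMA pathway: inflow `v1` under feedback
  inhibition by the end product X4, branch point at X1, side branch X3
  cross-inhibiting the main-branch step, outflow `v6`.  4 metabolites, 6
  reactions, 13 free parameters, dof 2; independent set {v1, v6} is the
  default (square invertible `S_D`, 4 independent parameters; {v1, v4}
  has 5).  Rate constants bounded in [0, 25], kinetic orders in a
  width-2 box ([0, 2], sign-flipped for the two inhibitory orders).  The
  shipped ground truth is synthetic (chosen once for the in-silico
  benchmark, with all rates positive along the transient); a user config
  can substitute other values.  The observation window (T = 2.0, 50
  points) follows a timescale rule: the grid step is kept below about a
  third of the fastest relaxation timescale at steady state (Jacobian
  eigenvalues give τ_fast ≈ 0.16, τ_slow ≈ 0.76), so the measurement-grid
  quadrature resolves the transient and the noise-free objective at the
  truth sits at the 10⁻⁴ level rather than creating a displaced optimum.
* **lactis lin-log** — structural reconstruction of an L. lactis
  glycolysis lin-log model: 9 metabolites of which external glucose, ATP
  and Pi (X7–X9) are *offline* — they modulate rates but carry no mass
  balance; their trajectories come from spline smoothing of data, with
  (s, o) = (6, 4) as the study setting.  9 fluxes, dof 3 over the 6
  balanced species, default independent set {v5, v7, v9}, bounds
  [−500, 500].  Shipped without truth values (structure-only); synthetic
  lin-log recovery is exercised on the lin-log toy instead.
* **toys** — 2-species/3-reaction chains (one GMA, one lin-log), dof 1:
  the smallest networks exercising the nested machinery end to end.

What the synthetic data do *not* emulate: model mismatch (data are
generated from the same equations that are fitted — an idealized,
a-priori-identifiable setting), irregular or sparse sampling, partially
measured species, correlated or non-Gaussian measurement error.  Passing
recovery tests therefore demonstrate correctness of the estimation
machinery, not robustness to structural error in real data.

## Numerical choices and edge cases

* Stoichiometric rank uses SVD with singular values below 10⁻⁸ × the
  largest counted as zero (stoichiometric coefficients are small
  integers; the spectral gap is wide).
* `S_D⁺` is computed once per partition and cached; per-time-point
  application is a matrix–vector product.
* Non-positive concentrations where a logarithm or fractional power is
  required raise a domain error naming the species and reaction; inside
  the ODE right-hand side concentrations are floored at 10⁻¹² so that
  trial steps of the solver stay evaluable.
* Missing data cells are flagged on read, never silently filled; linear
  interpolation (nearest-value at the boundaries) is an explicit step.
* The noise-free benchmark protocol runs the full estimation under
  several seeds and reports the run with the lowest objective; noisy
  protocols fit each replicate separately and report mean ± sd.

## Problem sizes used in the shipped benchmarks

The packaged test-suite and reproduction-script runs use the 50-point
(branched, T = 2) and 60-point (toy, T = 8) grids, outer-search budgets
of 25–150 iterations with evaluation caps of 2,500–6,000, and 1–5
seeds/replicates per protocol (noise-free runs report the
best-objective repeat; noisy runs fit five technical replicates
independently).  These sizes were chosen so the whole benchmark suite
runs on a single CPU in minutes while leaving the qualitative method
ordering (IFPE ≪ SPE at equal budget; IPE accuracy strongly
(s, o)-dependent, IFPE smoothing-independent) clearly resolved.

## Known limitations

* The partial-measurement scenario (unmeasured species) is out of scope;
  all balanced species must be measured.
* No identifiability analysis, confidence intervals or ensemble
  modeling.
* Lin-log reference states are not modeled; no thermodynamic validation.
* The quadrature is fixed to the measurement grid; no adaptive
  refinement between points, so very sparse grids over fast transients
  bias the IFs (visible as the first-panel error discussed above).
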