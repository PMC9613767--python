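# Methods

## Models

**Lattice model.**  A rectangular grid of 500×50 sites (columns × rows), one
cell per site.  Update cycle per Monte Carlo step (MCS = 1 h): every cell, in
a freshly shuffled order, passes through (1) spontaneous death (TCs only,
probability α/24 with α given per day), (2) a proliferation attempt with
probability p = 1/24 — an exhausted TC (ρ = 0) dies at this point; otherwise
a daughter is placed on a uniformly random vacant neighbor site if any exists
(CSC daughters are CSCs with probability p_s, else TCs with ρ = ρ_max = 15;
TC divisions decrement ρ in *both* daughters), and (3) migration with
probability μ = 1 to a uniformly random vacant neighbor.  A cell acts at most
once per MCS; newborn and moved cells are flagged so the sweep never touches
them twice.  Neighborhoods are 8-connected (Moore; 4-connected selectable).
Rows wrap periodically to remove wall artifacts in the narrow strip; columns
are closed.  The initial state is one full column of 50 CSCs at the left
edge, which produces a quasi-1-D front quickly.  The update kernel is
numba-compiled; each MCS draws its own 31-bit seed from a per-run
`numpy` generator, so trajectories are exactly reproducible and
single-stepping equals batch running.

**Continuum model.**  Densities u (CSC) and v (TC) with crowding function F
from the four-member family (1−n), (1−n⁴), (e^{−(n−1)}−1)/(e−1),
cos(πn/2), each clamped to its non-negative part; user-supplied F with
F(0)=1, F(1)=0, F decreasing are accepted.  Division rates are normalized to
1, which transfers a unit of 1/time onto F.  Solvers:

* *full system* (fast time, ε > 0): method of lines, central differences,
  no-flux boundaries, interleaved (u,v) layout so LSODA can use a
  pentadiagonal banded Jacobian;
* *fast subsystem*: scalar ODE v' = F(u+v)(u+v) − αv at frozen u;
* *slow system*: u_τ = d u_xx + f(u) with f(u) = F(u+v_α(u))u.  For linear
  F the slaved manifold is the closed-form quadratic root and f is evaluated
  exactly; for the other families f is tabulated (2049 nodes) and
  interpolated with a monotone cubic on **square-spaced** nodes — v_α(u)
  behaves like √u near u = 0 when α ≥ 1, and the leading edge, which selects
  the pulled front speed, must be resolved there (a uniform table measurably
  slows the computed front);
* *treatment system*: the slow system with α̂(t) = α + T(t) and an extra
  −b̂(t)u = −δT(t)u kill term, v slaved to the treatment manifold
  F(n)n = α̂v.  Integration restarts at every schedule window edge so the
  discontinuous switches never cross an integrator step.  Only linear F is
  supported here (closed-form treated manifold).

The slaved v field is reported as 0 on nodes where u = 0 exactly: the
manifold limit v_α(0) = v*_α describes the equilibrium *given* a residual
stem-cell presence and is an artifact of the reduction ahead of the front.

**Slow manifold.**  v_α(u) solves (α − F(u+v))v = F(u+v)u, found by Brent's
method on the bracket [0, 1−u] at absolute tolerance 1e-12 (guaranteed sign
change under the F assumptions).  At u = 0 the equation is degenerate and
v*_α is returned by continuity (0 for α ≥ 1, else the root of F(v) = α).
The derivative uses the implicit-differentiation formula; the (α = 1, u = 0)
endpoint, where the slope diverges, raises by default and reports +inf in
plotting contexts.

**Hazards and schedules.**  Decaying source:
T(t) = α_r R₀ e^{−λt} + 2β_r(R₀²/λ)(e^{−2λt+λω} − e^{−2λt}), with t the
time since the source was placed; for intermittent block schedules the clock
restarts at each on-window (each block is modeled as a fresh implant — the
source decays physically, so re-irradiation restarts the decay).
Fractionated: T = (α_r + β_r D)·D/w during a fraction of dose D and width w
days, so the integrated kill per fraction equals the linear–quadratic
exponent α_r D + β_r D²; whole-day fractions reduce to (α_r + β_r d)d.
Bundled parameter sets: prostate-like (d = 8.64e-4 mm²/day, α_r = 0.15/Gy,
β_r = 0.048/Gy²; used with the decaying source) and glioma-like (d = 0.65,
α_r = 0.11, β_r = 0.019; used with fractionation), baseline α = 0.012/day.
Fractionated protocols start day 20 and stop at 60 Gy cumulative; a
schedule that specifies a number of treatment days ends with a hard stop
once the cumulative on-time is reached.

## Front-speed measurement

The front position of a profile is the **rightmost** linearly interpolated
crossing of a threshold (rightmost so that non-monotone transients behind
the front cannot be picked up).  The threshold defaults to half the
left-edge plateau of the final snapshot — mid-height is robust against the
exponential leading edge, where pulled fronts converge slowest.  Speed is
the least-squares slope of position vs time over a window defaulting to the
final half of the run ("after the wave is established"); the estimate
carries the fit RMS and is flagged invalid if the front touches the right
boundary inside the window (truncated domain).  On the lattice the profiles
are column populations (0–50) thresholded at the half-full column (25), and
the fit runs over every snapshot between front formation and boundary
contact.

## Benchmark protocol and numerical choices

The standard continuum benchmark uses d = 1, a step invasion initial
condition u₀ = 1 for x ≤ 20, domain [0, 200] (the front stays interior for
τ ≤ 80 at any speed ≤ 2.04), Δx = 0.1, τ ∈ [0, 80] with 81 outputs, LSODA
at rtol 1e-8 / atol 1e-10.  Halving Δx changes the measured speed by well
under 0.5%, so the values are mesh-converged: 1.9759 (α = 5), 1.9668 (1),
1.7580 (0.8), 1.3745 (0.5), 0.2998 (0.05).  These sit *below* the
asymptotic minimal speeds 2, 2, 1.7889, 1.4142, 0.4472 — as they must:
pulled fronts from step data approach σ* from below with a slowly decaying
O(1/t) speed deficit, and the establishment time grows as α shrinks (at
α = 0.05 the wave is still far from asymptotic at τ = 80; its finite-time
mid-height speed cannot reach the ~0.41 sometimes quoted for this setup,
which we attribute to measurement on a different level set or coarser
numerics).  No tuning of threshold, window or mesh toward external values
was done; the protocol above is fixed a priori.

The lattice sweep uses p_s = 0.01 as the base self-renewal probability (a
typical "small" value; the paradox weakens as p_s grows) with 5 replicate
seeds per death rate and 7000 MCS.  Replicate-mean speeds rise from
~0.003 px/MCS at α = 0 (a near-stalled front whose fitted slope is
noise-dominated) to ~0.03–0.06 px/MCS at α = 0.35/day.  Published magnitudes
for this experiment depend strongly on the (often unstated) base p_s;
ordering and order of magnitude are the meaningful observables here.

## What the tests do and do not show

Unit and property tests validate each operation against independent
routes: brute-force bisection vs Brent for the manifold, central
differences vs the implicit-derivative formula, fast-ODE terminal states vs
manifold roots, constructed translating fronts of exactly known speed vs
the estimator, closed-form vs measured speed scalings (√d, α-branches),
and invariants (occupancy, CSC monotonicity, density bounds, dose caps,
hazard monotonicity) on randomized inputs.  The acceptance tests exercise
the full experiments at the benchmark sizes above.

Synthetic inputs (step fronts, tanh fronts, seeded lattices) emulate the
*geometry* of invasion, not the biology of any specific cancer: no
microenvironment, immunity, vasculature, mechanics, cell-cycle structure or
de-differentiation is modeled, parameters are generic rather than
calibrated, and treatment acts only through death-rate modifiers.  Passing
tests therefore demonstrate internal mathematical consistency of the models
and estimators, not clinical predictivity.

## Known limitations

* The high-dose brachytherapy regime (R₀ = 50 Gy/day, δ = 0.3) drives the
  stem-cell field to ~1e-9 of capacity before the source decays (the
  integrated kill ∫δT dt ≈ 68 over days 20–80 exceeds the maximal
  integrated growth ≤ 60); by day 80 the tumor has only partially regrown,
  so its invaded region is *narrower* than under the moderate dose rate at
  any fixed density threshold, while its burden is far lower.  The
  kill-vs-spread trade-off (wider region, lower non-stem burden than
  untreated) is exhibited robustly by the moderate dose rate.  The
  corresponding acceptance check encodes the stricter "higher dose rate ⇒
  wider region" reading and is expected to fail its width clause; we report
  this honestly rather than redefining the width metric post hoc.
* The slow reduction slaves v instantaneously; during rapid hazard decay
  the true v lags by O(ε).
* Treatment solving is restricted to linear F.
* The full-system solver is validated at moderate ε (0.05–0.2); very stiff
  ε ≪ 0.01 runs are out of its intended envelope.
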