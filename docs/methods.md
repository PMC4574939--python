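# Methods

`mbdoe` designs experiments for nonlinear ODE models whose parameters are
only known up to a box of plausible values. Given prior noisy data, it
chooses (i) a piecewise-constant stimulus sequence and (ii) K measurement
pairs (species, time) so that, once the experiment is performed, the
remaining uncertainty in the trajectories of user-chosen *target states* is
as small as possible. This note records the model, the algorithmic choices,
the defaults, and what the bundled synthetic study does and does not
demonstrate.

## Problem setting

The system is

    dx/dt = f(x, u, θ, θ′, t),  x(T_I) = x0,      y = h(x, u, θ, θ′, t)

with known parameters θ, unknown parameters θ′ ∈ Ω (a finite box), a
piecewise-constant input u switching only at user-fixed admissible times
𝓣 = {τ_1 … τ_N} (control vector parameterization; segments are half-open
[τ_j, τ_{j+1}) so evaluation at a switch time is unambiguous, and the last
segment runs to T_F), and measurable outputs y. A *target system* is a
subset of states x_T observed under a fixed target input u_T.

The design objective is the **target-state dynamical uncertainty** (TDU)

    γ(u) = Σ_i max_t Var( x_{T,i}(t) )

— the sum over target states of the time-maximum probability-weighted
variance of their trajectories across the data-consistent parameter
ensemble.

## Stage a — acceptable and representative parameters

A parameter vector is *acceptable* when its simulated outputs fit the data:

    fitness(θ′) = log10( 1 + Σ_records ((ỹ − ŷ)/σ)² ) ≤ T_A,    T_A = 2.

Ω is sampled by Latin hypercube; model outputs come from an adaptive
sparse-grid surrogate (below) rather than per-sample ODE solves. If fewer
than N_A acceptable vectors are found, *focused grids* — refined surrogates
on padded bounding boxes of the acceptable points found so far (boxes from
DBSCAN clusters in the unit-scaled box, 10 % padding, up to 5 rounds) —
are re-sampled until the set is large enough or the round cap is hit.

A subsample of the acceptable set (default 600) is simulated directly and
its output trajectories on the sampling grid are clustered into
*experimentally distinguishable dynamics*: L2 distance on range-normalized
outputs, a locally scaled Gaussian affinity (per-point bandwidth = distance
to the 7th neighbour; a single global bandwidth cannot separate balanced
bundles), and the cluster count from the largest eigengap of the
normalized-Laplacian spectrum (k ≤ 6; on a continuum of dynamics the eigengap occasionally fragments
into ten or more clusters, which multiplies the representative count and
the greedy search's cost without adding distinguishable dynamics — the cap
keeps N_RA near the few-dozen scale the probability weighting is designed
for). From each cluster, C = 12 convex-
hull vertices of the member parameter vectors are drawn at random (hull
vertices are the dynamical extremes; clusters with fewer vertices are
topped up with members nearest the hull, and degenerate clusters fall back
to their distinct members). The pooled N_RA = C·k *representative
parameters* carry uniform initial probability weights; every ensemble
expectation and variance downstream is weighted over them.

## Stage b — greedy input design

Input magnitudes are discretized per dimension as
u_p = u_min + (p−1)·δu with N_u = ⌊(u_max − u_min)/δu⌋ + 1 levels. Each
greedy iteration considers every not-yet-optimized admissible time τ_j and
every level; a candidate splices the level into the current schedule from
τ_j up to the next previously optimized time. Candidates are scored as
"prior + one optimally placed measurement":

1. simulate (or interpolate) representative outputs under the candidate;
2. pick the single measurement pair maximizing the distinguishability
   metric ξ (below);
3. predict its datum as the weighted median of representative predictions,
   Bayes-update a *fresh copy* of the uniform weights;
4. recompute γ from the (pre-computed) target trajectories with the updated
   weights.

The hypothetical update never accumulates across iterations — each
iteration re-scores from the uniform prior. Accumulating updates would
collapse the weights onto one or two representatives within a few
iterations and reduce the trace to numerical noise; scoring with a single
hypothetical measurement keeps the trace interpretable as "how much one
good measurement would resolve under this input". The best (τ*, u*) is
accepted only if it strictly lowers TDU; ties break toward the smaller
admissible time, then the smaller level index. The search stops when 𝓣 is
exhausted or no change improves TDU, so it runs at most N iterations.

When N_u exceeds the predicted 1-D grid size, a per-representative
interpolant over the input magnitude is built per (τ_j, iteration) and
sampled at all levels; otherwise levels are simulated directly. The input
dimension uses nested Chebyshev–Gauss–Lobatto nodes with a polynomial
(barycentric) basis rather than the piecewise-linear hierarchy: the
response is smooth in the input level, and at the 9–33 nodes the depth cap
(5) allows, the polynomial basis cuts the worst-case interpolation error
from several output units to well below the measurement-noise scale —
piecewise-linear scoring at the same budget visibly distorts candidate
ranking. Node counts per depth (9/17/33) match the 1-D sparse-grid counts,
so the budget accounting is unchanged. Multi-input problems vary one input
dimension at a time.

A closed-form bound on total model simulations,

    T_eval = SG_θ + N_A + min(N_u, SG_u)·N_RA·N(N+1)/2 + N_RA,

is logged with every run and asserted against the actual per-stage counts.

## Stage c — scenario-tree measurement selection

Under the designed input, the *distinguishability metric* per output i is

    ξ_i(t) = Hampel( Var(y_i(u, ·, t)) / E(σ_i(u, t))² )

where the variance is over representatives, E(σ²) is the weighted
expectation of the squared expected-noise model
σ = ζ_b + ζ_s·|y| + ζ_t·|ẏ| (defaults ζ_b = 0.05, ζ_s = 0.1, ζ_t = 0.01
min; output time-derivatives by finite differences; measured data sd
overrides the model when available), and the Hampel identifier (window
half-width 3 grid steps, 3-sigma rule with the 1.4826 MAD scale) removes
isolated spikes along time.

Because no data exist at design time, a 3-branch scenario tree plans K
measurements: each node selects its pair among the top-5 by ξ as the one
whose median-outcome Bayes update minimizes γ; its three children condition
on the weighted 10th/50th/90th-percentile predicted outcomes (left-
continuous weighted CDF with ≥ thresholds) and re-select under the branch
posterior. Pairs already measured on the node's own root path are excluded
from re-selection (repeats across branches remain possible and are recorded
once in the final plan). The tree starts from uniform weights — the greedy
phase's hypothetical updates are not carried over — and grows breadth-first
until it contains at least K unique pairs, with caps on depth and on
consecutive levels that add nothing.

## Sparse-grid surrogates

The surrogate is a hierarchical piecewise-multilinear sparse grid on nested
equidistant nodes (level 0: box midpoint; level 1: endpoints; level ℓ ≥ 2:
odd multiples of 2^−ℓ). Surpluses are stored per node, so stored nodes are
reproduced exactly (≤ 1e-10, tested), and multilinear polynomials are
reproduced exactly once the grid depth reaches the dimension. Refinement is
level-by-level; the error estimate is the largest absolute surplus of the
newest level (relative form: divided by the per-output value range).
Termination: max depth (3 for screening grids, 5 for focused and input
grids), or relative error ≤ 10 %, or absolute error ≤ 5 — whichever comes
first; an optional node cap is enforced before a level is added. Failed
node evaluations are flagged, logged, and contribute nothing. Full state
*and* output trajectories are stored on a dense uniform 151-point time
grid; off-grid times use local barycentric Lagrange interpolation (cubic
stencils, exact pass-through at grid hits). Interpolants serialize to a
single npz archive (JSON header + binary node table).

The screening surrogate on a wide box is deliberately coarse (depth 3);
screening *decisions* still agree with direct simulation for ≥ 95 % of LHS
points (tested), because most of the box is decisively inconsistent with
the data. Everything that decides the *verdict* on a design — the in-silico
evaluation below — uses direct ODE solves, not the surrogate.

## In-silico evaluation

A synthetic *plant* (the model at nominal parameters) is stimulated with
the designed input; each designed pair is measured in 3 replicates with
additive Gaussian noise of sd = noise_frac·|y| (default 10 %); the dataset
records the replicate mean and empirical sd (floored at 1e-6 of the output
scale so the fitness stays finite). The new records pool with the initial
data under the same T_A, which tightens the per-record tolerance as records
accumulate.

The *dynamical uncertainty region* of a target state is the band spanned by
the most extreme acceptable trajectories under u_T; the headline statistic
is the envelope **area** reduction 100·(1 − A_after/A_before) (the
pointwise-max band-width reduction is also reported). Estimating extreme-
trajectory envelopes from finite samples is biased narrow, so the evaluator
works as follows, all by direct simulation:

- candidate pool = stored acceptable points + a large fresh LHS (linear and
  log-scale halves, the latter covering the decades of the box) prescreened
  through the surrogate with a 0.15 log10 margin, then direct-verified;
- focused refinement rounds (box the surviving post-experiment points, pad
  25 %, LHS inside, direct-verify) until the after-set has ≥ 250 members —
  seeded from the nearest near-misses if the pool has none;
- one breadth round for the before-region (validated to converge after a
  single round against a 60k-point reference).

Containment of the plant trajectory in the final band is reported with a
slack of 1 % of the band width: all trajectories share x0, so early-time
bands are razor-thin and strict containment would fail by O(1e-2) even for
a substantively correct band.

TDU reduction for comparing designs is computed over the re-screened
acceptable ensembles with uniform weights (the variance analogue of the
envelope metric). Conditioning the representative weights on the real data
is also reported (`tdu_reduction_posterior`) but saturates near 100 % for
any reasonable design once ~10 real measurements exist, so it does not
discriminate.

## Bundled Hes1 study and defaults

The bundled model is the 3-state Hes1 negative-feedback oscillator (mRNA m,
cytosolic protein P1, nuclear protein P2) with known degradation rate
k = 0.03 /min and transport rate k1 = 0.16 /min; unknown repression
threshold P0, Hill coefficient h, and translation rate ν, each bounded by
0.1–10× the nominal values (2.4, 2, 0.025 /min). The stimulus α scales the
transport rate (α·k1), α ∈ [0.01, 2] at resolution 0.05 (40 levels),
switchable at {0, 2, 5, 8, 10, 50, 100, 150, 200} min; measurements of m
and P1+P2 on a 10-min grid over [0, 300] min; K = 8; targets m, P1, P2
under α = 1.

Choices the problem statement leaves open, fixed here once:

- **Initial condition** x0 = (2, 5, 3), configurable. All reduction
  percentages are conditional on x0 — it controls how informative the early
  initial measurements are and therefore how broad the initial acceptable
  region is.
- **Initial data**: m and P1+P2 at t = 10, 20, 60 min, 3 replicates, 10 %
  noise, empirical-sd records.
- **Ensemble sizes**: n_lhs = 10,000 screening samples, N_A = 2000,
  clustering subsample 600, C = 12 per cluster (N_RA lands near 48 for the
  k = 2–4 clusters typical here). These sizes keep a full design+evaluate
  run near one minute on a single core while leaving the weighted-ensemble
  machinery non-degenerate.

## What the synthetic study shows — and does not

The plant shares the model's structure exactly (no model mismatch), its
noise is Gaussian and uncorrelated, replicates are i.i.d., and x0 is known
to the designer. Passing tests therefore demonstrate the *machinery* —
screening correctness against direct simulation, greedy optimality against
exhaustive enumeration at toy scale, posterior normalization and
concentration, envelope estimation — not performance on real data, where
structural mismatch and non-Gaussian noise would widen the residual band.

Reduction percentages are strongly conditional on the breadth of the
initial acceptable region and on T_A: the post-experiment band cannot
shrink below the ±~2 sd per-record tolerance that T_A implies, so with the
bundled conditions (tight, informative initial data) typical per-target
envelope reductions land in the ~45–75 % range across seeds, with the mRNA
target highest. The joint input+measurement design beats a measurement-only
design on TDU reduction in the majority of seeds (tested).

## Known limitations

- Admissible switch times are user-fixed; the package optimizes magnitudes
  only, and one input dimension at a time.
- The sparse grid is level-adaptive, not dimension-adaptive; very
  anisotropic responses pay for it in nodes.
- The eigengap cluster count on a continuum of dynamics is a heuristic; it
  varies across seeds (k = 2–11 observed), and N_RA = C·k varies with it.
- The scenario tree assumes Gaussian likelihoods and exactly three branches
  per node.
- A 19-dimensional two-drug immune-signalling configuration is referenced
  in the budget-bound defaults, but no second model ships with the package;
  plugging one in requires only registering its `DynamicalModel`.
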