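# mbdoe — global model-based design of experiments for uncertain ODE models

Mechanistic ODE models of biological systems are routinely left with wide
parameter uncertainty: limited, noisy data are fit by a whole region of
parameter values, each implying different dynamics. `mbdoe` designs the
*next* experiment — a piecewise-constant stimulus sequence **u** plus K
measurement pairs (species, time) — so that the new data shrink the
**dynamical uncertainty** of chosen target states as much as possible,
without assuming a good initial parameter estimate. It is aimed at
systems-biology modellers planning stimulation/sampling protocols (e.g.
ligand or drug schedules with a fixed sampling budget).

## Method in brief

For a model dx/dt = f(x, u, θ, θ′, t), y = h(x, u, θ, θ′, t) with unknown
parameters θ′ in a box Ω, the design minimizes the target-state dynamical
uncertainty

&nbsp;&nbsp;&nbsp;&nbsp;γ(**u**) = Σᵢ maxₜ Var(x_{T,i}(t)),

the probability-weighted trajectory variance of the target states, via
three stages:

1. **Screen** Ω with Latin-hypercube samples through an adaptive
   sparse-grid surrogate of the model; keep the parameters consistent with
   existing data, log₁₀(1 + Σ((ỹ−ŷ)/σ)²) ≤ T_A; cluster their dynamics
   (spectral clustering, eigengap model order) and draw *representative
   parameters* from each cluster's convex hull, with probability weights.
2. **Greedy input search**: input magnitudes are discretized
   (N_u = ⌊(u_max−u_min)/δu⌋+1); each iteration scores every remaining
   admissible switch time and level by the γ that would remain after one
   optimally placed measurement (distinguishability metric
   ξ = Hampel(Var(y)/E(σ)²), Bayesian weight update on the predicted
   datum), and accepts the best strictly improving change.
3. **Scenario tree**: under the designed input, a 3-branch tree of
   hypothetical outcomes (weighted 10th/50th/90th percentile predictions)
   selects K unique measurement pairs, each node re-planning under its
   branch posterior.

An in-silico evaluator then plays the design against a noisy synthetic
plant, re-screens the acceptable set with the pooled data by direct ODE
simulation, and reports the per-target reduction of the uncertainty region
(envelope area of the extreme trajectories) plus TDU reduction and whether
the final band encloses the true dynamics. See `docs/methods.md` for the
full model and all numerical choices.

## Worked example

The bundled study designs a stimulus for the 3-state Hes1 oscillator
(mRNA `m`, cytosolic protein `P1`, nuclear protein `P2`; unknown repression
threshold, Hill coefficient, and translation rate, each uncertain over
0.1–10× nominal). The stimulus α scales the protein transport rate and may
switch at {0, 2, 5, 8, 10, 50, 100, 150, 200} min within [0.01, 2] at
resolution 0.05; `m` and `P1+P2` are measurable every 10 min over
[0, 300] min; K = 8 measurements are requested; six initial data points
(both outputs at t = 10, 20, 60 min, 10 % noise) seed the screen.

```python
from mbdoe import RunConfig, run_design, evaluate_design_in_silico

config = RunConfig(seed=1)                 # bundled Hes1 study conditions
report = run_design(config)
print("designed input levels:", report.schedule.levels.ravel().tolist())
print("greedy TDU trace:", [round(v, 3) for v in report.trace["min_TDU"]])
print("measurement plan:", [(p.species, p.time) for p in report.measurements])

result = evaluate_design_in_silico(report)
print("envelope reductions (%):",
      {k: round(v, 1) for k, v in result.reductions_area.items()})
print("TDU reduction (%):", round(result.tdu_reduction, 1))
print("plant enclosed:", result.containment)
```

prints (about a minute on one core):

```
designed input levels: [1.0, 0.76, 0.76, 0.76, 0.76, 0.76, 0.76, 0.76, 0.76]
greedy TDU trace: [7.67, 1.861]
measurement plan: [('m', 110.0), ('m', 60.0), ('P1+P2', 50.0), ('m', 150.0),
                   ('m', 120.0), ('m', 270.0), ('m', 40.0), ('m', 50.0),
                   ('m', 10.0)]
envelope reductions (%): {'m': 67.6, 'P1': 24.1, 'P2': 24.4}
TDU reduction (%): 56.8
plant enclosed: {'m': True, 'P1': True, 'P2': True}
```

Reading: the greedy search lowered the single-measurement TDU from 7.67 to
1.86 by dropping the transport stimulus to α = 0.76 from t = 2 min on; the
scenario tree then placed nine unique measurements, concentrated on the
mRNA around its most parameter-sensitive window. Executing that experiment
on the synthetic plant and re-screening shrinks the mRNA uncertainty band
by 68 % (24 % for the proteins on this seed), the final band still
encloses the true trajectories, and the ensemble TDU falls by 57 %.
Reductions are stochastic (plant noise, LHS seeds, clustering) and
conditional on the initial condition and T_A — across seeds 1–5 the mean
per-target reductions are roughly 68/46/44 % for m/P1/P2; see
`docs/methods.md`.

A command-line interface wraps the same pipeline:

```bash
mbdoe design   --config examples/hes1.yaml --seed 1 --outdir out/
mbdoe evaluate --config examples/hes1.yaml --seed 1 --outdir out/
mbdoe compare  --config examples/hes1.yaml --seed 1 --outdir out/
mbdoe simulate --config examples/hes1.yaml --seed 1 --out-csv data.csv
```

`design` writes the report JSON, the greedy trace and measurement plan as
CSV, the schedule and scenario tree as JSON; `evaluate` adds the reduction
summary and before/after envelope figures; `compare` evaluates the joint
design against a measurement-only design in a 2×2 table.

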