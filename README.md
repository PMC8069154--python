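# actinf

Discrete-state active inference with Fisher-information path-length accounting.

## The problem

Active inference casts perception as minimisation of variational free energy:
an agent holding a categorical belief `s` over hidden states descends

    F(s) = E_s[ln s − ln P(o, s)] = D_KL[s ‖ P(s|o)] − ln P(o)

after each observation `o` of a POMDP generative model (likelihood `A`,
transitions `B`, log-preferences `C`, prior `D`).  The neuronal update

    s ← σ(ln s − ε ∇F)        (softmax / voltage-to-firing-rate dynamics)

is, to first order in ε, the natural gradient update

    s ← (s − ε g⁻¹(s) ∇F)~    with g⁻¹(s) = diag(s) on the simplex,

i.e. steepest descent in information space.  Because belief updating has a
metabolic price proportional to the distance travelled in information space,
the interesting quantity is the **Fisher information length** of a belief
trajectory — the accumulated Fisher–Rao distance
`d(a, b) = 2‖√a − √b‖` between consecutive iterates.  This package lets you
run both update schemes on simulated decision tasks and compare the
information lengths they accrue, quantifying how close biologically plausible
softmax dynamics come to steepest descent.

It is aimed at computational neuroscientists and researchers in
active inference / information geometry who want a small, fully seeded,
pure-Python laboratory for these questions.

## What's inside

- `actinf.geometry` — the simplex as a statistical manifold: Fisher metric,
  chord/arc information distances, path lengths, geodesics (great-circle
  arcs under the square-root sphere embedding).
- `actinf.free_energy` — single-step variational free energy, its gradient
  (the prediction error), the exact-posterior oracle, convexity diagnostics.
- `actinf.inference` — the two belief-update schemes, iterate traces,
  simulated local field potentials (`v = ln s`, LFP = rate of change of `v`).
- `actinf.models` — POMDP containers, validation, JSON/YAML serialisation,
  Dirichlet learning of `A` and `B`.
- `actinf.planning` — expected free energy (risk + ambiguity), deterministic
  argmin-G decisions, the per-trial agent loop.
- `actinf.tasks` — builders for the T-Maze paradigm (8 joint states /
  7-dimensional simplex) and an abstract-rule surrogate (144 states, 16
  control states, 48 outcomes / 143-dimensional simplex).
- `actinf.experiments` — seed-matched cohort simulation, scheme comparison,
  CSV/JSON/plot reports, plus the `actinf` CLI.

## Worked example

Infer a hidden state from one observation (prior `(0.5, 0.3, 0.2)`,
likelihood evidence `(0.7, 0.2, 0.1)`), starting from an agnostic belief:

```python
import numpy as np
import actinf as ai
from actinf.free_energy import FreeEnergyContext, exact_posterior

ctx = FreeEnergyContext.from_distributions([0.7, 0.2, 0.1], [0.5, 0.3, 0.2])
trace = ai.run_inference(np.full(3, 1/3), ctx, scheme="active_inference", eps=0.25)

print(np.round(exact_posterior(ctx), 4))      # [0.814  0.1395 0.0465]
print(np.round(trace.beliefs[-1], 4))         # [0.8139 0.1395 0.0465]
print(trace.iterations, trace.converged)      # 35 True
print(round(trace.info_path.total_length, 4)) # 1.0712
print(round(ai.geodesic_distance(trace.beliefs[0], trace.beliefs[-1]), 4))  # 1.0668
print(np.round([trace.free_energies[0], trace.free_energies[-1]], 4))
                                              # [1.4931 0.844 ]
```

The softmax dynamics land on the exact Bayes posterior; the free energy
falls monotonically to `−ln P(o) = 0.8440` nats; and the path travelled in
information space (1.0712) is within half a percent of the geodesic
(1.0668) — descent here is nearly as short as geometrically possible.

Cohort-level comparison from the shell (writes CSVs, a JSON summary and
optional figures):

```sh
actinf simulate --task tmaze --scheme both --agents 128 --trials 24 \
    --epsilon 0.25 --seed 0 --out results/tmaze --plots
```

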