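# Methods

## Model

Perception is modelled as approximate Bayesian inference on a discrete-state
POMDP.  The generative model is the joint distribution over hidden states
and outcomes defined by a likelihood matrix `A` (`A[o,s] = P(o|s)`, columns
sum to one), one transition matrix per action (`B[u][s',s] = P(s'|s,u)`),
log-preferences over outcomes `C` (unnormalised, nats), a prior over the
initial state `D`, and a set of fixed-horizon policies.  Beliefs are a
single categorical distribution over the *joint* hidden state — one flat
simplex, not a product of per-factor simplices.  This keeps the geometry
exact (one Fisher metric, one free energy) at the price of muting per-factor
structure; see "Limitations".

For one observation the free energy of a belief `s` is

    F(s) = Σ_i s_i (ln s_i − ln prior_i − ln evidence_i),

with `evidence = A[o, :]` and `prior` the forward prediction
`B[u] @ s_prev` (or `D` at the first step).  `F = KL(s ‖ posterior) − ln
P(o)`: it is bounded below by the negative log evidence, tight exactly at
the Bayes posterior `softmax(ln prior + ln evidence)`, and convex (Hessian
`diag(1/s)`, positive definite on the simplex tangent space).  The gradient
`ln s − ln prior − ln evidence` is the prediction error; the additive
constant from differentiating `s ln s` is dropped because both update rules
annihilate constant shifts.

## The two update schemes

Per inference iterate, with step size ε:

- **Active inference (softmax / neuronal)**: `s ← softmax(ln s − ε ∇F)`.
  In log space this is a convex combination `(1−ε) ln s + ε (ln prior + ln
  evidence)`, i.e. motion along the exponential-family geodesic toward the
  posterior's natural parameters — hence unconditionally simplex-preserving
  and monotone in F for ε ≤ 1.
- **Natural gradient**: `s ← (s − ε s ⊙ ∇F)~`, where `~` is normalisation
  by the component sum and `s ⊙ ∇F` is the inverse Fisher metric `diag(s)`
  acting on the gradient.  Components driven negative by a large step are
  clipped to zero before renormalising; if every component would be
  non-positive the step is halved (with a warning) until usable.

A first-order Taylor expansion of the exponential shows the two updates
agree to O(ε²); the test suite verifies the Richardson ratio ≈ 4 when ε is
halved on unit-scale problems.

A caveat worth knowing: the *clipped* natural-gradient step is not a
monotone descent in every regime.  On adversarial contexts (a sharp prior
pointing one way and floored evidence pointing the other) a clip can
overshoot the optimum and transiently raise F.  Within the tasks shipped
here, and on generic unit-scale problems, both schemes descend monotonically
to numerical precision — the suite asserts this — but the clipped update
carries no global guarantee, whereas the softmax update does.

## Information geometry

On the simplex the Fisher metric is the Hessian of the KL divergence; under
the component-wise square-root embedding the simplex maps onto the positive
orthant of the unit sphere (isometrically up to a factor 2), so geodesics
are great circles and the geodesic distance is `2·arccos(√a · √b)`.  Two
finite-separation distances are exposed:

- `chord` (default): `2‖√a − √b‖` — the straight-line distance in the
  embedding; agrees with the metric to second order and is what trajectory
  lengths accumulate by default;
- `arc`: the exact geodesic length.

The chord never exceeds the arc and their ratio tends to one for small
separations, so for per-iterate accumulation the choice is nearly
immaterial; both are available because path-length conventions differ across
the literature.  Information length of an inference run is the sum of
distances between consecutive iterates, over every iterate of every
observation of a trial.

## Numerical choices

- Probabilities are floored at `1e-16` and renormalised before logarithms,
  square roots, and metric operations (quantities diverge at the boundary).
- ε defaults to 0.25 (the conventional discretisation step for these
  schemes); convergence is declared when the tangent-projected gradient norm
  drops below `1e-4`, with at most 64 iterates per observation.
  Non-convergence is recorded on the trace, not raised.
- Each observation's inference starts at the predictive prior by default
  (`init="prior"`): the prior *is* the agnostic belief before evidence.
  `init="uniform"` starts every run at the simplex barycentre instead;
  this mid-simplex convention is what makes cross-trial learning effects
  visible in the length traces (below).
- Ties in policy selection break toward the lowest policy index; decisions
  are deterministic argmin-G (no sampling from the policy posterior).
- Every simulation entry point requires an explicitly seeded
  `numpy.random.Generator`; cohorts spawn per-agent seeds from a master
  seed via `SeedSequence`, so identical master seeds give bit-identical
  results.

## Planning and learning

Policies are scored by expected free energy in the risk + ambiguity form:
risk is the KL divergence from predicted outcomes to `softmax(C)`, ambiguity
the expected outcome entropy of predicted states, summed along the policy
with states rolled forward through `B`.  Because risk contains the negative
entropy of predicted outcomes, reading an informative cue is preferred over
idling even under flat preferences — epistemic behaviour needs no extra
term.  The agent re-plans after every observation using the remaining policy
suffixes.

Learning accumulates Dirichlet counts at trial end: observing `o` with
posterior `s` adds `s` to row `o` of the likelihood counts; each transition
adds the outer product of consecutive posteriors to that action's transition
counts.  Expected log-parameters (`digamma(n) − digamma(column sum)`) feed
inference; column-normalised means feed prediction and planning.  Known
mappings are encoded as large counts (1e4) with a small floor (1e-3).

## Tasks (the synthetic-data layer)

**T-Maze.**  Location {centre, left-arm, right-arm, cue} × context
{reward-left, reward-right}: 8 joint states (7-dimensional simplex), 4
actions (arms absorbing), 7 outcomes, horizon 2 (three observations per
trial).  Preferences: +3 nats for the baited arm, −6 for the unbaited one,
neutral otherwise — strong enough that exploitation dominates once the
context is known, weak enough that the cue is visited under uncertainty
(the suite asserts both behaviours).  Contexts are random for trials 0–2
and fixed from trial 3.  The environment carries a two-component Dirichlet
count over the context (prior count 4.5 per side, +1 per trial from the
final posterior's context marginal) which rebuilds `D` each trial: agents
gradually come to expect the reward location, and around the ninth trial the
expected-utility balance `R·p − P·(1−p)` crosses zero for the modal
schedule, at which point they stop checking the cue and head straight for
the reward.

**Abstract-rule surrogate.**  Factors rule(3) × stimulus(3) × stage(4) ×
response(4): 144 joint states (143-dimensional simplex), 16 control states
(response choice × stimulus probe), 48 outcomes (display × feedback ×
position), horizon 2 with feedback at the final stage.  The environment's
matrices are deterministic; the agent's feedback likelihood starts flat
(half a count on correct/incorrect per state), so the
(stimulus, response) → feedback contingency must be learned across trials.
This builder is a *dimensional surrogate*: it reproduces the published
state/control/outcome counts and the learning pressure of the original
rule-learning paradigm, not its stimulus semantics.  With per-timestep
filtered-posterior count updates, credit spreads evenly over the rule
factor (stimulus and response are observed directly), so the rule dimension
stays uniform while the contingency is learned at the (stimulus, response)
level — the belief simplex has the full 143 dimensions, but the rule factor
is a placeholder, not an inferred variable.

## Cohort design and problem sizes

Scheme comparisons are paired: both cohorts run from the same master seed,
so schedules and task draws match agent-for-agent, and the per-agent,
per-trial difference in information length isolates the update rule.  The
headline statistic is `mean(|L_AI − L_NG|) / mean(pooled lengths)`.

The package's reference scale is 128 agents × 24 trials per scheme per
task; the test suite and the acceptance script use 32 agents × 24 trials,
which keeps the full pipeline within a few minutes on one CPU while leaving
the statistic stable to well below the thresholds being tested.

## What the simulations show — and what they do not

- Under default settings the two schemes' information lengths agree to a
  small fraction of a percent on both tasks, far inside the 4% bound the
  suite asserts; with predictive-prior starts most updates are small, which
  is precisely the regime where the O(ε²) agreement is tight.
- Under mid-simplex starts (`init="uniform"`) every update travels a long
  way and the schemes become distinguishable: the clipped natural-gradient
  step reaches a much sharper posterior in one or two iterates (its path
  length approaches the endpoint chord), while the softmax update follows
  the curved exponential-family path, which is somewhat longer — more so in
  higher-dimensional state spaces.  The sign of the mean difference can go
  either way across tasks.
- Cross-trial learning lengthens mid-simplex trajectories: in the T-Maze,
  per-trial mean length rises once the reward location is fixed and the
  context prior sharpens, exceeding its pre-learning baseline by the ninth
  trial (asserted in the suite).  In this flat joint-state representation
  the effect is gradual rather than abrupt: the location dimension, which is
  re-inferred from the barycentre at every step, dominates each run's path
  length and dilutes the context-belief travel that a per-factor account
  would attribute cleanly to learning.

These are simulations of small synthetic tasks with deterministic
likelihoods and an exhaustively enumerable policy set.  Passing tests show
the schemes' mathematical relationship and the geometry of their belief
paths under those conditions; they say nothing about noisy likelihoods,
deep policy trees, factorised (mean-field) message passing, continuous
state spaces, or empirical electrophysiology, none of which are modelled.

## Known limitations

- Single flat joint-state posterior; no mean-field factorisation over
  hidden factors and no smoothing (filtering only), so likelihood learning
  cannot exploit retrospective inference within a trial.
- The per-step free energy uses the forward prediction as its prior; no
  policy-conditioned posterior over full sequences.
- Preferences and Dirichlet hyperparameters are task-builder defaults
  chosen once for qualitative behaviour (documented above), not fitted
  quantities.
- The clipped natural-gradient update lacks a global descent guarantee
  (see above); step-halving guards against leaving the simplex, not against
  overshoot.
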