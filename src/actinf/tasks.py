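"""Task builders: the T-Maze paradigm and an abstract-rule surrogate.

Both builders return a :class:`TaskEnvironment` bundling the agent's
generative model (a flat joint-state POMDP), its initial Dirichlet counts,
and the environment's true matrices used to generate observations.  Builders
are pure functions of their parameters; all run-time randomness (context
schedules, rule/stimulus draws, sampling) flows through the explicitly
seeded generator handed to the environment methods.

T-Maze
------
A rat starts at the centre of a T-maze.  One upper arm is baited; a cue at
the bottom arm reveals which.  Hidden states are the joint of location
{centre, left-arm, right-arm, cue} and context {reward-left, reward-right}
-- eight states, a seven-dimensional belief simplex.  Four actions move the
rat (arms are absorbing).  Seven outcomes: centre, each arm with or without
reward, and the two cue readings.  Preferences favour the reward and
penalise the unbaited arm.  For the first three trials the context is drawn
uniformly; from the fourth trial it is fixed, and the environment carries a
small Dirichlet count over the context which is updated at trial end --
this is how agents come to expect the reward location and eventually skip
the cue.

Rule surrogate
--------------
A dimensionally faithful stand-in for an abstract rule-learning task: 16
control states, 144 hidden states (factors: rule x stimulus x stage x
response, default 3 x 3 x 4 x 4 -- a 143-dimensional simplex) and 48
outcomes (display x feedback x position).  A hidden rule fixes the correct
response to each stimulus; feedback arrives at the final stage.  The agent's
likelihood counts for the feedback mapping start flat, so the contingency
must be learned across trials.  This builder reproduces the printed
dimensions and the learning pressure of the original paradigm, not its
stimulus semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import DirichletCounts, POMDPModel

__all__ = [
    "TaskEnvironment",
    "TMazeEnvironment",
    "RuleEnvironment",
    "TMazeSchedule",
    "tmaze_schedule",
    "build_tmaze",
    "build_rule_surrogate",
]


@dataclass
class TaskEnvironment:
    """A generative model plus the true process that generates observations."""

    model: POMDPModel
    counts: DirichletCounts
    true_A: np.ndarray
    true_B: list[np.ndarray]
    horizon: int
    name: str = "task"

    def _require_rng(self, rng) -> None:
        if not isinstance(rng, np.random.Generator):
            raise TypeError("rng must be an explicitly seeded numpy.random.Generator")

    def begin_trial(self, rng: np.random.Generator) -> int:
        raise NotImplementedError

    def transition(self, state: int, action: int, rng: np.random.Generator) -> int:
        self._require_rng(rng)
        return int(rng.choice(self.true_B[action].shape[0], p=self.true_B[action][:, state]))

    def emit(self, state: int, rng: np.random.Generator) -> int:
        self._require_rng(rng)
        return int(rng.choice(self.true_A.shape[0], p=self.true_A[:, state]))

    def learn_trial(self, record) -> None:
        """Hook for cross-trial environment-side learning (priors); default no-op."""


# ---------------------------------------------------------------------------
# T-Maze
# ---------------------------------------------------------------------------

_LOCS = ["centre", "left-arm", "right-arm", "cue"]
_CTXS = ["reward-left", "reward-right"]
_TMAZE_OUTCOMES = [
    "centre",
    "left-reward",
    "left-no-reward",
    "right-reward",
    "right-no-reward",
    "cue-left",
    "cue-right",
]


def _tmaze_state(loc: int, ctx: int) -> int:
    return 2 * loc + ctx


class TMazeSchedule:
    """Per-trial context rule: three uniform draws, then one fixed draw.

    Contexts for trials 0-2 are drawn uniformly; the context for every trial
    from index 3 onward is a single draw made at trial 3.  All draws are
    made at construction so queries are order-independent and two schedules
    built from identically seeded generators coincide exactly.
    """

    def __init__(self, rng: np.random.Generator):
        if not isinstance(rng, np.random.Generator):
            raise TypeError("rng must be an explicitly seeded numpy.random.Generator")
        self._random = [int(rng.integers(2)) for _ in range(3)]
        self._fixed = int(rng.integers(2))

    def __call__(self, trial_index: int) -> int:
        if trial_index < 0:
            raise ValueError("trial_index must be >= 0")
        return self._random[trial_index] if trial_index < 3 else self._fixed


def tmaze_schedule(trial_index: int, rng: np.random.Generator) -> int:
    """Functional form of :class:`TMazeSchedule` (consumes four draws)."""
    return TMazeSchedule(rng)(trial_index)


@dataclass
class TMazeEnvironment(TaskEnvironment):
    """T-Maze with a learnable context prior.

    ``context_counts`` is a two-component Dirichlet count over the reward
    location; :meth:`learn_trial` adds the final posterior's context
    marginal and rebuilds the model's initial-state prior ``D`` so that, over
    consistent trials, agents come to expect the reward location.
    """

    context_counts: np.ndarray = field(default_factory=lambda: np.full(2, 4.5))
    context_rate: float = 1.0
    _schedule: TMazeSchedule | None = None
    _trial_index: int = 0

    def begin_trial(self, rng: np.random.Generator) -> int:
        self._require_rng(rng)
        if self._schedule is None:
            self._schedule = TMazeSchedule(rng)
        ctx = self._schedule(self._trial_index)
        self._trial_index += 1
        return _tmaze_state(0, ctx)

    def context_marginal(self, s: np.ndarray) -> np.ndarray:
        return np.array([s[0::2].sum(), s[1::2].sum()])

    def learn_trial(self, record) -> None:
        self.context_counts = self.context_counts + self.context_rate * self.context_marginal(
            record.final_belief
        )
        d = np.zeros(self.model.n_states)
        d[0:2] = self.context_counts / self.context_counts.sum()
        self.model.D = d


def build_tmaze(
    reward_value: float = 3.0,
    punish_value: float = -6.0,
    *,
    context_prior_count: float = 4.5,
    context_rate: float = 1.0,
    known_count: float = 1e4,
    count_floor: float = 1e-3,
) -> TMazeEnvironment:
    """Build the T-Maze task (Figure-3-style structure).

    ``reward_value`` (nats, > 0) and ``punish_value`` (nats, <= 0) are the
    log-preferences for the baited and unbaited arm outcomes; all other
    outcomes are neutral.  ``context_prior_count`` sets how many consistent
    trials are needed before the agent trusts its context prior enough to
    skip the cue.  The builder is deterministic; randomness enters only at
    run time through the trial schedule.
    """
    if punish_value > 0:
        raise ValueError("punish_value must be <= 0")
    n_states, n_outcomes, n_actions = 8, 7, 4

    A = np.zeros((n_outcomes, n_states))
    for loc in range(4):
        for ctx in range(2):
            j = _tmaze_state(loc, ctx)
            if loc == 0:
                A[0, j] = 1.0
            elif loc == 1:
                A[1 if ctx == 0 else 2, j] = 1.0
            elif loc == 2:
                A[3 if ctx == 1 else 4, j] = 1.0
            else:  # cue location reveals the context
                A[5 if ctx == 0 else 6, j] = 1.0

    B: list[np.ndarray] = []
    for action in range(n_actions):
        b = np.zeros((n_states, n_states))
        for loc in range(4):
            target = loc if loc in (1, 2) else action  # arms are absorbing
            for ctx in range(2):
                b[_tmaze_state(target, ctx), _tmaze_state(loc, ctx)] = 1.0
        B.append(b)

    C = np.zeros(n_outcomes)
    C[[1, 3]] = reward_value
    C[[2, 4]] = punish_value

    D = np.zeros(n_states)
    D[0:2] = 0.5  # centre known, context uniform

    policies = [(a1, a2) for a1 in range(n_actions) for a2 in range(n_actions)]
    model = POMDPModel(
        A=A,
        B=B,
        C=C,
        D=D,
        policies=policies,
        labels={
            "states": [f"{l}/{c}" for l in _LOCS for c in _CTXS],
            "outcomes": list(_TMAZE_OUTCOMES),
            "actions": [f"go-{l}" for l in _LOCS],
        },
    )
    counts = DirichletCounts(
        a=known_count * A + count_floor,
        b=[known_count * b + count_floor for b in B],
        prior_count=count_floor,
    )
    return TMazeEnvironment(
        model=model,
        counts=counts,
        true_A=A.copy(),
        true_B=[b.copy() for b in B],
        horizon=2,
        name="tmaze",
        context_counts=np.full(2, float(context_prior_count)),
        context_rate=context_rate,
    )


# ---------------------------------------------------------------------------
# Abstract-rule surrogate
# ---------------------------------------------------------------------------


@dataclass
class RuleEnvironment(TaskEnvironment):
    """Rule-surrogate environment: one hidden rule per agent, new stimulus per trial."""

    factor_sizes: tuple[int, int, int, int] = (3, 3, 4, 4)
    _rule: int | None = None

    def begin_trial(self, rng: np.random.Generator) -> int:
        self._require_rng(rng)
        n_rules, n_stim, _, _ = self.factor_sizes
        if self._rule is None:
            self._rule = int(rng.integers(n_rules))
        stim = int(rng.integers(n_stim))
        return int(np.ravel_multi_index((self._rule, stim, 0, 0), self.factor_sizes))


def build_rule_surrogate(
    factor_sizes: tuple[int, int, int, int] = (3, 3, 4, 4),
    n_outcomes: int = 48,
    *,
    reward_value: float = 3.0,
    punish_value: float = -6.0,
    feedback_prior_count: float = 1.0,
    known_count: float = 1e4,
    count_floor: float = 1e-3,
    horizon: int = 2,
) -> RuleEnvironment:
    """Build the abstract-rule surrogate task.

    Hidden factors: rule (static, unknown), stimulus (per-trial, displayed),
    stage (advances each step, absorbing at the end) and response (set by
    action).  16 control states combine a response choice with a probe that
    rotates the stimulus.  48 outcomes combine the display (stimulus or
    blank), feedback (none / correct / incorrect -- correct iff the response
    matches ``(rule + stimulus) mod n_responses`` at the feedback stage) and
    a stage marker.  The environment's matrices are deterministic; the
    agent's feedback likelihood starts flat, so the rule's contingency must
    be learned.  A dimensional surrogate: it reproduces the published state,
    control and outcome counts, not the original study's contingencies.
    """
    n_rules, n_stim, n_stages, n_resp = factor_sizes
    n_states = int(np.prod(factor_sizes))
    n_probe = 4
    n_actions = n_resp * n_probe
    outcome_dims = (n_stim + 1, 3, n_stages)  # display, feedback, position
    if int(np.prod(outcome_dims)) != n_outcomes:
        raise ValueError(
            f"inconsistent sizes: factors {factor_sizes} imply "
            f"{int(np.prod(outcome_dims))} outcomes, got n_outcomes={n_outcomes}"
        )
    feedback_stage = min(horizon, n_stages - 1)

    def outcome_of(rule: int, stim: int, stage: int, resp: int) -> int:
        display = stim if stage < feedback_stage else n_stim
        if stage < feedback_stage:
            fb = 0
        else:
            fb = 1 if resp == (rule + stim) % n_resp else 2
        return int(np.ravel_multi_index((display, fb, stage), outcome_dims))

    A = np.zeros((n_outcomes, n_states))
    for idx in range(n_states):
        r, s, t, p = np.unravel_index(idx, factor_sizes)
        A[outcome_of(r, s, t, p), idx] = 1.0

    eye_rule = np.eye(n_rules)
    adv = np.zeros((n_stages, n_stages))
    for t in range(n_stages):
        adv[min(t + 1, n_stages - 1), t] = 1.0
    B: list[np.ndarray] = []
    for action in range(n_actions):
        resp, probe = action % n_resp, action // n_resp
        shift = np.zeros((n_stim, n_stim))
        for s in range(n_stim):
            shift[(s + probe) % n_stim, s] = 1.0
        set_resp = np.zeros((n_resp, n_resp))
        set_resp[resp, :] = 1.0
        B.append(np.kron(eye_rule, np.kron(shift, np.kron(adv, set_resp))))

    C = np.zeros(n_outcomes)
    for d in range(n_stim + 1):
        for q in range(n_stages):
            C[np.ravel_multi_index((d, 1, q), outcome_dims)] = reward_value
            C[np.ravel_multi_index((d, 2, q), outcome_dims)] = punish_value

    D = np.zeros(n_states)
    for r in range(n_rules):
        for s in range(n_stim):
            D[np.ravel_multi_index((r, s, 0, 0), factor_sizes)] = 1.0 / (n_rules * n_stim)

    policies = [
        tuple(p)
        for p in np.stack(
            np.meshgrid(*[np.arange(n_actions)] * horizon, indexing="ij"), axis=-1
        ).reshape(-1, horizon)
    ]

    model = POMDPModel(
        A=A,
        B=B,
        C=C,
        D=D,
        policies=policies,
        labels={
            "factors": ["rule", "stimulus", "stage", "response"],
            "outcome_dims": ["display", "feedback", "position"],
            "actions": [f"resp{a % n_resp}-probe{a // n_resp}" for a in range(n_actions)],
        },
    )

    # Agent's likelihood counts: display/position structure known, feedback flat.
    a_counts = np.full_like(A, count_floor)
    for idx in range(n_states):
        r, s, t, p = np.unravel_index(idx, factor_sizes)
        if t < feedback_stage:
            a_counts[outcome_of(r, s, t, p), idx] += known_count
        else:
            display = n_stim
            for fb in (1, 2):
                o = int(np.ravel_multi_index((display, fb, t), outcome_dims))
                a_counts[o, idx] += feedback_prior_count / 2.0
    counts = DirichletCounts(
        a=a_counts,
        b=[known_count * b + count_floor for b in B],
        prior_count=count_floor,
    )
    return RuleEnvironment(
        model=model,
        counts=counts,
        true_A=A.copy(),
        true_B=[b.copy() for b in B],
        horizon=horizon,
        name="rule",
        factor_sizes=factor_sizes,
    )
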