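"""Planning as inference, decision-making, and the per-trial agent loop.

Policies (fixed-horizon action sequences) are scored by their expected free
energy ``G``, here in the standard risk + ambiguity decomposition: for each
remaining step of the policy the predicted state distribution is rolled
forward through ``B``, and

    G += KL( predicted outcomes || softmax(C) )        (risk)
       + E_predicted-states[ H(A[:, s]) ]              (ambiguity)

Risk pulls predicted outcomes toward the log-preferences ``C``; ambiguity
penalises states whose outcome mapping is uncertain.  Because the risk term
contains the negative entropy of the predicted outcomes, policies whose
outcomes are informative about hidden states (e.g. reading a cue) are
favoured when preferences are flat -- epistemic, ambiguity-resolving
behaviour falls out of the same objective as goal-seeking.

Decision-making is deterministic: the first action of a policy attaining the
minimum ``G`` (ties broken by lowest policy index).  The softmax policy
posterior ``softmax(-G)`` is recorded for completeness.

The trial loop repeats observation -> perceptual inference -> planning ->
action, re-planning after every observation with the policy suffixes that
remain, and applies Dirichlet learning of A and B at trial end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import digamma

from .free_energy import FreeEnergyContext
from .geometry import FLOOR, as_belief, floor_beliefs, softmax
from .inference import InferenceTrace, run_inference
from .models import DirichletCounts, POMDPModel, mean_params, update_counts

__all__ = [
    "PolicyEvaluation",
    "TrialRecord",
    "expected_free_energy",
    "evaluate_policies",
    "run_trial",
]


def _kl(q: np.ndarray, log_p: np.ndarray) -> float:
    ln_q = np.log(np.clip(q, FLOOR, None))
    return float(np.sum(np.where(q > 0, q * (ln_q - log_p), 0.0)))


def expected_free_energy(
    m: POMDPModel,
    s: np.ndarray,
    policy: Sequence[int],
    *,
    A: np.ndarray | None = None,
    B: list[np.ndarray] | None = None,
) -> float:
    """Expected free energy (nats) of ``policy`` from current belief ``s``.

    ``A``/``B`` default to the model's matrices; pass posterior-mean
    estimates from Dirichlet counts to plan under a learned model.
    """
    A = m.A if A is None else A
    B = m.B if B is None else B
    s = as_belief(s)
    log_pref, col_entropy = _efe_tables(m.C, A)
    return _efe(A, B, log_pref, col_entropy, s, tuple(policy))


def _efe_tables(C: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shared planning tables: log-preferences and per-state outcome entropy."""
    log_pref = np.log(np.clip(softmax(C), FLOOR, None))
    ln_a = np.log(np.clip(A, FLOOR, None))
    col_entropy = -np.einsum("os,os->s", A, np.where(A > 0, ln_a, 0.0))
    return log_pref, col_entropy


def _efe(
    A: np.ndarray,
    B: list[np.ndarray],
    log_pref: np.ndarray,
    col_entropy: np.ndarray,
    s: np.ndarray,
    policy: tuple[int, ...],
    _roll_cache: dict | None = None,
) -> float:
    g = 0.0
    x = s
    for t, a in enumerate(policy):
        key = policy[: t + 1]
        if _roll_cache is not None and key in _roll_cache:
            x, g = _roll_cache[key]
            continue
        x = B[a] @ x
        q_o = A @ x
        g = g + _kl(q_o, log_pref) + float(col_entropy @ x)
        if _roll_cache is not None:
            _roll_cache[key] = (x, g)
    return g


@dataclass(frozen=True)
class PolicyEvaluation:
    """Expected free energies over a policy set and the induced choice."""

    G: np.ndarray
    policy_posterior: np.ndarray
    chosen_action: int
    policies: tuple[tuple[int, ...], ...]


def evaluate_policies(
    m: POMDPModel,
    s: np.ndarray,
    policies: Sequence[Sequence[int]] | None = None,
    *,
    A: np.ndarray | None = None,
    B: list[np.ndarray] | None = None,
) -> PolicyEvaluation:
    """Score every policy; choose the first action of the best (lowest-G) one.

    Policies sharing a tail are evaluated once (G depends only on the action
    sequence and the current belief).
    """
    pols = [tuple(int(a) for a in p) for p in (m.policies if policies is None else policies)]
    if not pols:
        raise ValueError("empty policy set")
    A_ = m.A if A is None else A
    B_ = m.B if B is None else B
    s = as_belief(s)
    log_pref, col_entropy = _efe_tables(m.C, A_)
    roll_cache: dict = {}
    G = np.array([_efe(A_, B_, log_pref, col_entropy, s, p, roll_cache) for p in pols])
    best = int(np.argmin(G))  # ties -> lowest index
    return PolicyEvaluation(
        G=G,
        policy_posterior=softmax(-G),
        chosen_action=pols[best][0],
        policies=tuple(pols),
    )


@dataclass
class TrialRecord:
    """Everything one trial produced: observations, choices, traces, lengths."""

    observations: list[int]
    actions: list[int]
    policy_evaluations: list[PolicyEvaluation]
    traces: list[InferenceTrace]
    beliefs: list[np.ndarray] = field(default_factory=list)
    info_length: float = 0.0
    counts: DirichletCounts | None = None

    @property
    def final_belief(self) -> np.ndarray:
        return self.beliefs[-1]

    @property
    def step_info_lengths(self) -> list[float]:
        return [t.info_path.total_length for t in self.traces]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "observations": [int(o) for o in self.observations],
            "actions": [int(a) for a in self.actions],
            "G": [pe.G.tolist() for pe in self.policy_evaluations],
            "step_information_lengths": self.step_info_lengths,
            "information_length": self.info_length,
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def run_trial(
    env,
    counts: DirichletCounts,
    scheme: str = "active_inference",
    eps: float = 0.25,
    rng: np.random.Generator | None = None,
    *,
    init: str = "prior",
    max_iter: int = 64,
    tol: float = 1e-4,
    distance: str = "chord",
    learn: bool = True,
    learning_rate: float = 1.0,
) -> TrialRecord:
    """Run one trial of ``env`` with the given inference scheme.

    The loop samples an observation from the environment's true state,
    infers hidden states by free-energy descent (starting each run either at
    the uniform belief, ``init="uniform"``, or at the predictive prior,
    ``init="prior"``), evaluates the remaining policy suffixes, executes the
    lowest-G action, and -- after the final observation -- accumulates
    likelihood/transition Dirichlet counts from the recorded posteriors.

    ``rng`` must be an explicitly seeded :class:`numpy.random.Generator`;
    this is the reproducibility contract for every simulation entry point.
    """
    if not isinstance(rng, np.random.Generator):
        raise TypeError("rng must be an explicitly seeded numpy.random.Generator")
    if init not in {"uniform", "prior"}:
        raise ValueError("init must be 'uniform' or 'prior'")
    model: POMDPModel = env.model
    horizon = env.horizon
    eln_a = digamma(counts.a) - digamma(counts.a.sum(axis=0, keepdims=True))
    a_bar, b_bar = mean_params(counts)

    state = env.begin_trial(rng)
    prior = model.D.copy()
    observations: list[int] = []
    actions: list[int] = []
    evaluations: list[PolicyEvaluation] = []
    traces: list[InferenceTrace] = []
    beliefs: list[np.ndarray] = []

    for t in range(horizon + 1):
        o = env.emit(state, rng)
        observations.append(o)
        ctx = FreeEnergyContext(
            log_likelihood_evidence=eln_a[o, :],
            log_prior=np.log(floor_beliefs(prior)),
        )
        s0 = np.full(model.n_states, 1.0 / model.n_states) if init == "uniform" else prior
        trace = run_inference(
            s0, ctx, scheme=scheme, eps=eps, max_iter=max_iter, tol=tol, distance=distance
        )
        traces.append(trace)
        s = trace.beliefs[-1]
        beliefs.append(s)
        if t < horizon:
            suffixes = [p[t:] for p in model.policies]
            pe = evaluate_policies(model, s, suffixes, A=a_bar, B=b_bar)
            evaluations.append(pe)
            action = pe.chosen_action
            actions.append(action)
            state = env.transition(state, action, rng)
            prior = b_bar[action] @ s

    new_counts = counts
    if learn:
        for t, o in enumerate(observations):
            if t == 0:
                new_counts = update_counts(new_counts, o, beliefs[t], rate=learning_rate)
            else:
                new_counts = update_counts(
                    new_counts,
                    o,
                    beliefs[t],
                    s_prev=beliefs[t - 1],
                    action=actions[t - 1],
                    rate=learning_rate,
                )

    return TrialRecord(
        observations=observations,
        actions=actions,
        policy_evaluations=evaluations,
        traces=traces,
        beliefs=beliefs,
        info_length=float(sum(tr.info_path.total_length for tr in traces)),
        counts=new_counts,
    )
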