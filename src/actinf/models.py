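"""POMDP generative models and Dirichlet learning of their mappings.

The generative model is the standard discrete-state POMDP used throughout
active inference:

* ``A`` -- likelihood matrix, ``A[o, s] = P(o | s)`` (columns sum to one),
* ``B`` -- one transition matrix per action, ``B[a][s', s] = P(s' | s, a)``,
* ``C`` -- log-preferences over outcomes (unnormalised, in nats; preferences
  enter expected free energy only through log-ratios),
* ``D`` -- prior belief over the initial hidden state,
* ``policies`` -- the allowed action sequences, all of one fixed horizon.

``A`` and ``B`` can be learned from experience by accumulating Dirichlet
concentration counts: observing outcome ``o`` with posterior state belief
``s`` adds ``s`` to row ``o`` of the likelihood counts, and a transition
under action ``u`` adds the outer product of the consecutive posteriors to
that action's transition counts.  The expected log-parameters under the
Dirichlet posterior are ``digamma(count) - digamma(column sum)``, which is
what perceptual inference uses as its (log) likelihood and prior messages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.special import digamma

__all__ = [
    "POMDPModel",
    "DirichletCounts",
    "validate_model",
    "expected_log_params",
    "mean_params",
    "update_counts",
    "known_counts",
]

_COLSUM_TOL = 1e-10


@dataclass
class POMDPModel:
    """A discrete-state partially observed Markov decision process."""

    A: np.ndarray
    B: list[np.ndarray]
    C: np.ndarray
    D: np.ndarray
    policies: list[tuple[int, ...]]
    labels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = [np.asarray(b, dtype=float) for b in self.B]
        self.C = np.asarray(self.C, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.policies = [tuple(int(a) for a in p) for p in self.policies]

    @property
    def n_states(self) -> int:
        return self.A.shape[1]

    @property
    def n_outcomes(self) -> int:
        return self.A.shape[0]

    @property
    def n_actions(self) -> int:
        return len(self.B)

    @property
    def horizon(self) -> int:
        return len(self.policies[0]) if self.policies else 0

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        def arr(x: np.ndarray) -> dict:
            return {"shape": list(x.shape), "data": np.asarray(x, float).ravel().tolist()}

        return {
            "A": arr(self.A),
            "B": [arr(b) for b in self.B],
            "C": arr(self.C),
            "D": arr(self.D),
            "policies": [list(p) for p in self.policies],
            "labels": {k: list(v) for k, v in self.labels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "POMDPModel":
        def arr(spec: dict) -> np.ndarray:
            return np.array(spec["data"], dtype=float).reshape(spec["shape"])

        return cls(
            A=arr(d["A"]),
            B=[arr(b) for b in d["B"]],
            C=arr(d["C"]),
            D=arr(d["D"]),
            policies=[tuple(p) for p in d["policies"]],
            labels={k: list(v) for k, v in d.get("labels", {}).items()},
        )

    def save(self, path: str | Path) -> None:
        """Write the model as JSON or YAML (chosen by file extension)."""
        path = Path(path)
        doc = self.to_dict()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(doc, sort_keys=True))
        else:
            path.write_text(json.dumps(doc, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "POMDPModel":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.from_dict(doc)


def _check_stochastic(name: str, m: np.ndarray, violations: list[str]) -> None:
    if np.any(m < 0):
        bad = np.argwhere(m < 0)
        violations.append(f"{name} has negative entries (first at {tuple(bad[0])})")
    colsums = m.sum(axis=0)
    for j, cs in enumerate(colsums):
        if abs(cs - 1.0) > _COLSUM_TOL:
            violations.append(f"{name} column {j} sums to {cs:.6g} (expected 1)")


def validate_model(m: POMDPModel) -> list[str]:
    """Return a list of invariant violations; an empty list means the model is valid."""
    v: list[str] = []
    if m.A.ndim != 2:
        v.append(f"A must be 2-D, got shape {m.A.shape}")
        return v
    _check_stochastic("A", m.A, v)
    for i, b in enumerate(m.B):
        if b.shape != (m.n_states, m.n_states):
            v.append(f"B[{i}] has shape {b.shape}, expected ({m.n_states}, {m.n_states})")
        else:
            _check_stochastic(f"B[{i}]", b, v)
    if m.C.shape != (m.n_outcomes,):
        v.append(f"C has shape {m.C.shape}, expected ({m.n_outcomes},)")
    if m.D.shape != (m.n_states,):
        v.append(f"D has shape {m.D.shape}, expected ({m.n_states},)")
    else:
        if np.any(m.D < 0) or abs(float(m.D.sum()) - 1.0) > _COLSUM_TOL:
            v.append("D is not a valid belief vector")
    if not m.policies:
        v.append("policy set is empty")
    else:
        T = len(m.policies[0])
        if T < 1:
            v.append("policies must have length >= 1")
        for i, p in enumerate(m.policies):
            if len(p) != T:
                v.append(f"policy {i} has length {len(p)}, expected {T}")
            if any(a < 0 or a >= m.n_actions for a in p):
                v.append(f"policy {i} uses an action index outside 0..{m.n_actions - 1}")
    return v


@dataclass
class DirichletCounts:
    """Dirichlet concentration counts over the likelihood and transition mappings.

    ``a`` is shaped like ``A``; ``b`` holds one array shaped like each
    ``B[u]``.  All counts stay at or above ``prior_count``, a strictly
    positive floor, so expected log-parameters are finite everywhere.
    "Known" mappings are represented by large counts (see ``known_counts``).
    """

    a: np.ndarray
    b: list[np.ndarray]
    prior_count: float = 1e-3

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = [np.asarray(x, dtype=float) for x in self.b]
        if self.prior_count <= 0:
            raise ValueError("prior_count floor must be > 0")
        if np.any(self.a < self.prior_count - 1e-12) or any(
            np.any(x < self.prior_count - 1e-12) for x in self.b
        ):
            raise ValueError("all counts must be >= the prior_count floor")

    def copy(self) -> "DirichletCounts":
        return DirichletCounts(
            a=self.a.copy(), b=[x.copy() for x in self.b], prior_count=self.prior_count
        )


def known_counts(
    m: POMDPModel, scale: float = 1e4, floor: float = 1e-3
) -> DirichletCounts:
    """Counts representing a fully known model: ``scale * matrix + floor``."""
    return DirichletCounts(
        a=scale * m.A + floor,
        b=[scale * b + floor for b in m.B],
        prior_count=floor,
    )


def expected_log_params(d: DirichletCounts) -> tuple[np.ndarray, list[np.ndarray]]:
    """Expected log-parameters under the Dirichlet: digamma(n) - digamma(colsum)."""
    eln_a = digamma(d.a) - digamma(d.a.sum(axis=0, keepdims=True))
    eln_b = [digamma(x) - digamma(x.sum(axis=0, keepdims=True)) for x in d.b]
    return eln_a, eln_b


def mean_params(d: DirichletCounts) -> tuple[np.ndarray, list[np.ndarray]]:
    """Column-normalised counts: posterior-mean estimates of A and B."""
    a_bar = d.a / d.a.sum(axis=0, keepdims=True)
    b_bar = [x / x.sum(axis=0, keepdims=True) for x in d.b]
    return a_bar, b_bar


def update_counts(
    d: DirichletCounts,
    o: int,
    s_post: np.ndarray,
    s_prev: np.ndarray | None = None,
    action: int | None = None,
    rate: float = 1.0,
) -> DirichletCounts:
    """Accumulate evidence into the Dirichlet counts, returning a new object.

    Row ``o`` of the likelihood counts gains ``rate * s_post``.  If ``s_prev``
    and ``action`` are given, that action's transition counts gain
    ``rate * outer(s_post, s_prev)``.  ``rate`` is the learning rate (counts
    added per observation); the total mass added to ``a`` equals ``rate``
    because ``s_post`` sums to one.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    s_post = np.asarray(s_post, dtype=float)
    if not (0 <= o < d.a.shape[0]):
        raise IndexError(f"outcome index {o} out of range 0..{d.a.shape[0] - 1}")
    out = d.copy()
    out.a[o, :] += rate * s_post
    if (s_prev is None) != (action is None):
        raise ValueError("s_prev and action must be given together")
    if action is not None:
        if not (0 <= action < len(d.b)):
            raise IndexError(f"action index {action} out of range 0..{len(d.b) - 1}")
        out.b[action] += rate * np.outer(s_post, np.asarray(s_prev, dtype=float))
    return out
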