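"""Variational free energy for a categorical posterior.

For a single inference step the generative model contributes two log-domain
messages over hidden states: the prior (the forward prediction
``ln(B[u] @ s_prev)``, or ``ln D`` at the first step) and the likelihood
evidence for the sampled outcome (``ln A[o, :]``).  With a categorical
posterior ``s`` the free energy is

    F(s) = sum_i s_i * (ln s_i - log_prior_i - log_evidence_i)
         = KL(s || posterior) - ln P(o),

so F is bounded below by the negative log evidence, with equality exactly at
the Bayes posterior ``softmax(log_prior + log_evidence)``.  The gradient
``ln s - log_prior - log_evidence`` (the additive constant 1 is dropped --
softmax and simplex normalisation annihilate constants) is the prediction
error driving neuronal belief updating, and the Hessian ``diag(1/s)`` is
positive definite on the simplex tangent space: the landscape is convex.

All quantities are in nats.  Probabilities are floored at ``FLOOR`` before
any logarithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import null_space

from .geometry import FLOOR, BoundaryWarning, as_belief, floor_beliefs, softmax

__all__ = [
    "FreeEnergyContext",
    "free_energy",
    "free_energy_gradient",
    "tangent_project",
    "exact_posterior",
    "free_energy_hessian_psd",
]


@dataclass(frozen=True)
class FreeEnergyContext:
    """Log-domain messages defining one inference step's free energy.

    ``log_likelihood_evidence`` is ``ln A^T`` applied to the observation
    (i.e. ``ln A[o, :]``); ``log_prior`` is the log of the predictive prior
    over states.  Both are floored, hence finite, and share one dimension.
    """

    log_likelihood_evidence: np.ndarray
    log_prior: np.ndarray

    def __post_init__(self) -> None:
        lle = np.asarray(self.log_likelihood_evidence, dtype=float)
        lp = np.asarray(self.log_prior, dtype=float)
        if lle.shape != lp.shape or lle.ndim != 1:
            raise ValueError("evidence and prior must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(lle)) and np.all(np.isfinite(lp))):
            raise ValueError("context must be finite; floor probabilities first")
        object.__setattr__(self, "log_likelihood_evidence", lle)
        object.__setattr__(self, "log_prior", lp)

    @classmethod
    def from_distributions(
        cls,
        likelihood_evidence: Sequence[float] | np.ndarray,
        prior: Sequence[float] | np.ndarray,
        floor: float = FLOOR,
    ) -> "FreeEnergyContext":
        """Build a context from probability-domain messages, flooring then logging."""
        lle = np.log(np.clip(np.asarray(likelihood_evidence, dtype=float), floor, None))
        lp = np.log(floor_beliefs(np.asarray(prior, dtype=float), floor))
        return cls(log_likelihood_evidence=lle, log_prior=lp)

    @property
    def n(self) -> int:
        return self.log_prior.size


def free_energy(s: np.ndarray, ctx: FreeEnergyContext) -> float:
    """F(s) = E_s[ln s - ln prior - ln evidence], with 0 * ln 0 = 0.  In nats."""
    s = as_belief(s)
    if s.size != ctx.n:
        raise ValueError(f"dimension mismatch: belief {s.size} vs context {ctx.n}")
    ln_s = np.log(np.clip(s, FLOOR, None))
    return float(np.sum(s * (ln_s - ctx.log_prior - ctx.log_likelihood_evidence)))


def free_energy_gradient(s: np.ndarray, ctx: FreeEnergyContext) -> np.ndarray:
    """Prediction error ``ln s - log_prior - log_evidence``.

    The constant ``+1`` from differentiating ``s ln s`` is omitted: both the
    softmax update and simplex normalisation annihilate constant shifts.
    Boundary beliefs are floored first (with a warning).
    """
    s = as_belief(s)
    if s.size != ctx.n:
        raise ValueError(f"dimension mismatch: belief {s.size} vs context {ctx.n}")
    if np.any(s <= 0.0):
        warnings.warn(
            "boundary belief passed to free_energy_gradient; flooring first",
            BoundaryWarning,
            stacklevel=2,
        )
    s = floor_beliefs(s)
    return np.log(s) - ctx.log_prior - ctx.log_likelihood_evidence


def tangent_project(g: np.ndarray) -> np.ndarray:
    """Project a gradient onto the simplex tangent space (remove its mean)."""
    g = np.asarray(g, dtype=float)
    return g - g.mean()


def exact_posterior(ctx: FreeEnergyContext) -> np.ndarray:
    """Bayes posterior ``softmax(log_prior + log_evidence)`` -- the F minimiser."""
    return softmax(ctx.log_prior + ctx.log_likelihood_evidence)


def free_energy_hessian_psd(
    ctx: FreeEnergyContext, s: np.ndarray
) -> tuple[bool, float]:
    """Check convexity of F at ``s`` restricted to the simplex tangent space.

    The Hessian of F is ``diag(1/s)`` (the context enters only linearly).
    Returns ``(is_positive_definite, min_tangent_eigenvalue)`` where the
    eigenvalues are those of the Hessian projected onto the sum-zero
    subspace.
    """
    s = floor_beliefs(as_belief(s))
    if s.size != ctx.n:
        raise ValueError(f"dimension mismatch: belief {s.size} vs context {ctx.n}")
    hess = np.diag(1.0 / s)
    u = null_space(np.ones((1, s.size)))  # orthonormal basis of the tangent space
    tangent_hess = u.T @ hess @ u
    eigs = np.linalg.eigvalsh(tangent_hess)
    min_eig = float(eigs.min())
    return min_eig > 0.0, min_eig
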