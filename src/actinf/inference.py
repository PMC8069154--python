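"""Perceptual inference: two belief-update schemes and simulated electrophysiology.

Both schemes descend the (convex) single-step free energy from the same
starting belief, with step size ``eps``:

* ``active_inference``: ``s <- softmax(ln s - eps * grad F)``.  Equivalently
  ``s * exp(-eps * grad F)`` renormalised -- an exponentiated-gradient /
  mirror-descent step.  In log-space the iterate moves along a straight line
  toward the exact posterior's natural parameters, so the scheme is
  unconditionally simplex-preserving and monotone in F for ``eps <= 1``.
* ``natural_gradient``: ``s <- (s - eps * s * grad F)`` renormalised by its
  component sum.  ``s * grad F`` is the inverse Fisher metric ``diag(s)``
  acting on the gradient, i.e. steepest descent in information space,
  followed by the simplest projection back to the simplex.  A first-order
  Taylor expansion of the exponential shows the two updates agree to
  ``O(eps^2)`` per step.

The voltage code ``v = ln s`` (defined up to an additive constant, with
``s = softmax(v)``) is recorded alongside the beliefs; its per-iterate rate
of change is returned by :func:`simulated_lfp` as a proxy for local field
potentials, decaying to zero as the free-energy gradient vanishes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .free_energy import FreeEnergyContext, free_energy_gradient
from .geometry import InfoPath, as_belief, floor_beliefs, softmax

__all__ = [
    "SCHEMES",
    "InferenceTrace",
    "ai_update",
    "ng_update",
    "run_inference",
    "simulated_lfp",
]


def ai_update(s: np.ndarray, ctx: FreeEnergyContext, eps: float) -> np.ndarray:
    """One active-inference step: ``softmax(ln s - eps * grad F)``."""
    if eps < 0:
        raise ValueError("step size must be non-negative")
    s = floor_beliefs(as_belief(s))
    g = free_energy_gradient(s, ctx)
    return softmax(np.log(s) - eps * g)


def ng_update(s: np.ndarray, ctx: FreeEnergyContext, eps: float) -> np.ndarray:
    """One natural-gradient step: ``(s - eps * s * grad F)`` sum-normalised.

    Components driven negative by a large step are clipped to zero before
    renormalisation (then floored back into the interior).  In the
    pathological case where every component would be non-positive, the step
    is halved until the iterate is usable, with a warning.
    """
    if eps < 0:
        raise ValueError("step size must be non-negative")
    s = floor_beliefs(as_belief(s))
    g = free_energy_gradient(s, ctx)
    natural_step = s * g  # diag(s) @ g: inverse-metric action is elementwise
    step = eps
    raw = s - step * natural_step
    while raw.max() <= 0.0:
        step *= 0.5
        warnings.warn(
            f"natural-gradient iterate left the simplex entirely; halving step to {step:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        raw = s - step * natural_step
    raw = np.clip(raw, 0.0, None)
    return floor_beliefs(raw / raw.sum())


SCHEMES = {
    "active_inference": ai_update,
    "ai": ai_update,
    "natural_gradient": ng_update,
    "ng": ng_update,
}


@dataclass
class InferenceTrace:
    """Iterate-by-iterate record of one perceptual-inference run.

    ``beliefs[i] == softmax(voltages[i])`` at every iterate;
    ``free_energies`` is non-increasing on these convex problems for the
    default step sizes; ``info_path`` accumulates the information distance
    between consecutive iterates.
    """

    beliefs: np.ndarray          # (iterations + 1, n)
    voltages: np.ndarray         # (iterations + 1, n); v = ln s
    gradient_norms: np.ndarray   # tangent-projected gradient norm per iterate
    free_energies: np.ndarray    # nats, per iterate
    info_path: InfoPath
    converged: bool
    iterations: int
    scheme: str

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (iterate, state)."""
        n_iter, n = self.beliefs.shape
        lfp = simulated_lfp(self)
        rows = []
        cumulative = self.info_path.cumulative
        for t in range(n_iter):
            for j in range(n):
                rows.append(
                    {
                        "iteration": t,
                        "state": j,
                        "belief": self.beliefs[t, j],
                        "voltage": self.voltages[t, j],
                        "lfp": lfp[t - 1, j] if t >= 1 else 0.0,
                        "cumulative_information_length": cumulative[t],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_inference(
    s0: np.ndarray,
    ctx: FreeEnergyContext,
    scheme: str = "active_inference",
    eps: float = 0.25,
    max_iter: int = 64,
    tol: float = 1e-4,
    distance: str = "chord",
) -> InferenceTrace:
    """Iterate the chosen update from ``s0`` until the tangent gradient norm
    drops below ``tol`` or ``max_iter`` steps are taken.

    Non-convergence sets ``converged=False`` without raising; a non-finite
    iterate aborts with ``ArithmeticError`` carrying the partial trace.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    use_ai = SCHEMES[scheme] is ai_update
    if distance not in {"chord", "arc"}:
        raise ValueError(f"unknown distance kind {distance!r}")
    eta = ctx.log_prior + ctx.log_likelihood_evidence
    s = floor_beliefs(as_belief(s0))
    ln_s = np.log(s)
    g = ln_s - eta
    beliefs = [s]
    norms = [float(np.linalg.norm(g - g.mean()))]
    energies = [float(s @ g)]
    converged = norms[-1] < tol
    while not converged and len(beliefs) - 1 < max_iter:
        if use_ai:
            v = (1.0 - eps) * ln_s + eps * eta
            z = np.exp(v - v.max())
            s = floor_beliefs(z / z.sum())
        else:
            step = eps
            raw = s - step * (s * g)
            while raw.max() <= 0.0:
                step *= 0.5
                warnings.warn(
                    "natural-gradient iterate left the simplex entirely; "
                    f"halving step to {step:g}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                raw = s - step * (s * g)
            raw = np.clip(raw, 0.0, None)
            s = floor_beliefs(raw / raw.sum())
        if not np.all(np.isfinite(s)):
            raise ArithmeticError(
                f"non-finite belief at iteration {len(beliefs)} of scheme {scheme!r}; "
                f"trace so far: {np.array(beliefs)!r}"
            )
        ln_s = np.log(s)
        g = ln_s - eta
        beliefs.append(s)
        norms.append(float(np.linalg.norm(g - g.mean())))
        energies.append(float(s @ g))
        converged = norms[-1] < tol
    belief_arr = np.array(beliefs)
    voltages = np.log(belief_arr)
    sq = np.sqrt(belief_arr)
    if distance == "chord":
        steps = 2.0 * np.linalg.norm(np.diff(sq, axis=0), axis=1)
    else:
        steps = 2.0 * np.arccos(np.clip(np.einsum("ij,ij->i", sq[:-1], sq[1:]), -1.0, 1.0))
    info_path = InfoPath(
        points=tuple(belief_arr),
        step_distances=steps,
        total_length=float(steps.sum()),
    )
    return InferenceTrace(
        beliefs=belief_arr,
        voltages=voltages,
        gradient_norms=np.array(norms),
        free_energies=np.array(energies),
        info_path=info_path,
        converged=converged,
        iterations=len(beliefs) - 1,
        scheme=scheme,
    )


def simulated_lfp(trace: InferenceTrace) -> np.ndarray:
    """Rate of change of the voltage code: row ``t`` is ``v(t+1) - v(t)``.

    One row per update; a single-iterate trace yields an empty array.  Rows
    decay toward zero as the free-energy gradient vanishes, mirroring the
    decay of evoked depolarisations once inference has converged.
    """
    if trace.voltages.shape[0] < 2:
        return np.empty((0, trace.voltages.shape[1]))
    return np.diff(trace.voltages, axis=0)
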