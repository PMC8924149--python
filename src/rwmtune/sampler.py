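"""Seeded random walk Metropolis: theta' = theta + S eps, accept w.p. min{1, pi'/pi}.

Acceptance is decided in the log domain (``log U < delta log pi``) so that
unnormalized densities and extreme ratios are handled without overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy import linalg

from .tuning import ProposalScaling

__all__ = ["TargetDensity", "ChainResult", "rwm_step", "run_chain", "gaussian_target"]


@dataclass(frozen=True)
class TargetDensity:
    """A target distribution known up to a constant through its log-density.

    ``exact_sampler(rng)`` draws one stationary state when available
    (Gaussian targets), enabling exact stationary starts.
    """

    dim: int
    log_density: Callable[[np.ndarray], float]
    exact_sampler: Optional[Callable[[np.random.Generator], np.ndarray]] = None
    name: str = ""


@dataclass(frozen=True)
class ChainResult:
    """States and acceptance indicators of one RWM run (post burn-in)."""

    states: np.ndarray = field(repr=False)  # (T, d)
    accepted: np.ndarray = field(repr=False)  # (T,) bool
    seed: int
    scaling: ProposalScaling
    initial_state: np.ndarray = field(repr=False)
    burn_in: int = 0
    target_name: str = ""

    @property
    def n_steps(self) -> int:
        return self.states.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean())

    def to_csv(self, path) -> None:
        d = self.states.shape[1]
        frame = pd.DataFrame(self.states, columns=[f"x{i}" for i in range(d)])
        frame.insert(0, "accepted", self.accepted.astype(int))
        frame.to_csv(path, index=False)


def rwm_step(
    state: np.ndarray,
    target: TargetDensity,
    scaling: ProposalScaling,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """One Metropolis step from ``state``; returns (next state, accepted flag)."""
    state = np.asarray(state, dtype=float)
    lp = target.log_density(state)
    if not np.isfinite(lp):
        raise ValueError("log-density at the current state is not finite")
    proposal = state + scaling.matrix @ rng.standard_normal(target.dim)
    lp_prop = target.log_density(proposal)
    if np.log(rng.random()) < lp_prop - lp:
        return proposal, True
    return state, False


def run_chain(
    target: TargetDensity,
    scaling: ProposalScaling,
    n_steps: int,
    init: Union[np.ndarray, str] = "stationary",
    seed: int = 0,
    burn_in: int = 0,
) -> ChainResult:
    """Run a RWM chain; identical seeds produce identical chains.

    ``init`` is a d-vector, or the string ``"stationary"`` to draw the start
    from the target's exact sampler.  ``burn_in`` initial steps are discarded
    from the returned states and acceptance indicators.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0 <= burn_in < n_steps:
        raise ValueError("burn_in must lie in [0, n_steps)")
    rng = np.random.default_rng(seed)
    d = target.dim
    if isinstance(init, str):
        if init != "stationary":
            raise ValueError(f"unknown init {init!r}")
        if target.exact_sampler is None:
            raise ValueError("stationary init requires the target's exact_sampler")
        x = np.asarray(target.exact_sampler(rng), dtype=float)
    else:
        x = np.asarray(init, dtype=float).copy()
    if x.shape != (d,):
        raise ValueError(f"initial state has shape {x.shape}, expected ({d},)")
    x0 = x.copy()
    lp = target.log_density(x)
    if not np.isfinite(lp):
        raise ValueError("log-density at the initial state is not finite")

    # all proposal increments and uniforms drawn up front: the loop body is
    # one log-density evaluation plus a comparison
    increments = rng.standard_normal((n_steps, d)) @ scaling.matrix.T
    log_u = np.log(rng.random(n_steps))
    states = np.empty((n_steps, d))
    accepted = np.zeros(n_steps, dtype=bool)
    log_density = target.log_density
    for k in range(n_steps):
        proposal = x + increments[k]
        lp_prop = log_density(proposal)
        if log_u[k] < lp_prop - lp:
            x = proposal
            lp = lp_prop
            accepted[k] = True
        states[k] = x

    init_state = states[burn_in - 1].copy() if burn_in > 0 else x0
    return ChainResult(
        states=states[burn_in:],
        accepted=accepted[burn_in:],
        seed=seed,
        scaling=scaling,
        initial_state=init_state,
        burn_in=burn_in,
        target_name=target.name,
    )


def gaussian_target(cov: np.ndarray, name: str = "gaussian") -> TargetDensity:
    """A centred Gaussian target N(0, cov) with an exact stationary sampler."""
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    d = cov.shape[0]
    chol = linalg.cholesky(cov, lower=True)
    precision = linalg.cho_solve((chol, True), np.eye(d))

    def log_density(x: np.ndarray) -> float:
        return -0.5 * float(x @ precision @ x)

    def exact_sampler(rng: np.random.Generator) -> np.ndarray:
        return chol @ rng.standard_normal(d)

    return TargetDensity(dim=d, log_density=log_density,
                         exact_sampler=exact_sampler, name=name)
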