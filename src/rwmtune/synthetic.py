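"""Synthetic-data generators with the statistical structure the analyses assume.

The logistic generator emulates the shape of a moderately large
epidemiological regression study: n = 4866 observations, an intercept plus 8
Gaussian covariates with AR(1) cross-correlation (default rho = 0.5, enough
parameter correlation to separate the preconditioned and isotropic samplers),
and coefficients drawn once per seed from N(0, 0.5^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .gaussian_study import ar1_covariance
from .information import InformationMetric
from .logistic import LogisticDataset

__all__ = ["LogisticGenSpec", "generate_logistic", "true_fisher_information"]


@dataclass(frozen=True)
class LogisticGenSpec:
    """Shape parameters of a synthetic logistic-regression study."""

    n: int = 4866
    d: int = 9  # including the intercept
    covariate_rho: float = 0.5
    theta0: np.ndarray | None = field(default=None, repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.d < 1:
            raise ValueError("need n >= 2 and d >= 1")
        if not 0 <= self.covariate_rho < 1:
            raise ValueError(f"covariate_rho must lie in [0, 1), got {self.covariate_rho}")
        if self.theta0 is not None and np.shape(self.theta0) != (self.d,):
            raise ValueError("theta0 must have length d")

    def resolve_theta0(self) -> np.ndarray:
        """The coefficients: supplied, or drawn once from N(0, 0.5^2) per seed."""
        if self.theta0 is not None:
            return np.asarray(self.theta0, dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(0,)))
        return 0.5 * rng.standard_normal(self.d)

    def covariate_chol(self) -> np.ndarray:
        if self.d == 1:
            return np.empty((0, 0))
        return np.linalg.cholesky(ar1_covariance(self.covariate_rho, self.d - 1))


def _draw_design(spec: LogisticGenSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    X = np.ones((n, spec.d))
    if spec.d > 1:
        X[:, 1:] = rng.standard_normal((n, spec.d - 1)) @ spec.covariate_chol().T
    return X


def generate_logistic(spec: LogisticGenSpec) -> LogisticDataset:
    """Draw a dataset: X ~ N(0, AR1(rho)) covariates, r ~ Bernoulli(logistic(X theta0))."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    theta0 = spec.resolve_theta0()
    X = _draw_design(spec, rng, spec.n)
    p = expit(X @ theta0)
    r = (rng.random(spec.n) < p).astype(float)
    return LogisticDataset(X=X, r=r, theta0=theta0)


def true_fisher_information(
    spec: LogisticGenSpec,
    n_draws: int = 1_000_000,
    seed: int | None = None,
) -> tuple[InformationMetric, np.ndarray]:
    """Monte-Carlo Fisher information E[p(1-p) X X^T] at theta0, with SE matrix.

    Fresh covariate draws, independent of any generated dataset.  When
    theta0 = 0 the weight p(1-p) is exactly 1/4 and the estimate converges to
    0.25 E[X X^T].
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed if seed is None else seed, spawn_key=(2,))
    )
    theta0 = spec.resolve_theta0()
    total = np.zeros((spec.d, spec.d))
    total_sq = np.zeros((spec.d, spec.d))
    chunk = 100_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        X = _draw_design(spec, rng, m)
        w = expit(X @ theta0)
        w = w * (1.0 - w)
        total += np.einsum("ni,nj->ij", X * w[:, None], X)
        # second moment of the per-draw summand w x_i x_j, entrywise
        total_sq += np.einsum("ni,nj->ij", (X**2) * (w**2)[:, None], X**2)
        done += m
    fisher = total / n_draws
    var = total_sq / n_draws - fisher**2
    se = np.sqrt(np.maximum(var, 0.0) / n_draws)
    return InformationMetric.from_matrix(fisher), se
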