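"""Bayesian logistic regression: log-posterior, MAP fit, observed information,
and preconditioned RWM tuning on the posterior.

The model: binary responses ``r_i ~ Bernoulli(logistic(x_i^T theta))`` with an
intercept as the first covariate, and independent N(0, prior_sd^2) priors on
the coefficients (weak by default, so the MAP is close to the MLE at the
sample sizes considered).  The standardized observed information

    I_hat_n = (1/n) sum_i p_i (1 - p_i) x_i x_i^T   (at the MAP)

is the data-term average negative log-likelihood Hessian; its inverse
Cholesky factor supplies the preconditioner M_n in the proposal scaling
``S_n = (ell / sqrt(d n)) M_n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import tuning
from .diagnostics import ChainSummary, summarize_chain
from .information import InformationMetric
from .sampler import TargetDensity, run_chain

__all__ = [
    "LogisticDataset",
    "GaussianPrior",
    "PosteriorFit",
    "log_posterior",
    "log_posterior_grad",
    "neg_loglik_hessian",
    "fit_map",
    "posterior_target",
    "tune_and_sample_posterior",
]

DEFAULT_PRIOR_SD = 10.0


@dataclass(frozen=True)
class LogisticDataset:
    """Design matrix (first column all ones), binary responses, optional truth."""

    X: np.ndarray = field(repr=False)
    r: np.ndarray = field(repr=False)
    theta0: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        X, r = self.X, self.r
        if X.ndim != 2 or len(r) != X.shape[0]:
            raise ValueError("X must be n x d with matching response length")
        if X.shape[0] <= X.shape[1]:
            raise ValueError("need more observations than parameters")
        if not np.all(X[:, 0] == 1.0):
            raise ValueError("first column of X must be the intercept (all ones)")
        if not np.isin(r, (0, 1)).all():
            raise ValueError("responses must be binary 0/1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(self.X[:, 1:], columns=[f"x{i}" for i in range(1, self.d)])
        frame.insert(0, "r", self.r.astype(int))
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LogisticDataset":
        frame = pd.read_csv(path)
        r = frame.pop("r").to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(frame)), frame.to_numpy(dtype=float)])
        return cls(X=X, r=r)


@dataclass(frozen=True)
class GaussianPrior:
    """Independent zero-mean Gaussian prior, one standard deviation for all."""

    sd: float = DEFAULT_PRIOR_SD

    def log_density(self, theta: np.ndarray) -> float:
        return -0.5 * float(theta @ theta) / self.sd**2

    def grad(self, theta: np.ndarray) -> np.ndarray:
        return -theta / self.sd**2

    def hessian(self, d: int) -> np.ndarray:
        return -np.eye(d) / self.sd**2


@dataclass(frozen=True)
class PosteriorFit:
    theta_hat: np.ndarray = field(repr=False)
    obs_info: np.ndarray = field(repr=False)
    converged: bool = True
    n_iter: int = 0


def log_posterior(theta: np.ndarray, data: LogisticDataset,
                  prior: GaussianPrior | None = None) -> float:
    """Unnormalized log-posterior; overflow-safe via logaddexp."""
    prior = prior or GaussianPrior()
    eta = data.X @ theta
    loglik = float(data.r @ eta - np.logaddexp(0.0, eta).sum())
    return loglik + prior.log_density(theta)


def log_posterior_grad(theta: np.ndarray, data: LogisticDataset,
                       prior: GaussianPrior | None = None) -> np.ndarray:
    prior = prior or GaussianPrior()
    p = expit(data.X @ theta)
    return data.X.T @ (data.r - p) + prior.grad(theta)


def neg_loglik_hessian(theta: np.ndarray, data: LogisticDataset) -> np.ndarray:
    """Data-term Hessian of the negative log-likelihood: sum p(1-p) x x^T."""
    p = expit(data.X @ theta)
    w = p * (1.0 - p)
    return (data.X * w[:, None]).T @ data.X


def fit_map(data: LogisticDataset, prior: GaussianPrior | None = None,
            tol: float = 1e-8, max_iter: int = 100) -> PosteriorFit:
    """Newton iterations to the MAP; gradient norm below ``tol`` on success.

    The standardized observed information is the data-term average Hessian at
    the MAP, excluding the (weak) prior curvature.  Complete separation shows
    up as a diverging estimate and raises.
    """
    prior = prior or GaussianPrior()
    theta = np.zeros(data.d)
    value = log_posterior(theta, data, prior)
    for it in range(1, max_iter + 1):
        grad = log_posterior_grad(theta, data, prior)
        if np.linalg.norm(grad) < tol:
            if np.linalg.norm(theta) > 100.0:
                # likelihood gradient underflows once fitted probabilities
                # saturate, so a "converged" huge estimate means separation
                raise RuntimeError(
                    "MAP estimate diverging; responses may be completely separated"
                )
            obs_info = neg_loglik_hessian(theta, data) / data.n
            return PosteriorFit(theta_hat=theta, obs_info=obs_info,
                                converged=True, n_iter=it - 1)
        hess_neg = neg_loglik_hessian(theta, data) - prior.hessian(data.d)
        step = np.linalg.solve(hess_neg, grad)
        # backtracking keeps Newton honest far from the optimum
        t = 1.0
        for _ in range(40):
            candidate = theta + t * step
            cand_value = log_posterior(candidate, data, prior)
            # near the optimum the improvement sits below machine precision;
            # accept any step that does not measurably decrease the objective
            if cand_value >= value - 1e-9 * max(abs(value), 1.0):
                break
            t *= 0.5
        else:
            raise RuntimeError("MAP line search failed; data may be degenerate")
        theta, value = candidate, cand_value
        if np.linalg.norm(theta) > 1e4:
            raise RuntimeError(
                "MAP estimate diverging; responses may be completely separated"
            )
    raise RuntimeError(f"MAP did not converge in {max_iter} iterations")


def posterior_target(data: LogisticDataset,
                     prior: GaussianPrior | None = None) -> TargetDensity:
    prior = prior or GaussianPrior()
    return TargetDensity(
        dim=data.d,
        log_density=lambda th: log_posterior(th, data, prior),
        name=f"logistic-posterior(n={data.n}, d={data.d})",
    )


def tune_and_sample_posterior(
    data: LogisticDataset,
    prior: GaussianPrior | None = None,
    mode: str = "cholesky",
    n_steps: int = 200_000,
    seed: int = 0,
    burn_in_frac: float = 0.1,
    ell: float | None = None,
    tune_n_samples: int = 100_000,
) -> tuple[tuning.TuningResult, ChainSummary, PosteriorFit]:
    """Fit the MAP, build the guideline proposal, run RWM, and summarize.

    ``ell`` overrides the tuned step size (e.g. to use a tabulated guideline
    value directly).  The chain starts at the MAP and the first
    ``burn_in_frac`` of steps is discarded, approximating a stationary start.
    The diagnostics metric is ``n * I_hat_n`` so the empirical ESJD is on the
    scale of the limiting chain.
    """
    prior = prior or GaussianPrior()
    fit = fit_map(data, prior)
    info_n = InformationMetric.from_matrix(data.n * fit.obs_info)
    info_std = InformationMetric.from_matrix(fit.obs_info)
    d = data.d
    if mode == "cholesky":
        tuned = tuning.optimize_ell(d, mode="cholesky")
    else:
        tune_seed = int(np.random.SeedSequence(seed, spawn_key=(7,)).generate_state(1)[0] % 2**31)
        tuned = tuning.optimize_ell(d, mode="identity", info=info_std,
                                    n_samples=tune_n_samples, seed=tune_seed)
    use_ell = tuned.ell_hat if ell is None else float(ell)
    scaling = tuning.build_scaling(use_ell, d, n=data.n, mode=mode, info=info_std)
    burn_in = int(burn_in_frac * n_steps)
    chain = run_chain(posterior_target(data, prior), scaling, n_steps,
                      init=fit.theta_hat, seed=seed, burn_in=burn_in)
    summary = summarize_chain(chain, metric=info_n)
    return tuned, summary, fit
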