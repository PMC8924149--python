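"""Limiting-chain study on Gaussian targets with AR(1) covariance.

The target covariance has entries ``rho^|i-j|`` (autoregressive of order 1;
its inverse is tridiagonal).  For each (rho, d) the ESJD-optimal step size is
found for both proposal modes, stationary-start chains are run, and the
minimum marginal ESS per iteration and acceptance rate are tabulated.  The
matched (cholesky) proposal is invariant to rho by construction; the
isotropic proposal deteriorates as rho grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tuning
from .diagnostics import summarize_chain
from .information import InformationMetric
from .sampler import gaussian_target, run_chain

__all__ = ["AR1Spec", "ar1_covariance", "run_ar1_study", "plot_ar1_study"]

DEFAULT_RHOS = (0.0, 0.3, 0.6, 0.8, 0.9)
DEFAULT_DIMS = (5, 10, 50)


def ar1_covariance(rho: float, d: int) -> np.ndarray:
    """The d x d matrix with entries rho^|i-j|."""
    if not -1 < rho < 1:
        raise ValueError(f"rho must lie in (-1, 1), got {rho}")
    idx = np.arange(d)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass(frozen=True)
class AR1Spec:
    rho: float
    d: int

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 0.9:
            raise ValueError(
                f"rho must lie in [0, 0.9] (the isotropic proposal becomes "
                f"unreliable beyond 0.9), got {self.rho}"
            )

    @property
    def sigma(self) -> np.ndarray:
        return ar1_covariance(self.rho, self.d)

    def metric(self) -> InformationMetric:
        return InformationMetric.from_inverse(self.sigma)


def run_ar1_study(
    rhos=DEFAULT_RHOS,
    dims=DEFAULT_DIMS,
    n_steps: int = 200_000,
    n_reps: int = 10,
    seed: int = 0,
    modes=("identity", "cholesky"),
    tune_n_samples: int = 100_000,
    path=None,
) -> pd.DataFrame:
    """Tune, run and summarize limiting chains over a (rho, d, mode) grid.

    Returns one row per (rho, d, mode, replicate) with the tuned ell, the
    acceptance rate, the minimum marginal ESS per iteration and the metric
    ESJD.  Chains start in stationarity (exact Gaussian draws).
    """
    rhos = list(rhos)
    if not rhos:
        raise ValueError("rhos must be nonempty")
    for rho in rhos:
        if not 0 <= rho <= 0.9:
            raise ValueError(f"rho values must lie in [0, 0.9], got {rho}")
    ss = np.random.SeedSequence(seed)
    rows = []
    chol_cache: dict[int, tuning.TuningResult] = {}
    for d in dims:
        for rho in rhos:
            spec = AR1Spec(rho=rho, d=d)
            info = spec.metric()
            target = gaussian_target(spec.sigma, name=f"ar1(rho={rho}, d={d})")
            for mode in modes:
                if mode == "cholesky":
                    if d not in chol_cache:
                        chol_cache[d] = tuning.optimize_ell(d, mode="cholesky")
                    tuned = chol_cache[d]
                else:
                    tune_seed = int(
                        np.random.SeedSequence(seed, spawn_key=(d, int(100 * rho)))
                        .generate_state(1)[0] % 2**31
                    )
                    tuned = tuning.optimize_ell(
                        d, mode="identity", info=info,
                        n_samples=tune_n_samples, seed=tune_seed,
                    )
                scaling = tuning.build_scaling(
                    tuned.ell_hat, d, mode=mode, info=info
                )
                for rep in range(n_reps):
                    chain_seed = int(
                        np.random.SeedSequence(
                            seed,
                            spawn_key=(d, int(100 * rho),
                                       0 if mode == "identity" else 1, rep),
                        ).generate_state(1)[0] % 2**31
                    )
                    chain = run_chain(target, scaling, n_steps,
                                      init="stationary", seed=chain_seed)
                    summary = summarize_chain(chain, metric=info)
                    rows.append(
                        dict(
                            rho=rho,
                            d=d,
                            mode=mode,
                            rep=rep,
                            seed=chain_seed,
                            ell_hat=tuned.ell_hat,
                            acceptance=summary.acceptance_rate,
                            min_ess_per_iter=summary.min_ess_per_iter,
                            esjd=summary.esjd_metric.value,
                            esjd_se=summary.esjd_metric.std_error,
                        )
                    )
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, index=False)
    return table


def plot_ar1_study(table: pd.DataFrame, path) -> None:
    """Two panels: min ESS/iter and acceptance versus rho, per (d, mode)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = (
        table.groupby(["d", "mode", "rho"], as_index=False)
        .agg(ess=("min_ess_per_iter", "mean"), acc=("acceptance", "mean"))
    )
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for (d, mode), grp in agg.groupby(["d", "mode"]):
        style = "-" if mode == "cholesky" else "--"
        axes[0].plot(grp["rho"], grp["ess"], style, marker="o", label=f"d={d}, {mode}")
        axes[1].plot(grp["rho"], grp["acc"], style, marker="o", label=f"d={d}, {mode}")
    axes[0].set_xlabel(r"$\rho$")
    axes[0].set_ylabel("min ESS / iteration")
    axes[0].set_yscale("log")
    axes[1].set_xlabel(r"$\rho$")
    axes[1].set_ylabel("acceptance rate")
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
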