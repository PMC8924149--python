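"""Chain diagnostics: acceptance rate, metric ESJD, and marginal ESS.

The empirical ESJD is the trajectory average of
``(Z_{k+1} - Z_k)^T I (Z_{k+1} - Z_k)`` with a non-overlapping batch-means
standard error.  Effective sample size uses Geyer's initial monotone positive
sequence estimator on each marginal; the performance summary follows the
convention of reporting the minimum marginal ESS per iteration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .information import InformationMetric
from .sampler import ChainResult
from .theory import EfficiencyValue

__all__ = ["ChainSummary", "empirical_esjd", "ess_geyer", "ess_min_per_iteration", "summarize_chain"]


@dataclass(frozen=True)
class ChainSummary:
    acceptance_rate: float
    esjd_metric: EfficiencyValue
    min_ess_per_iter: float
    ess_per_coordinate: np.ndarray = field(repr=False)
    constant_coordinates: np.ndarray = field(repr=False)
    seed: int | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "acceptance_rate": self.acceptance_rate,
            "esjd": self.esjd_metric.value,
            "esjd_se": self.esjd_metric.std_error,
            "min_ess_per_iter": self.min_ess_per_iter,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _batch_means_se(x: np.ndarray) -> float:
    """SE of the mean by non-overlapping batch means with ~sqrt(T) batches."""
    m = len(x)
    n_batches = max(int(np.sqrt(m)), 2)
    batch = m // n_batches
    trimmed = x[: n_batches * batch].reshape(n_batches, batch)
    means = trimmed.mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def empirical_esjd(chain: ChainResult, metric: InformationMetric) -> EfficiencyValue:
    """Trajectory-average squared jump in the metric norm, with batch-means SE."""
    if chain.n_steps < 2:
        raise ValueError("chain must have at least 2 states")
    if metric.dim != chain.states.shape[1]:
        raise ValueError("metric dimension does not match the chain")
    path = np.vstack([chain.initial_state, chain.states])
    jumps = np.diff(path, axis=0)
    sq = metric.norm_sq(jumps)
    return EfficiencyValue(
        value=float(sq.mean()),
        std_error=_batch_means_se(sq),
        method="monte_carlo",
        n_samples=len(sq),
    )


def _autocovariance(x: np.ndarray) -> np.ndarray:
    n = len(x)
    x = x - x.mean()
    size = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, size)
    acov = np.fft.irfft(f * np.conj(f), size)[:n].real / n
    return acov

def ess_geyer(x: np.ndarray) -> float:
    """ESS of a 1-D series via the initial monotone positive sequence estimator.

    Returns 0.0 for a (numerically) constant series.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("series too short for an ESS estimate")
    acov = _autocovariance(x)
    g0 = acov[0]
    if g0 <= 1e-300 or not np.isfinite(g0):
        return 0.0
    m = (n // 2) * 2
    pair_sums = acov[0:m:2] + acov[1:m:2]  # Gamma_m = gamma_{2m} + gamma_{2m+1}
    # initial positive sequence: truncate at the first nonpositive pair sum
    nonpos = np.nonzero(pair_sums <= 0)[0]
    if len(nonpos):
        pair_sums = pair_sums[: nonpos[0]]
    if len(pair_sums) == 0:
        return float(n)
    # monotone: running minimum
    pair_sums = np.minimum.accumulate(pair_sums)
    tau = 2.0 * pair_sums.sum() / g0 - 1.0
    tau = max(tau, 1.0 / n)
    return float(n / tau)


def ess_min_per_iteration(chain: ChainResult,
                          metric: InformationMetric | None = None) -> ChainSummary:
    """Per-coordinate ESS, its minimum per iteration, and the chain summary.

    A constant coordinate yields ESS 0 and a warning (flagged in
    ``constant_coordinates``), not an exception.  ``metric`` defaults to the
    identity for the ESJD entry of the summary.
    """
    return summarize_chain(chain, metric=metric)


def summarize_chain(chain: ChainResult,
                    metric: InformationMetric | None = None) -> ChainSummary:
    states = chain.states
    n, d = states.shape
    if n < 100:
        raise ValueError("chain too short to summarize (need >= 100 states)")
    if metric is None:
        metric = InformationMetric.identity(d)
    ess = np.empty(d)
    constant = np.zeros(d, dtype=bool)
    for j in range(d):
        ess[j] = ess_geyer(states[:, j])
        if ess[j] == 0.0:
            constant[j] = True
    if constant.any():
        warnings.warn(
            f"coordinates {np.nonzero(constant)[0].tolist()} are constant; ESS set to 0",
            RuntimeWarning,
        )
    return ChainSummary(
        acceptance_rate=chain.acceptance_rate,
        esjd_metric=empirical_esjd(chain, metric),
        min_ess_per_iter=float(ess.min() / n),
        ess_per_coordinate=ess,
        constant_coordinates=constant,
        seed=chain.seed,
    )
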