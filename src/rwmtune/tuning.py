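"""Grid optimization of the step-size parameter ell and proposal scaling.

The practical guideline implemented here: propose ``theta' = theta + S_n eps``
with ``S_n = (ell / sqrt(d n)) M_n``, where ``M_n M_n^T`` is the inverse
(estimated) information matrix — "cholesky" mode — or ``M_n = 1`` —
"identity" mode.  The ESJD-optimal ``ell`` in cholesky mode depends only on
the dimension ``d`` and is tabulated by :func:`make_table1`; in identity
mode it depends on the information metric and is found by a Monte-Carlo grid
search with common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import theory
from .information import InformationMetric

__all__ = [
    "GridSpec",
    "TuningResult",
    "ProposalScaling",
    "optimize_ell",
    "make_table1",
    "build_scaling",
    "TABLE1_DIMS",
    "DEFAULT_GRID_CHOLESKY",
    "DEFAULT_GRID_IDENTITY",
]

TABLE1_DIMS = (1, 2, 3, 4, 5, 10, 15, 20, 30, 50)


@dataclass(frozen=True)
class GridSpec:
    """A regular grid (lo, hi, step) for the ell search."""

    lo: float
    hi: float
    step: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi and self.step > 0):
            raise ValueError(f"invalid grid {self}")

    def points(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step)) + 1
        return self.lo + self.step * np.arange(n)


DEFAULT_GRID_CHOLESKY = GridSpec(0.5, 6.0, 0.01)
DEFAULT_GRID_IDENTITY = GridSpec(0.01, 20.0, 0.01)


@dataclass(frozen=True)
class TuningResult:
    d: int
    mode: str
    grid: GridSpec
    ell_hat: float
    esjd_at_opt: float
    acceptance_at_opt: float
    method: str
    n_samples: int = 0
    seed: int | None = None

    @property
    def ell_hat_rounded(self) -> float:
        """ell_hat at the 2-decimal print precision of the guideline table."""
        return round(self.ell_hat, 2)


@dataclass(frozen=True)
class ProposalScaling:
    """The proposal scale matrix S: proposal increment is S @ eps."""

    ell: float
    d: int
    n: int | None
    mode: str
    matrix: np.ndarray = field(repr=False)

    @property
    def lam(self) -> float:
        return self.ell / np.sqrt(self.d)


def _coerce_grid(grid) -> GridSpec:
    if isinstance(grid, GridSpec):
        return grid
    return GridSpec(*grid)


def optimize_ell(
    d: int,
    mode: str = "cholesky",
    info: InformationMetric | None = None,
    grid: GridSpec | tuple | None = None,
    method: str | None = None,
    n_samples: int = theory.DEFAULT_MC_SAMPLES,
    seed=None,
) -> TuningResult:
    """Grid-maximize the ESJD over ell for a given dimension and proposal mode.

    Cholesky mode maximizes the matched-proposal ESJD (independent of the
    metric, quadrature by default); identity mode maximizes the isotropic
    ESJD for the supplied metric (Monte Carlo with common random numbers
    shared across the grid).  Ties break toward the smallest ell.  An argmax
    on the grid boundary raises, signalling a too-narrow grid.
    """
    if mode not in ("identity", "cholesky"):
        raise ValueError(f"mode must be 'identity' or 'cholesky', got {mode!r}")
    if mode == "identity" and info is None:
        raise ValueError("identity mode requires an information metric")
    if mode == "identity" and info.dim != d:
        raise ValueError(f"metric dimension {info.dim} != d = {d}")
    if grid is None:
        grid = DEFAULT_GRID_CHOLESKY if mode == "cholesky" else DEFAULT_GRID_IDENTITY
    grid = _coerce_grid(grid)
    if method is None:
        method = "quadrature" if mode == "cholesky" else "monte_carlo"

    ells = grid.points()
    sqrt_d = np.sqrt(d)
    seed_out = None

    if mode == "cholesky":
        if method == "quadrature":
            esjd_vals = np.array(
                [theory.esjd_matched(l, d, method="quadrature").value for l in ells]
            )
            n_used = 0
        else:
            rng = np.random.default_rng(_require(seed))
            seed_out = seed
            chi_sq = rng.chisquare(d, size=n_samples)
            chi = np.sqrt(chi_sq)
            esjd_vals = _grid_mc(ells / sqrt_d, chi, chi_sq)
            n_used = n_samples
    else:
        if method == "quadrature":
            if not info.is_scalar_multiple_of_identity():
                raise ValueError(
                    "identity-mode quadrature requires a scalar-multiple-of-identity "
                    "metric; use monte_carlo"
                )
            c = info.matrix[0, 0]
            esjd_vals = np.array(
                [
                    theory.esjd_identity(l / sqrt_d, info, method="quadrature").value
                    for l in ells
                ]
            )
            n_used = 0
        else:
            rng = np.random.default_rng(_require(seed))
            seed_out = seed
            norms = theory._metric_norms(info, rng, n_samples)
            esjd_vals = _grid_mc(ells / sqrt_d, norms, norms**2)
            n_used = n_samples

    idx = int(np.argmax(esjd_vals))  # first maximum: ties go to smallest ell
    if idx == 0 or idx == len(ells) - 1:
        raise ValueError(
            f"ESJD argmax ell = {ells[idx]:.4g} lies on the grid boundary "
            f"[{grid.lo}, {grid.hi}]; widen the grid"
        )
    ell_hat = float(ells[idx])

    if mode == "cholesky":
        acc = theory.acceptance_matched(
            ell_hat, d, method=method, n_samples=n_samples, seed=seed
        ).value
    else:
        if method == "quadrature":
            acc = theory.acceptance_identity(ell_hat / sqrt_d, info, method="quadrature").value
        else:
            acc = theory.acceptance_identity(ell_hat / sqrt_d, info, norms=norms).value

    return TuningResult(
        d=d,
        mode=mode,
        grid=grid,
        ell_hat=ell_hat,
        esjd_at_opt=float(esjd_vals[idx]),
        acceptance_at_opt=float(acc),
        method=method,
        n_samples=n_used,
        seed=seed_out,
    )


def _require(seed):
    if seed is None:
        raise ValueError("monte_carlo tuning requires an explicit seed")
    return seed


def _grid_mc(lams: np.ndarray, norms: np.ndarray, norms_sq: np.ndarray) -> np.ndarray:
    """Vectorized 2 lam^2 E[q^2 Phi(-lam q / 2)] over a lam grid, chunked.

    Chunk size keeps the (grid x samples) work array near 32 MB.
    """
    chunk = max(1, int(4_000_000 // max(len(norms), 1)))
    out = np.empty(len(lams))
    for start in range(0, len(lams), chunk):
        block = lams[start : start + chunk, None]
        phis = ndtr(-0.5 * block * norms[None, :])
        out[start : start + chunk] = (
            2.0 * block[:, 0] ** 2 * (norms_sq[None, :] * phis).mean(axis=1)
        )
    return out


def make_table1(
    dims=TABLE1_DIMS,
    grid: GridSpec | tuple | None = None,
    method: str = "quadrature",
    n_samples: int = theory.DEFAULT_MC_SAMPLES,
    seed=None,
    path=None,
) -> pd.DataFrame:
    """Tabulate the cholesky-mode optimal ell and acceptance rate per dimension.

    One row per d with ell_hat (2-decimal print precision) and the acceptance
    probability at the optimum, in percent.  Written as CSV when ``path`` is
    given.
    """
    if len(dims) == 0:
        raise ValueError("dims must be nonempty")
    rows = []
    for d in dims:
        res = optimize_ell(d, mode="cholesky", grid=grid, method=method,
                           n_samples=n_samples, seed=seed)
        rows.append(
            dict(
                d=d,
                mode="cholesky",
                ell_hat=res.ell_hat_rounded,
                esjd=res.esjd_at_opt,
                acceptance_pct=100.0 * res.acceptance_at_opt,
                method=res.method,
                n_samples=res.n_samples,
                seed=res.seed,
            )
        )
    table = pd.DataFrame(rows)
    if path is not None:
        table.to_csv(path, index=False)
    return table


def build_scaling(
    ell: float,
    d: int,
    n: int | None = None,
    mode: str = "identity",
    info: InformationMetric | None = None,
) -> ProposalScaling:
    """Build the proposal scale matrix S = (ell / sqrt(d n)) M.

    ``n`` is the data sample size when targeting a posterior; omit it for the
    limiting chain (then S = (ell/sqrt(d)) M).  In cholesky mode M is the
    lower Cholesky factor of the inverse information.
    """
    if ell <= 0:
        raise ValueError(f"ell must be positive, got {ell}")
    if d < 1:
        raise ValueError(f"d must be a positive integer, got {d}")
    if n is not None and n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    scale = ell / np.sqrt(d * n) if n is not None else ell / np.sqrt(d)
    if mode == "identity":
        matrix = scale * np.eye(d)
    elif mode == "cholesky":
        if info is None:
            raise ValueError("cholesky mode requires an information metric")
        if info.dim != d:
            raise ValueError(f"metric dimension {info.dim} != d = {d}")
        matrix = scale * info.chol_factor
    else:
        raise ValueError(f"mode must be 'identity' or 'cholesky', got {mode!r}")
    return ProposalScaling(ell=float(ell), d=int(d), n=n, mode=mode, matrix=matrix)
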