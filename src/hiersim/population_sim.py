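"""Individual-level population sampling with a target correlation structure.

Two generators are provided:

``sample_mvn``
    Standardised multivariate normal draws from the diagram-implied
    correlation matrix.

``sample_mixed``
    An iterative rank-matching generator for mixed normal/bernoulli
    marginals.  Each variable gets a fixed pool of values drawn from its
    target marginal; multivariate normal "shape" samples are drawn under an
    intermediate correlation matrix and each column is replaced by the
    rank-matched pool values, so marginals are exact by construction.  The
    intermediate matrix is updated additively by the residual between target
    and realised correlations until no further improvement is seen.

Correlations between a normal and a bernoulli variable are bounded above by
the point-biserial bound (``point_biserial_bound``); targets beyond the bound
are recorded as feasibility warnings in the diagnostics, not errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .path_model import VARIABLES

__all__ = [
    "Marginal",
    "PopulationSample",
    "sample_mvn",
    "sample_mixed",
    "point_biserial_bound",
    "nearest_correlation",
]

#: Smallest eigenvalue retained when repairing an intermediate matrix.
EIGEN_FLOOR = 1e-8


@dataclass(frozen=True)
class Marginal:
    """Target marginal for one variable: standard normal or bernoulli(p)."""

    kind: str  # "normal" | "bernoulli"
    p: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "bernoulli"):
            raise ValueError(f"unknown marginal kind {self.kind!r}")
        if self.kind == "bernoulli" and (self.p is None or not 0.0 < self.p < 1.0):
            raise ValueError("bernoulli prevalence must lie strictly in (0, 1)")


NORMAL = Marginal("normal")


@dataclass
class PopulationSample:
    """n individuals x (Z, L, N, X, Y) plus generation diagnostics."""

    data: pd.DataFrame
    marginals: dict[str, Marginal]
    target_corr: np.ndarray
    realized_corr: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def to_csv(self, path) -> None:
        """Dump the individual-level table (header row, one row per person)."""
        self.data.to_csv(path, index=False)


def point_biserial_bound(p: float) -> float:
    """Maximum attainable correlation between a N(0,1) and a bernoulli(p).

    Attained by thresholding the normal at its (1-p) quantile:
    ``phi(Phi^-1(1-p)) / sqrt(p (1-p))``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    q = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(q) / np.sqrt(p * (1.0 - p)))


def _bernoulli_pair_bound(p1: float, p2: float) -> float:
    """Frechet upper bound on the correlation of bernoulli(p1), bernoulli(p2)."""
    p11 = min(p1, p2)
    return float((p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2)))


def nearest_correlation(matrix: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalues are clipped at a small positive floor and the result is
    rescaled to unit diagonal.  Deterministic, single-shot repair.
    """
    sym = (matrix + matrix.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, EIGEN_FLOOR, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _mvn_draws(rng: np.random.Generator, sigma: np.ndarray, n: int) -> np.ndarray:
    """n x k standard-normal draws with correlation sigma (Cholesky)."""
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(nearest_correlation(sigma))
    return rng.standard_normal((n, sigma.shape[0])) @ chol.T


def _check_psd(sigma: np.ndarray) -> None:
    vals = np.linalg.eigvalsh((sigma + sigma.T) / 2.0)
    if vals.min() < -1e-8:
        raise ValueError("target correlation matrix is not positive semi-definite")


def sample_mvn(sigma: np.ndarray, n: int, seed: int) -> PopulationSample:
    """Draw ``n`` individuals from N(0, sigma) over (Z, L, N, X, Y)."""
    if n <= 0:
        raise ValueError("n must be positive")
    _check_psd(sigma)
    rng = np.random.default_rng(seed)
    values = _mvn_draws(rng, sigma, n)
    data = pd.DataFrame(values, columns=list(VARIABLES))
    realized = np.corrcoef(values, rowvar=False)
    return PopulationSample(
        data=data,
        marginals={v: NORMAL for v in VARIABLES},
        target_corr=np.asarray(sigma, dtype=float),
        realized_corr=realized,
        diagnostics={
            "generator": "mvn",
            "iterations": 1,
            "rmsr": _rmsr(sigma, realized),
            "feasibility_warnings": [],
        },
    )


def _rmsr(target: np.ndarray, realized: np.ndarray) -> float:
    """Root-mean-square residual over the off-diagonal entries."""
    k = target.shape[0]
    mask = ~np.eye(k, dtype=bool)
    return float(np.sqrt(np.mean((target[mask] - realized[mask]) ** 2)))


def _marginal_pool(rng: np.random.Generator, marginal: Marginal, n: int) -> np.ndarray:
    """Sorted pool of n values from the target marginal.

    Bernoulli pools use a deterministic composition of exactly round(n*p)
    ones so the realised prevalence is controlled, which stabilises
    rare-outcome settings.
    """
    if marginal.kind == "normal":
        return np.sort(rng.standard_normal(n))
    ones = int(round(n * marginal.p))
    pool = np.zeros(n)
    pool[n - ones:] = 1.0
    return pool  # already sorted


def _feasibility_warnings(
    sigma: np.ndarray, marginals: dict[str, Marginal]
) -> list[str]:
    warnings: list[str] = []
    names = list(VARIABLES)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            ma, mb = marginals[a], marginals[b]
            target = abs(sigma[i, j])
            if ma.kind == "normal" and mb.kind == "normal":
                continue
            if ma.kind == "bernoulli" and mb.kind == "bernoulli":
                bound = _bernoulli_pair_bound(ma.p, mb.p)
            else:
                p = ma.p if ma.kind == "bernoulli" else mb.p
                bound = point_biserial_bound(p)
            if target > bound + 1e-12:
                warnings.append(
                    f"target corr({a},{b}) = {sigma[i, j]:.3f} exceeds the "
                    f"attainable bound {bound:.3f} for the given marginals"
                )
    return warnings


def sample_mixed(
    sigma: np.ndarray,
    marginals: dict[str, Marginal],
    n: int,
    seed: int,
    max_outer_iterations: int = 50,
    patience: int = 10,
    tolerance: float = 1e-4,
) -> PopulationSample:
    """Iterative rank-matching sampler for mixed normal/bernoulli marginals.

    Each output column is an exact permutation of its marginal pool; the
    intermediate correlation matrix is nudged by the residual (target minus
    realised) each iteration and repaired to a valid correlation matrix when
    needed.  The sample with the smallest root-mean-square residual is
    retained; iteration stops after ``patience`` rounds without an
    improvement larger than ``tolerance``, or ``max_outer_iterations``.

    With all-normal marginals this reduces to (rank-matched) multivariate
    normal sampling.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    _check_psd(sigma)
    sigma = np.asarray(sigma, dtype=float)
    missing = set(VARIABLES) - set(marginals)
    if missing:
        raise ValueError(f"missing marginal specs: {sorted(missing)}")

    root = np.random.SeedSequence(seed)
    # One substream per variable pool plus one for the iteration draws, so
    # changing one marginal does not perturb the other pools.
    streams = root.spawn(len(VARIABLES) + 1)
    pools = {
        name: _marginal_pool(np.random.default_rng(streams[i]), marginals[name], n)
        for i, name in enumerate(VARIABLES)
    }
    iter_rng = np.random.default_rng(streams[-1])

    warnings = _feasibility_warnings(sigma, marginals)

    intermediate = sigma.copy()
    best_values: np.ndarray | None = None
    best_rmsr = np.inf
    best_realized: np.ndarray | None = None
    rmsr_path: list[float] = []
    stall = 0
    iterations = 0
    for _ in range(max_outer_iterations):
        iterations += 1
        shape = _mvn_draws(iter_rng, nearest_correlation(intermediate), n)
        values = np.empty_like(shape)
        for j, name in enumerate(VARIABLES):
            # Rank matching: the pool value of rank r goes to the individual
            # holding rank r in the shape column (stable sort breaks ties by
            # the shape column's order statistics).
            order = np.argsort(shape[:, j], kind="stable")
            values[order, j] = pools[name]
        realized = np.corrcoef(values, rowvar=False)
        rmsr = _rmsr(sigma, realized)
        if rmsr < best_rmsr - tolerance:
            stall = 0
        else:
            stall += 1
        if rmsr < best_rmsr:
            best_rmsr = rmsr
            best_values = values
            best_realized = realized
        rmsr_path.append(best_rmsr)
        if stall >= patience:
            break
        intermediate = nearest_correlation(intermediate + (sigma - realized))

    data = pd.DataFrame(best_values, columns=list(VARIABLES))
    return PopulationSample(
        data=data,
        marginals=dict(marginals),
        target_corr=sigma,
        realized_corr=best_realized,
        diagnostics={
            "generator": "rank-matching",
            "iterations": iterations,
            "rmsr": best_rmsr,
            "rmsr_path": rmsr_path,
            "feasibility_warnings": warnings,
        },
    )
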