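"""Cluster-size construction from the latent individual variable N_i.

The algorithm turns the latent driver N_i into C integer cluster sizes and a
cluster assignment, so cluster size N_j inherits the causal content of its
individual-level source:

(a) stable-sort individuals by ascending N_i;
(b) affine-rescale the sorted N_i to candidate sizes with mean n/C and a
    target standard deviation;
(c) split the sorted individuals into C evenly sized consecutive subsets;
(d) per subset take one candidate uniformly at random and round
    (``random-pick``, default) or round the subset mean (``subset-mean``);
(e) add/subtract 1 from uniformly chosen clusters until the sizes sum to n
    exactly (never reducing a size below 1);
(f) re-walk the sorted individuals, assigning the first N_1 of them to
    cluster 0, the next N_2 to cluster 1, and so on.

Because assignment follows the N_i ranks, cluster mean N_i is nondecreasing
in cluster index and cluster size carries a cross-level association with any
variable correlated with N_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population_sim import PopulationSample

__all__ = ["ClusterAssignment", "build_clusters", "crosslevel_diagnostics"]

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Integer cluster sizes plus a per-individual cluster label (0-based)."""

    C: int
    sizes: np.ndarray  # int, length C, sums to n
    labels: np.ndarray  # int in 0..C-1, aligned to the original individual order
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.sizes.sum())

    def sizes_per_individual(self) -> np.ndarray:
        """N_j attached to each individual via its cluster label."""
        return self.sizes[self.labels]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(individual index -> cluster) and (cluster -> size) tables."""
        members = pd.DataFrame(
            {"individual": np.arange(len(self.labels)), "cluster": self.labels}
        )
        sizes = pd.DataFrame({"cluster": np.arange(self.C), "N_j": self.sizes})
        return members, sizes


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def build_clusters(
    n_latent: np.ndarray,
    C: int,
    size_sd: float = 10.0,
    seed: int = 0,
    mode: str = "random-pick",
    size_mean: float | None = None,
) -> ClusterAssignment:
    """Execute steps (a)-(f) above on the latent column ``n_latent``.

    ``size_mean`` defaults to n/C and, if given, must equal it (the sizes
    must sum to the population size).  Candidate sizes that round below 1
    are floored at 1 with a logged warning.
    """
    n_latent = np.asarray(n_latent, dtype=float)
    n = n_latent.size
    if not 1 <= C <= n:
        raise ValueError(f"cluster count C={C} must lie in 1..n={n}")
    if size_sd <= 0:
        raise ValueError("size_sd must be positive")
    target_mean = n / C
    if size_mean is not None and not np.isclose(size_mean, target_mean):
        raise ValueError(f"size_mean must equal n/C = {target_mean}")
    rng = np.random.default_rng(seed)

    # (a) stable sort by ascending N_i (ties broken by original index)
    order = np.argsort(n_latent, kind="stable")
    sorted_latent = n_latent[order]

    # (b) affine rescale to candidate sizes (sample sd, denominator n-1)
    latent_sd = sorted_latent.std(ddof=1) if n > 1 else 0.0
    if latent_sd > 0:
        candidates = target_mean + (sorted_latent - sorted_latent.mean()) * (
            size_sd / latent_sd
        )
    else:
        candidates = np.full(n, target_mean)

    # (c) C evenly sized consecutive subsets; the first n mod C get one extra
    base, extra = divmod(n, C)
    subset_sizes = np.full(C, base, dtype=int)
    subset_sizes[:extra] += 1
    bounds = np.concatenate([[0], np.cumsum(subset_sizes)])

    # (d) one representative size per subset
    picks = np.empty(C)
    for j in range(C):
        lo, hi = bounds[j], bounds[j + 1]
        if mode == "random-pick":
            picks[j] = candidates[rng.integers(lo, hi)]
        elif mode == "subset-mean":
            picks[j] = candidates[lo:hi].mean()
        else:
            raise ValueError(f"unknown mode {mode!r}")
    sizes = _round_half_away(picks).astype(int)
    if (sizes < 1).any():
        logger.warning(
            "%d candidate cluster sizes rounded below 1; flooring at 1",
            int((sizes < 1).sum()),
        )
        sizes = np.maximum(sizes, 1)

    pre_adjustment = sizes.copy()

    # (e) random unit adjustments until the sizes sum to n exactly
    total = int(sizes.sum())
    while total != n:
        j = int(rng.integers(C))
        if total < n:
            sizes[j] += 1
            total += 1
        elif sizes[j] > 1:
            sizes[j] -= 1
            total -= 1

    # (f) contiguous assignment along the N_i ranks
    labels = np.empty(n, dtype=int)
    labels[order] = np.repeat(np.arange(C), sizes)

    return ClusterAssignment(
        C=C,
        sizes=sizes,
        labels=labels,
        provenance={
            "size_mean": target_mean,
            "size_sd": size_sd,
            "seed": seed,
            "mode": mode,
            "pre_adjustment_sizes": pre_adjustment,
        },
    )


def crosslevel_diagnostics(
    assignment: ClusterAssignment, sample: PopulationSample
) -> dict[str, float]:
    """Pearson correlations of cluster size N_j with cluster means of L, X, Y.

    Confirms the cross-level association exists when the L -> N coefficient
    is nonzero and is absent when it is zero.  Degenerate inputs (constant
    sizes or constant cluster means) yield NaN entries.
    """
    if len(sample.data) != len(assignment.labels):
        raise ValueError("assignment does not match the sample")
    grouped = sample.data.groupby(assignment.labels)
    means = grouped[["L", "X", "Y"]].mean()
    sizes = assignment.sizes.astype(float)
    out: dict[str, float] = {}
    for col in ("L", "X", "Y"):
        v = means[col].to_numpy()
        if np.std(sizes) == 0 or np.std(v) == 0:
            out[f"corr_Nj_{col}j"] = float("nan")
        else:
            out[f"corr_Nj_{col}j"] = float(np.corrcoef(sizes, v)[0, 1])
    return out
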