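"""Deterministic aggregation of individual-level data to cluster level.

Continuous variables aggregate to within-cluster arithmetic means; bernoulli
variables aggregate to within-cluster counts of ones.  Cluster size N_j is
copied from the assignment.  The aggregated latent confounder L_j is stored
for diagnostics and truth oracles but flagged latent: fitted models must
never use it, mirroring its unobservability in real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_builder import ClusterAssignment
from .path_model import VARIABLES
from .population_sim import PopulationSample

__all__ = ["ClusterTable", "aggregate"]


@dataclass
class ClusterTable:
    """C rows x (N_j, Z_j, L_j, X_j, Y_j) with per-column aggregation tags."""

    data: pd.DataFrame
    tags: dict[str, str]  # column -> "mean" | "count" | "size"
    latent: frozenset[str] = field(default_factory=lambda: frozenset({"L_j"}))

    @property
    def C(self) -> int:
        return len(self.data)

    def column(self, name: str, allow_latent: bool = False) -> np.ndarray:
        """Fetch a column; latent columns require ``allow_latent=True``."""
        if name in self.latent and not allow_latent:
            raise ValueError(f"{name} is latent and may not be used in fitted models")
        return self.data[name].to_numpy()

    def to_csv(self, path) -> None:
        """Write the table with a leading aggregation-tag comment line."""
        with open(path, "w") as fh:
            fh.write(
                "# aggregation: "
                + ", ".join(f"{c}={t}" for c, t in self.tags.items())
                + "\n"
            )
            self.data.to_csv(fh, index=False)


def aggregate(sample: PopulationSample, assignment: ClusterAssignment) -> ClusterTable:
    """Build the cluster table from a sample and its cluster assignment."""
    if len(sample.data) != len(assignment.labels):
        raise ValueError("sample and assignment lengths differ")
    grouped = sample.data.groupby(assignment.labels)
    columns: dict[str, np.ndarray] = {"N_j": assignment.sizes}
    tags: dict[str, str] = {"N_j": "size"}
    for name in VARIABLES:
        if name == "N":
            continue  # N_j is the integer cluster size, not the mean of N_i
        agg_name = f"{name}_j"
        if sample.marginals[name].kind == "bernoulli":
            columns[agg_name] = grouped[name].sum().to_numpy()
            tags[agg_name] = "count"
        else:
            columns[agg_name] = grouped[name].mean().to_numpy()
            tags[agg_name] = "mean"
    data = pd.DataFrame(columns, index=pd.RangeIndex(assignment.C, name="cluster"))
    return ClusterTable(data=data, tags=tags)
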