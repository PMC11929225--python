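"""Hierarchical causal diagram over five individual-level variables.

The diagram is a fixed five-variable template: an observed ("regular")
confounder Z, a latent confounder L, a latent size-driver N, the exposure X
and the outcome Y.  Directed edges carry standardised path coefficients

    rho1: Z -> L    rho2: Z -> X    rho3: Z -> Y
    rho4: L -> X    rho5: L -> Y    rho6: L -> N
    rho7: X -> Y

Every variable has unit variance, so the recursive linear system implied by
the diagram determines a Pearson correlation matrix exactly (Wright's path
tracing).  ``implied_correlation`` computes that matrix; ``validate_diagram``
checks feasibility (acyclicity, coefficient range, positive residual
variances).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "VARIABLES",
    "EDGES",
    "VariableSpec",
    "PathDiagram",
    "ValidationReport",
    "InfeasibleDiagramError",
    "validate_diagram",
    "implied_correlation",
]

#: Canonical variable order; also the lexicographic tie-break for the
#: topological sort, so results are deterministic.
VARIABLES: tuple[str, ...] = ("Z", "L", "N", "X", "Y")

#: Fixed edge template: (parent, child, coefficient name).
EDGES: tuple[tuple[str, str, str], ...] = (
    ("Z", "L", "rho1"),
    ("Z", "X", "rho2"),
    ("Z", "Y", "rho3"),
    ("L", "X", "rho4"),
    ("L", "Y", "rho5"),
    ("L", "N", "rho6"),
    ("X", "Y", "rho7"),
)

#: Residual variances below this are treated as infeasible standardisation.
MIN_RESIDUAL_VARIANCE = 1e-12


@dataclass(frozen=True)
class VariableSpec:
    """One individual-level variable of the diagram.

    Parameters
    ----------
    name:
        One of ``Z, L, N, X, Y``.
    observed:
        Whether the variable is observable at level 1.  L and N are latent.
    marginal:
        ``"normal"`` (standard normal) or ``"bernoulli"``.
    prevalence:
        Success probability for a bernoulli marginal, strictly in (0, 1).
    """

    name: str
    observed: bool = True
    marginal: str = "normal"
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.name not in VARIABLES:
            raise ValueError(f"unknown variable {self.name!r}")
        if self.marginal not in ("normal", "bernoulli"):
            raise ValueError(f"unknown marginal {self.marginal!r}")
        if self.marginal == "bernoulli":
            if self.prevalence is None or not 0.0 < self.prevalence < 1.0:
                raise ValueError("bernoulli prevalence must lie strictly in (0, 1)")


def _default_variables() -> tuple[VariableSpec, ...]:
    # L and N are latent at level 1 (circles in the diagram); Z, X, Y observed.
    return tuple(
        VariableSpec(name, observed=name not in ("L", "N")) for name in VARIABLES
    )


@dataclass(frozen=True)
class PathDiagram:
    """The five-variable template with its seven standardised coefficients."""

    rho: dict[str, float]
    variables: tuple[VariableSpec, ...] = field(default_factory=_default_variables)

    def __post_init__(self) -> None:
        missing = {name for _, _, name in EDGES} - set(self.rho)
        if missing:
            raise ValueError(f"missing coefficients: {sorted(missing)}")
        names = [v.name for v in self.variables]
        if sorted(names) != sorted(VARIABLES):
            raise ValueError("diagram requires exactly the variables Z, L, N, X, Y")

    @classmethod
    def from_coefficients(
        cls,
        rho1: float = 0.0,
        rho2: float = 0.0,
        rho3: float = 0.0,
        rho4: float = 0.0,
        rho5: float = 0.0,
        rho6: float = 0.0,
        rho7: float = 0.0,
        variables: tuple[VariableSpec, ...] | None = None,
    ) -> "PathDiagram":
        rho = {
            "rho1": rho1, "rho2": rho2, "rho3": rho3, "rho4": rho4,
            "rho5": rho5, "rho6": rho6, "rho7": rho7,
        }
        if variables is None:
            return cls(rho=rho)
        return cls(rho=rho, variables=variables)

    def graph(self) -> nx.DiGraph:
        """Edge-weighted DiGraph over the five variables."""
        g = nx.DiGraph()
        g.add_nodes_from(v.name for v in self.variables)
        for parent, child, name in EDGES:
            g.add_edge(parent, child, coefficient=float(self.rho[name]))
        return g

    def marginal_of(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    problems: tuple[str, ...]


class InfeasibleDiagramError(ValueError):
    """Standardisation is impossible: some residual variance is <= 0."""


def _topological_order(g: nx.DiGraph) -> list[str]:
    # Deterministic: lexicographic in the canonical (Z, L, N, X, Y) order.
    rank = {name: i for i, name in enumerate(VARIABLES)}
    return list(nx.lexicographical_topological_sort(g, key=lambda v: rank[v]))


def _implied_sigma(diagram: PathDiagram) -> np.ndarray:
    """Correlation matrix of the recursive standardised linear system.

    Walks variables in topological order; each child is the coefficient-
    weighted sum of its parents plus an independent residual scaled so the
    child has unit variance.  Covariances follow by linearity.
    """
    g = diagram.graph()
    order = _topological_order(g)
    idx = {name: i for i, name in enumerate(VARIABLES)}
    sigma = np.zeros((5, 5))
    for child in order:
        c = idx[child]
        parents = list(g.predecessors(child))
        w = np.array([g.edges[p, child]["coefficient"] for p in parents])
        p_idx = [idx[p] for p in parents]
        if parents:
            explained = float(w @ sigma[np.ix_(p_idx, p_idx)] @ w)
        else:
            explained = 0.0
        residual = 1.0 - explained
        if residual <= MIN_RESIDUAL_VARIANCE:
            raise InfeasibleDiagramError(
                f"negative residual variance for {child}: "
                f"parent contribution {explained:.6g} >= 1"
            )
        sigma[c, c] = 1.0
        for other in VARIABLES:
            o = idx[other]
            if other == child or sigma[o, o] == 0.0:
                continue  # not yet placed
            cov = float(w @ sigma[p_idx, o]) if parents else 0.0
            sigma[c, o] = sigma[o, c] = cov
    return sigma


def validate_diagram(diagram: PathDiagram) -> ValidationReport:
    """Check acyclicity, coefficient range and residual-variance feasibility.

    Returns a report rather than raising; callers decide whether to abort.
    """
    problems: list[str] = []
    g = diagram.graph()
    if not nx.is_directed_acyclic_graph(g):
        problems.append("cycle: edge set is not acyclic")
    for name, value in diagram.rho.items():
        if not -1.0 <= value <= 1.0:
            problems.append(f"coefficient out of range: {name} = {value}")
    if not problems:
        try:
            _implied_sigma(diagram)
        except InfeasibleDiagramError as exc:
            problems.append(f"negative residual variance: {exc}")
    return ValidationReport(ok=not problems, problems=tuple(problems))


def implied_correlation(diagram: PathDiagram) -> np.ndarray:
    """Exact 5x5 correlation matrix implied by the diagram.

    Rows/columns follow the canonical order ``Z, L, N, X, Y``.  Raises
    :class:`InfeasibleDiagramError` when standardisation is impossible and
    ``ValueError`` for any other validation failure.
    """
    report = validate_diagram(diagram)
    if not report.ok:
        if any(p.startswith("negative residual") for p in report.problems):
            raise InfeasibleDiagramError("; ".join(report.problems))
        raise ValueError("; ".join(report.problems))
    return _implied_sigma(diagram)
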