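import numpy as np
import pytest

from hiersim import (
    PathDiagram,
    ScenarioSpec,
    aggregate,
    build_clusters,
    implied_correlation,
    sample_mvn,
)


@pytest.fixture(scope="session")
def scenario2_sigma() -> np.ndarray:
    """Implied correlation matrix of the latent-confounding scenario."""
    return implied_correlation(
        PathDiagram.from_coefficients(rho4=0.3, rho5=0.3, rho6=0.8)
    )


@pytest.fixture(scope="session")
def small_population(scenario2_sigma):
    """A modest MVN population under the latent-confounding scenario."""
    return sample_mvn(scenario2_sigma, n=20_000, seed=123)


@pytest.fixture(scope="session")
def small_clustered(small_population):
    """(sample, assignment, table) triple at n=20000, C=40."""
    assignment = build_clusters(small_population.column("N"), C=40, seed=5)
    table = aggregate(small_population, assignment)
    return small_population, assignment, table


@pytest.fixture(scope="session")
def tiny_spec() -> ScenarioSpec:
    """A fast scenario spec for pipeline-level tests."""
    return ScenarioSpec.preset(
        "2", n=2_000, C=20, replicates=3, effect_grid=(0.0, 0.2), base_seed=11
    )
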