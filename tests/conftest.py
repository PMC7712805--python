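import numpy as np
import pytest

from adburden.population import (
    AGE_MIN,
    N_AGES,
    N_COHORTS,
    ADState,
    IncidenceCurve,
    PopulationProjection,
    PrevalenceCurve,
    StageDistribution,
    TransitionMatrix,
)


def flat_projection(n_years: int = 5, count: float = 1000.0,
                    start_year: int = 2020, region: str = "test") -> PopulationProjection:
    """Projection with every cohort at a constant count in every year."""
    years = np.arange(start_year, start_year + n_years)
    return PopulationProjection(
        region=region, years=years, counts=np.full((N_COHORTS, n_years), count)
    )


def empty_state(year: int = 2020, healthy: float = 1000.0) -> ADState:
    return ADState(year=year, ad_counts=np.zeros((N_AGES, 3)),
                   healthy_counts=np.full(N_AGES, healthy))


def zero_incidence(projection: PopulationProjection) -> IncidenceCurve:
    return IncidenceCurve(
        values=np.zeros((projection.n_years - 1, N_AGES)),
        start_years=projection.years[:-1],
    )


@pytest.fixture
def progressive_matrix() -> TransitionMatrix:
    """Mild -> (stay 0.6, Moderate 0.3, Death 0.1), progressive throughout."""
    return TransitionMatrix(np.array([
        [0.6, 0.3, 0.0, 0.1],
        [0.0, 0.6, 0.2, 0.2],
        [0.0, 0.0, 0.7, 0.3],
        [0.0, 0.0, 0.0, 1.0],
    ]))


@pytest.fixture
def identity_matrix() -> TransitionMatrix:
    """Everyone stays in their stage; nobody dies."""
    return TransitionMatrix(np.eye(4))


@pytest.fixture
def all_mild() -> StageDistribution:
    return StageDistribution(np.array([1.0, 0.0, 0.0]))


@pytest.fixture
def flat_prevalence() -> PrevalenceCurve:
    return PrevalenceCurve(np.full(N_AGES, 0.05))
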