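import numpy as np
import pytest

from cwchord import (
    EyeBiometry,
    EyeModel,
    IncidentAngle,
    PopulationSpec,
    run_monte_carlo,
    sample_incident_angles,
    synthesize_population,
)

# Seeds for the shared Monte-Carlo runs, fixed once.
POPULATION_SEED = 101
ANGLE_SEED = 102


@pytest.fixture(scope="session")
def mean_eye() -> EyeBiometry:
    """Cohort-mean biometry of a large anterior-segment OCT population."""
    return EyeBiometry(
        laterality="left",
        Ra=7.76, Qa=-0.22, Rp=6.56, Qp=-0.11,
        CCT=0.55, ACD=3.36, Pup=3.24, Pup_X=-0.30, Pup_Y=-0.10,
    )


@pytest.fixture(scope="session")
def mean_model(mean_eye) -> EyeModel:
    return EyeModel.from_biometry(mean_eye)


@pytest.fixture(scope="session")
def mean_angle() -> IncidentAngle:
    return IncidentAngle(-5.03, 0.01)


@pytest.fixture(scope="session")
def centred_model() -> EyeModel:
    """Rotationally symmetric eye (centred pupil) for symmetry checks."""
    eye = EyeBiometry("left", 7.76, -0.22, 6.56, -0.11, 0.55, 3.36, 3.24, 0.0, 0.0)
    return EyeModel.from_biometry(eye)


@pytest.fixture(scope="session")
def mc_run():
    """Shared 2000-eye Monte-Carlo raytracing run (synthetic population)."""
    population = synthesize_population(PopulationSpec(n=2000, seed=POPULATION_SEED))
    angles = sample_incident_angles(2000, seed=ANGLE_SEED)
    results = run_monte_carlo(population, angles)
    assert (results["error"] == "").all()
    return results


@pytest.fixture(scope="session")
def small_population():
    """Twenty random eyes for solver-oracle comparisons."""
    population = synthesize_population(PopulationSpec(n=20, seed=POPULATION_SEED + 1))
    angles = sample_incident_angles(20, seed=ANGLE_SEED + 1)
    return population, angles


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
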