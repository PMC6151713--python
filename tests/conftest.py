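"""Shared fixtures: reference parameter sets and small synthetic studies."""

import numpy as np
import pytest

from s1popk import reference
from s1popk.datagen import PopulationModel, ResidualErrorModel, StudyDesign, simulate_study

ANALYTES = ("tegafur", "5fu", "gimeracil")


def noise_free_residuals() -> dict:
    """Residual models whose perturbation underflows to exactly zero."""
    return {a: ResidualErrorModel(additive=0.0, proportional=1e-300) for a in ANALYTES}


@pytest.fixture(scope="session")
def control_params():
    return reference.CONTROL_PARAMS


@pytest.fixture(scope="session")
def pretreated_params():
    return reference.PRETREATED_PARAMS


@pytest.fixture(scope="session")
def reference_population() -> PopulationModel:
    return PopulationModel.from_reference()


@pytest.fixture(scope="session")
def small_study(reference_population):
    """2 x 5 rats at the reference population values, fixed seed."""
    design = StudyDesign(n_per_group=5, seed=42)
    return simulate_study(reference_population, design)


@pytest.fixture(scope="session")
def deterministic_study():
    """Zero BSV, zero residual error: every subject equals the typical profile."""
    pop = PopulationModel.from_reference(omega2={}, residual=noise_free_residuals())
    return simulate_study(pop, StudyDesign(n_per_group=3, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
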