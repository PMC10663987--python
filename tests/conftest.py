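import numpy as np
import pytest
from hypothesis import settings

from dosecurve.simulate import SimulationSpec, simulate_experiment

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sigmoid_sim():
    """One simulated 20-gene experiment with mixed curve families (8 doses)."""
    spec = SimulationSpec(n_genes=20, seed=42, frac_null=0.2, frac_hook=0.1)
    return simulate_experiment(spec)


@pytest.fixture(scope="session")
def sigmoid_experiment(sigmoid_sim):
    return sigmoid_sim.experiment


@pytest.fixture(scope="session")
def design8(sigmoid_experiment):
    return sigmoid_experiment.design()


@pytest.fixture(scope="session")
def few_dose_sim():
    """A 3-dose experiment that routes to the robust ANOVA path."""
    spec = SimulationSpec(n_genes=10, seed=7, n_doses=3, frac_null=0.5,
                          frac_hook=0.0)
    return simulate_experiment(spec)


def well_conditioned_spec(seed, **kw):
    """Sigmoid benchmark family: canonical Hill slope near 1, strong effect."""
    from dosecurve.benchmarks import well_conditioned_sigmoid_spec

    return well_conditioned_sigmoid_spec(seed, **kw)
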