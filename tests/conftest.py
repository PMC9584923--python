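import numpy as np
import pytest

from ppv.model import train_nested_cv
from ppv.pipeline import design_from_observations
from ppv.simulate import SimulationConfig, generate_proteome, simulate_peptidome


@pytest.fixture(scope="session")
def default_run():
    """The default synthetic preset at seed 1, featurized and trained once."""
    config = SimulationConfig(seed=1)
    proteome, truth = generate_proteome(config)
    observations = simulate_peptidome(proteome, truth, config)
    design = design_from_observations(proteome, observations, truth.to_annotations())
    bundle = train_nested_cv(design, seed=1)
    return {
        "config": config,
        "proteome": proteome,
        "truth": truth,
        "observations": observations,
        "design": design,
        "bundle": bundle,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
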