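import warnings

import numpy as np
import pytest

from trostar.model import ModelConfig, build_design, fit_star
from trostar.simulate import SimulationConfig, simulate_county


@pytest.fixture(scope="session")
def small_county():
    """A 12-school county, small enough for fast fits."""
    return simulate_county(
        SimulationConfig(n_schools=12, n_students_per_school=(40, 60), seed=42)
    )


@pytest.fixture(scope="session")
def small_fit(small_county):
    """A short but usable MCMC run on the small county."""
    cfg = ModelConfig(n_iter=600, n_burn=200, seed=7)
    design = build_design(small_county.students, small_county.schools, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit_star(design, small_county.graph, cfg)
    return design, draws


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
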