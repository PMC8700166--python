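import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from gfrkit.synthetic_cohort import (GeneratorConfig, generate_cohort,
                                     generate_equation_cohort)


@pytest.fixture(scope="session")
def cohort400():
    """Marginal-emulating synthetic cohort, n=400."""
    return generate_cohort(GeneratorConfig(n=400, seed=11))


@pytest.fixture(scope="session")
def equation_cohort():
    """Cohort whose mGFR is generated from the 4-branch piecewise equation."""
    return generate_equation_cohort(2000, seed=3, sigma_log=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_valid_inputs(rng, n):
    """Random valid marker/demographic draws spanning the clinical range."""
    return {
        "age": rng.uniform(18, 90, n),
        "female": rng.random(n) < 0.5,
        "cys": np.exp(rng.normal(np.log(1.1), 0.5, n)),
        "cre_umol": np.exp(rng.normal(np.log(90), 0.55, n)),
        "val": np.exp(rng.normal(np.log(230), 0.25, n)),
        "myo": np.exp(rng.normal(np.log(40), 0.5, n)),
        "black": rng.random(n) < 0.1,
    }
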