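import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import confdelta as cd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    params = cd.GeneratorParams(
        n_proteins=6, n_mutations_per_protein=5, length_range=(40, 80), seed=42
    )
    return cd.generate_cohort(params)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    """The same cohort written to disk in score-array format."""
    outdir = tmp_path_factory.mktemp("cohort")
    cd.write_cohort(small_cohort, outdir, model_format="json")
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
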