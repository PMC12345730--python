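import numpy as np
import pytest

from cestdwi.phantom import PhantomSpec, SaturationSchedule
from cestdwi.pipeline import RunConfig, run_pipeline

STUDY_SEED = 7


@pytest.fixture(scope="session")
def schedule() -> SaturationSchedule:
    return SaturationSchedule()


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-study pipeline run (2 groups x 3 days x 6 animals),
    shared across integration and acceptance tests."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(phantom=PhantomSpec(seed=STUDY_SEED), make_plots=False)
    return run_pipeline(cfg, out)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
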