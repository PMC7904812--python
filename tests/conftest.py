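import numpy as np
import pytest

import carbonprospect as cp


@pytest.fixture(scope="session")
def small_world() -> cp.SynthWorld:
    """A 60x60 world for cheap per-test pipeline runs."""
    return cp.generate_world(cp.SynthConfig(n_rows=60, n_cols=60, seed=7))


@pytest.fixture(scope="session")
def world200() -> cp.SynthWorld:
    """The standard 200x200 study world."""
    return cp.generate_world(cp.SynthConfig(seed=11))


@pytest.fixture(scope="session")
def result200(world200) -> cp.PipelineResult:
    return cp.run_pipeline(world200, with_sweep=True)


@pytest.fixture(scope="session")
def small_result(small_world) -> cp.PipelineResult:
    return cp.run_pipeline(small_world)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
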