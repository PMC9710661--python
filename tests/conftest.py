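import numpy as np
import pytest

from denvar.cli import make_fixtures
from denvar.simulation_study import SimulationConfig, simulate_beta_cohort


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Bundled toy datasets, generated deterministically."""
    outdir = tmp_path_factory.mktemp("fixtures")
    make_fixtures(outdir, seed=7)
    return outdir


@pytest.fixture(scope="session")
def small_cohort():
    """A well-separated two-group Beta cohort: 12+8 subjects, 150 cells each."""
    cfg = SimulationConfig(
        design="beta-shift-A", N1=12, N2=8, n=150, l=200, reps=1, seed=99
    )
    gen = np.random.Generator(np.random.PCG64(2024))
    samples, truth = simulate_beta_cohort(cfg, gen)
    return samples, truth
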