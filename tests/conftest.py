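import numpy as np
import pytest

import embvsel as e


@pytest.fixture(scope="session")
def standard_map():
    """2,000 cM genome, 20 chromosomes, 1,000 equidistant loci."""
    return e.GeneticMap.equidistant(20, 2000.0, 1000)


@pytest.fixture(scope="session")
def small_map():
    """4 chromosomes x 100 cM with 40 loci; desk-scale unit-test genome."""
    return e.GeneticMap.equidistant(4, 400.0, 40)


@pytest.fixture(scope="session")
def reduced_base(standard_map):
    """Desk-scale base population (150 individuals, 300+15+3 generations)."""
    rng = np.random.default_rng(20180206)
    return e.reduced_base_population(standard_map, rng)


@pytest.fixture(scope="session")
def trend_experiment(reduced_base):
    """Paired 50-cycle programs of the standard scenario, 40 replicates.

    Shared by the trend-reproduction checks: per-replicate trajectories and
    their per-cycle aggregates for gebv/embv/ohv/wgebv from identical
    founders and architectures.
    """
    configs = [e.ProgramConfig(criterion=c, cycles=50)
               for c in ("gebv", "embv", "ohv", "wgebv")]
    traj = e.run_experiment(configs, reduced_base, n_replicates=40, seed=4)
    return traj, e.aggregate_trajectories(traj)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
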