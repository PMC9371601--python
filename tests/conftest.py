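import numpy as np
import pytest

from regentc import core
from regentc.core import SampleMeta, TimeCourseMatrix
from regentc.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic experiment shared across tests (seed 0)."""
    config = SimulationConfig(seed=0)
    matrix, spikeins, truth = simulate_experiment(config)
    return config, matrix, spikeins, truth


@pytest.fixture(scope="session")
def logged_sim(default_sim):
    config, matrix, spikeins, truth = default_sim
    logged = core.log_transform(core.normalize(matrix, "cpm"))
    return config, logged, spikeins, truth


@pytest.fixture(scope="session")
def averaged_sim(logged_sim):
    config, logged, spikeins, truth = logged_sim
    return config, core.average_replicates(logged), spikeins, truth


def make_matrix(values, times=None, paradigm="sucrose", scale="raw_counts", replicates=None):
    """Small matrix builder for unit tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if times is None:
        times = list(range(0, 30 * n_samples, 30))
    if replicates is None:
        replicates = [1] * n_samples
    samples = [
        SampleMeta(
            sample_id=f"s{j}", paradigm=paradigm, time_min=int(times[j]), replicate=replicates[j]
        )
        for j in range(n_samples)
    ]
    return TimeCourseMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        samples=samples,
        values=values,
        scale=scale,
    )
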