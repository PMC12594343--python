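import numpy as np
import pytest

from branchgas.integration import MultiomeIntegrator
from branchgas.synthetic import simulate_bifurcation


@pytest.fixture(scope="session")
def sim7():
    """The reference simulation used across the suite."""
    return simulate_bifurcation(300, 200, 20, 0.3, seed=7)


@pytest.fixture(scope="session")
def gim7(sim7):
    return MultiomeIntegrator().fit_transform(
        sim7.rna_counts, sim7.peak_counts, sim7.peak_bed,
        sim7.gene_annotation, cell_ids=sim7.cell_ids, gene_ids=sim7.gene_ids)


@pytest.fixture(scope="session")
def small_sim():
    """A fast, small simulation for shape/contract tests."""
    return simulate_bifurcation(80, 40, 5, 0.3, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
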