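import numpy as np
import pytest

from stmosaic.synthetic_data import SimulationSpec, ground_truth, simulate


@pytest.fixture(scope="session")
def tiny_sim():
    """Shared small 2-slice simulation with clear domains and a batch effect."""
    spec = SimulationSpec(
        n_slices=2,
        spots_per_slice=150,
        n_genes=120,
        n_domains=4,
        de_strength=2.0,
        batch_strength=0.5,
        seed=42,
    )
    sim = simulate(spec)
    domains, batches = ground_truth(spec, sim)
    return spec, sim, domains, batches


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
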