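import numpy as np
import pytest

from umirep import bundled_reference
from umirep.simulate import SimConfig, simulate_reads, simulate_repertoire


@pytest.fixture(scope="session")
def ref():
    return bundled_reference()


@pytest.fixture(scope="session")
def zero_error_run(ref):
    """Small noiseless run with distinct barcodes: 50 clones, 300 molecules."""
    cfg = SimConfig(n_clones=50, n_molecules=300, reads_per_molecule_mean=5.0,
                    sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
                    unique_barcodes=True, seed=11)
    clones = simulate_repertoire(cfg, ref)
    reads, molecules = simulate_reads(clones, cfg, ref)
    return cfg, clones, reads, molecules


@pytest.fixture(scope="session")
def noisy_run(ref):
    """Small run at the default indel-dominant error rates."""
    cfg = SimConfig(n_clones=100, n_molecules=1000, seed=5)
    clones = simulate_repertoire(cfg, ref)
    reads, molecules = simulate_reads(clones, cfg, ref)
    return cfg, clones, reads, molecules


@pytest.fixture
def rng():
    return np.random.default_rng(0)
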