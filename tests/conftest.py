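import numpy as np
import pytest

import ensemref as er


@pytest.fixture(scope="session")
def toy_system():
    return er.build_toy_chain(10, seed=1)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Noise-free fixture set: reference ensemble, shifts, NOE intervals."""
    return er.make_synthetic_dataset(n_beads=10, n_frames=20,
                                     noise_level=0.0, seed=3)


@pytest.fixture(scope="session")
def small_ensemble():
    """A 15-frame unrestrained toy ensemble for geometry/PCA tests."""
    system = er.build_toy_chain(8, seed=4)
    return er.sample_unrestrained(system, n_frames=15, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def refined_m4(synthetic_dataset):
    """A 4-replica restrained SA refinement against the noise-free fixture,
    started from a different chain conformation than the reference."""
    _, shifts, noes = synthetic_dataset
    system = er.build_toy_chain(10, seed=21)
    fn = er.make_restraint_function(system, shift_table=shifts, noe_set=noes)
    run = er.run_replica_sa(system, fn, er.default_schedule(), M=4,
                            n_cycles=30, seed=7, discard_cycles=15)
    return system, run
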