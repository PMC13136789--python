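import numpy as np
import pytest

from stochassembly import synth


@pytest.fixture(scope="session")
def bistable_experiment():
    """24-replicate synthetic experiment with the default bistable pools."""
    pools = synth.default_pools()
    design = synth.default_design(n_replicates=24, seed=11)
    params = [synth.default_dynamics(p) for p in pools]
    return synth.generate_dataset(pools, design, params)


@pytest.fixture()
def two_taxon_pool():
    return synth.SpeciesPool(["a", "b"], np.array([0.5, 0.5]), 1_000_000)


@pytest.fixture()
def small_table():
    """Tiny deterministic table: 1 source, 2 dilutions, 4 replicates, 2 days."""
    pool = synth.SpeciesPool([f"t{i}" for i in range(4)],
                             np.array([0.4, 0.3, 0.2, 0.1]), 100_000)
    design = synth.ExperimentDesign(n_sources=1, dilution_factors=(1.0, 0.01),
                                    n_replicates=4, sample_days=(2, 4), seed=5)
    params = synth.default_dynamics(pool, read_depth=1000)
    return synth.generate_dataset([pool], design, [params])
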