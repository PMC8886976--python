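import numpy as np
import pytest

from tadcnv import synthetic as syn


@pytest.fixture(scope="session")
def toy_genome():
    return syn.generate_genome(syn.ToyGenomeConfig(seed=11))


@pytest.fixture(scope="session")
def blocky_genome():
    return syn.generate_genome(syn.ToyGenomeConfig(seed=12, gc_profile="blocky"))


@pytest.fixture(scope="session")
def environments(toy_genome):
    return toy_genome.environments()


@pytest.fixture(scope="session")
def labeled_cnvs(toy_genome):
    effect = syn.CnvEffectModel(n_pathogenic=150, n_nonpathogenic=150, seed=21)
    return syn.generate_cnvs(toy_genome, effect)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
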