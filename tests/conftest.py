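import numpy as np
import pytest

import fluxgraphs as fg


@pytest.fixture(scope="session")
def ecoli():
    """E. coli core model (72 metabolites, 95 reactions)."""
    return fg.load_e_coli_core()


@pytest.fixture()
def chain():
    """Two-reaction import/export chain over one metabolite."""
    return fg.chain_model()


@pytest.fixture()
def toy():
    return fg.toy_network()


def small_random_models(n_models=8, max_n=12, max_m=12, base_seed=100):
    """Deterministic battery of small random models for oracle tests."""
    rng = np.random.default_rng(base_seed)
    models = []
    for k in range(n_models):
        spec = fg.FixtureSpec(
            n_metabolites=int(rng.integers(3, max_n + 1)),
            n_reactions=int(rng.integers(4, max_m + 1)),
            fraction_reversible=float(rng.uniform(0.0, 0.8)),
            density=float(rng.uniform(0.15, 0.5)),
            seed=base_seed + k,
        )
        models.append(fg.random_model(spec))
    return models
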