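import numpy as np
import pytest

from agglearn import learner, synthdata
from agglearn.chemspace import make_record


@pytest.fixture(scope="session")
def tiny_library():
    """Ten handcrafted molecules: a benzene-derivative series plus outliers."""
    smiles = {
        "m01": "c1ccccc1",
        "m02": "Cc1ccccc1",
        "m03": "CCc1ccccc1",
        "m04": "Oc1ccccc1",
        "m05": "Nc1ccccc1",
        "m06": "c1ccncc1",
        "m07": "C1CCCCC1",
        "m08": "CCO",
        "m09": "CC(=O)Nc1ccc(O)cc1",
        "m10": "OC(=O)c1ccccc1",
    }
    return [make_record(k, v) for k, v in sorted(smiles.items())]


@pytest.fixture(scope="session")
def small_library():
    """150 molecules from the combinatorial generator (seeded)."""
    return synthdata.generate_library(150, seed=7)


@pytest.fixture(scope="session")
def default_landscape_library():
    """The default study conditions: 2,000-molecule library with hidden potencies."""
    lib = synthdata.generate_library(2000, seed=0)
    return synthdata.landscape_potency(lib, synthdata.LandscapeSpec(seed=0))


@pytest.fixture(scope="session")
def default_embedding(default_landscape_library):
    return learner.embed_library(default_landscape_library.molecules)


@pytest.fixture(scope="session")
def campaign_comparison(default_landscape_library, default_embedding):
    """ML vs random campaigns over 10 seeds at the default study conditions.

    Expensive (several minutes); shared between the active-learning tests.
    Returns (ml_rates, random_rates) as (10, 3) arrays of percentages.
    """
    lib = default_landscape_library
    emb = default_embedding
    oracle = synthdata.campaign_oracle(lib)
    ml, rnd = [], []
    for seed in range(10):
        init = learner.make_initial_training_set(emb, oracle, 161, seed=seed)
        ml.append(
            learner.run_campaign(
                init, emb, oracle, n_iterations=3, batch_size=60, seed=seed,
                strategy="ml",
            ).optimization_rates
        )
        rnd.append(
            learner.run_campaign(
                init, emb, oracle, n_iterations=3, batch_size=60, seed=seed,
                strategy="random",
            ).optimization_rates
        )
    return np.array(ml), np.array(rnd)
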