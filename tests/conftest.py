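import numpy as np
import pytest

from lpbench.potts_inference import PottsModel, exact_log_probabilities, gauge_transform
from lpbench.sequence_sampler import AlignmentSet


@pytest.fixture(scope="session")
def cube3_library():
    """The full symmetry-reduced 3x3x3 enumeration (shared across tests)."""
    from lpbench.workbench import _full_enumeration

    return _full_enumeration((3, 3, 3), False)


@pytest.fixture(scope="session")
def cube2_system():
    from lpbench.workbench import make_toy_system

    return make_toy_system("cube2", q=2, seed=0)


def _random_model(L, q, seed, h_scale=0.3, j_scale=0.25):
    rng = np.random.default_rng(seed)
    h = rng.normal(0, h_scale, (L, q))
    J = np.zeros((L, L, q, q))
    for i in range(L):
        for j in range(i + 1, L):
            block = rng.normal(0, j_scale, (q, q))
            J[i, j] = block
            J[j, i] = block.T
    return PottsModel(h, J, meta={"alphabet": "ABCDEFGH"[:q]})


@pytest.fixture(scope="session")
def small_potts_truth():
    """A moderately coupled L=6, q=3 Potts model with its exact distribution
    (the parameter-recovery and entropy oracle)."""
    model = _random_model(6, 3, seed=42)
    states, logp = exact_log_probabilities(model)
    return {
        "model": model,
        "model_zs": gauge_transform(model, "zero-sum"),
        "states": states,
        "p": np.exp(logp),
    }


@pytest.fixture(scope="session")
def exact_sampler():
    """Draw alignments exactly from an enumerated model distribution."""

    def draw(truth, M, seed, alphabet="ABC"):
        idx = np.random.default_rng(seed).choice(len(truth["p"]), size=M, p=truth["p"])
        return AlignmentSet(truth["states"][idx], alphabet)

    return draw


@pytest.fixture
def random_model_factory():
    return _random_model
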