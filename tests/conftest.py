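import numpy as np
import pytest

from rhizomod.network_model import MetabolicModel, Reaction
from rhizomod.optimization import ObjectiveFunction
from rhizomod.synthetic import SyntheticSpec, generate_toy_model


@pytest.fixture
def chain_model():
    """EX -> a -> b with a 10-unit uptake bottleneck."""
    reactions = [
        Reaction(id="EX_a", stoichiometry={"a[c]": 1.0}, lower_bound=0.0,
                 upper_bound=10.0),
        Reaction(id="R_ab", stoichiometry={"a[c]": -1.0, "b[c]": 1.0},
                 genes=frozenset({"g1"}), enzymes=frozenset({"e1"}),
                 pathways=frozenset({"chain"})),
    ]
    return MetabolicModel.from_reactions(reactions)


@pytest.fixture
def chain_of():
    return ObjectiveFunction({"b[c]": 1.0})


@pytest.fixture
def clique_block_spec():
    """Three full-clique modules of five metabolites, one bridge per
    consecutive pair — the well-separated planted-block regime."""
    return SyntheticSpec(n_modules=3, mets_per_module=5, intra_reactions=10,
                         n_bridges=2, n_exchange=2, seed=11)


@pytest.fixture
def clique_block_model(clique_block_spec):
    return generate_toy_model(clique_block_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
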