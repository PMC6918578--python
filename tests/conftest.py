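import numpy as np
import pytest

from methylopath.model import MetabolicModel, Metabolite, ModelReaction
from methylopath.synthetic import CoreModelParams, generate_core_model
from methylopath.thermo import reference_table


@pytest.fixture(scope="session")
def core_model():
    return generate_core_model(CoreModelParams())


@pytest.fixture(scope="session")
def thermo_table():
    return reference_table()


def make_toy_model(reactions, metabolites, objective=None, **kwargs):
    """Build a small model from (id, {met: coeff}, lb, ub) tuples."""
    mets = [
        Metabolite(id=mid, carbon_atoms=carbon)
        for mid, carbon in metabolites.items()
    ]
    rxns = [
        ModelReaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub)
        for rid, stoich, lb, ub in reactions
    ]
    return MetabolicModel(
        metabolites=mets, reactions=rxns, objective=objective, **kwargs
    )


@pytest.fixture
def linear_chain_model():
    """uptake -> A -> sink, 1:1; optimum equals the uptake limit."""
    return make_toy_model(
        reactions=[
            ("EX_in", {"A": 1.0}, 0.0, 10.0),
            ("GROW", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            ("EX_out", {"B": -1.0}, 0.0, 1000.0),
        ],
        metabolites={"A": 1, "B": 1},
        objective={"GROW": 1.0},
    )


@pytest.fixture
def parallel_paths_model():
    """Two redundant routes from A to B carrying a total flux of 10."""
    return make_toy_model(
        reactions=[
            ("EX_in", {"A": 1.0}, 0.0, 10.0),
            ("P1", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            ("P2", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
            ("EX_out", {"B": -1.0}, 0.0, 1000.0),
        ],
        metabolites={"A": 1, "B": 1},
        objective={"EX_out": 1.0},
    )
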