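import numpy as np
import pandas as pd
import pytest

from fluxscreen.gpmm_bounds import apply_medium, compute_vmax_bounds
from fluxscreen.model_io import MetabolicModel, Metabolite, Reaction
from fluxscreen.synthetic_data import (
    default_kinetome,
    default_medium,
    make_toy_network,
    simulate_expression,
)


@pytest.fixture
def chain_model():
    """EX_A -> R1 -> EX_B with uptake 5 and an internal bottleneck of 3."""
    mets = [
        Metabolite(id="A[e]", name="A", compartment="e"),
        Metabolite(id="B[e]", name="B", compartment="e"),
    ]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A[e]": -1.0}, lb=-5.0, ub=1000.0),
        Reaction(id="R1", stoichiometry={"A[e]": -1.0, "B[e]": 1.0}, lb=0.0, ub=3.0),
        Reaction(id="EX_B", stoichiometry={"B[e]": -1.0}, lb=0.0, ub=1000.0),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns).validate()


@pytest.fixture
def branch_model():
    """8-reaction model with a shared intermediate and a reversible consumer."""
    mets = [
        Metabolite(id=m, name=m, compartment=m[-2])
        for m in ["A[e]", "A[c]", "B[c]", "C[e]", "D[e]"]
    ]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A[e]": -1.0}, lb=-5.0, ub=1000.0),
        Reaction(id="T", stoichiometry={"A[e]": -1.0, "A[c]": 1.0}, lb=0.0, ub=1000.0),
        Reaction(id="R1", stoichiometry={"A[c]": -1.0, "B[c]": 1.0}, lb=0.0, ub=4.0),
        Reaction(id="R2", stoichiometry={"B[c]": -1.0, "C[e]": 1.0}, lb=0.0, ub=1000.0),
        Reaction(id="R3", stoichiometry={"B[c]": -1.0, "D[e]": 1.0}, lb=-1000.0, ub=1000.0),
        Reaction(id="R4", stoichiometry={"A[c]": -1.0, "D[e]": 1.0}, lb=0.0, ub=1000.0),
        Reaction(id="EX_C", stoichiometry={"C[e]": -1.0}, lb=0.0, ub=1000.0),
        Reaction(id="EX_D", stoichiometry={"D[e]": -1.0}, lb=-2.0, ub=1000.0),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns).validate()


@pytest.fixture(scope="session")
def toy_network():
    return make_toy_network(8, 4, seed=1)


@pytest.fixture(scope="session")
def toy_study(toy_network):
    """Expression, kinetome, medium and per-sample bounded sets for the toy net."""
    model, truth = toy_network
    expr = simulate_expression(model, truth, 10, 10, seed=2)
    kinetome = default_kinetome(model)
    medium = default_medium(model)
    bounded = [
        apply_medium(bs, model, medium)
        for bs in compute_vmax_bounds(model, expr, kinetome)
    ]
    return {
        "model": model,
        "truth": truth,
        "expr": expr,
        "kinetome": kinetome,
        "medium": medium,
        "bounded": bounded,
    }


@pytest.fixture
def null_diff_table():
    """A fully null DiffFluxTable with symmetric significant calls."""
    rng = np.random.default_rng(5)
    n = 400
    sig = rng.random(n) < 0.3
    sign = np.where(sig, rng.choice([-1, 1], size=n), 0)
    return pd.DataFrame(
        {
            "log2fc": sign * 0.5,
            "p": np.where(sig, 0.01, 0.5),
            "significant": sig,
            "sign": sign,
        },
        index=[f"r{i}" for i in range(n)],
    )
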