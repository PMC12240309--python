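import pytest

from colongem import (
    MetabolicModel,
    Metabolite,
    Reaction,
    SyntheticSpec,
    make_expression,
    make_task_suite,
    make_toy_template,
)


def linear_chain_model() -> MetabolicModel:
    """A 3-step chain: uptake of A (bound 10) -> conversion -> biomass drain.

    The biomass optimum is the uptake bottleneck, 10.
    """
    m = MetabolicModel(id="chain")
    for mid in ["A[e]", "A[c]", "B[c]"]:
        m.add_metabolite(Metabolite(mid))
    m.add_reaction(Reaction("EX_A_e", stoichiometry={"A[e]": -1}, lower_bound=-10,
                            upper_bound=1000))
    m.add_reaction(Reaction("At", stoichiometry={"A[e]": -1, "A[c]": 1},
                            upper_bound=1000, gpr="g_t"))
    m.add_reaction(Reaction("AB", stoichiometry={"A[c]": -1, "B[c]": 1},
                            upper_bound=1000, gpr="g1"))
    m.add_reaction(Reaction("BIOMASS", stoichiometry={"B[c]": -1},
                            upper_bound=1000, kind="demand"))
    m.objective = {"BIOMASS": 1.0}
    return m


def parallel_branch_model() -> MetabolicModel:
    """Two parallel A->B branches behind one uptake (bound 10).

    At the optimum the flux splits freely between the branches.
    """
    m = MetabolicModel(id="parallel")
    for mid in ["A[e]", "A[c]", "B[c]"]:
        m.add_metabolite(Metabolite(mid))
    m.add_reaction(Reaction("EX_A_e", stoichiometry={"A[e]": -1}, lower_bound=-10,
                            upper_bound=1000))
    m.add_reaction(Reaction("At", stoichiometry={"A[e]": -1, "A[c]": 1},
                            upper_bound=1000))
    m.add_reaction(Reaction("AB1", stoichiometry={"A[c]": -1, "B[c]": 1},
                            upper_bound=1000, gpr="g_hi"))
    m.add_reaction(Reaction("AB2", stoichiometry={"A[c]": -1, "B[c]": 1},
                            upper_bound=1000, gpr="g_lo"))
    m.add_reaction(Reaction("BIOMASS", stoichiometry={"B[c]": -1},
                            upper_bound=1000, kind="demand"))
    m.objective = {"BIOMASS": 1.0}
    return m


@pytest.fixture
def chain_model():
    return linear_chain_model()


@pytest.fixture
def branch_model():
    return parallel_branch_model()


@pytest.fixture(scope="session")
def template():
    return make_toy_template(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def task_suite(template):
    return make_task_suite(template)


@pytest.fixture(scope="session")
def expression(template):
    return make_expression(SyntheticSpec(seed=0), template)


@pytest.fixture(scope="session")
def study(template, expression):
    from colongem import build_context_models

    return build_context_models(template, expression)
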