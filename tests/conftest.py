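"""Shared fixtures: reference model, prepared model, toy networks, oracle."""

from __future__ import annotations

import pytest

from fruitfba import (
    AnalysisConfig,
    MetabolicModel,
    RipeningConfig,
    add_rqs_objective,
    apply_ripening_constraints,
    build_reference_model,
    parse_reaction_table,
)

# Three toy networks (≤ 12 reactions each) with known FBA optima, written
# in the table dialect so they exercise the parser as well.

TOY_CHAIN = """\
id\tequation\tgpr\tsubsystem\tlb\tub
POOL_A\t --> a_c\t\tPools\t0\t5
R1\ta_c --> b_c\tg1\tPath
SINK_B\tb_c --> \t\tPools
"""

TOY_BRANCH = """\
id\tequation\tgpr\tsubsystem\tlb\tub
POOL_A\t --> a_c\t\tPools\t0\t4
R1\ta_c --> b_c\tg1\tPath
R2A\ta_c --> c_c\tg2\tPath
R2B\tc_c --> b_c\tg3\tPath
SINK_B\tb_c --> \t\tPools
"""

TOY_COFACTOR = """\
id\tequation\tgpr\tsubsystem\tlb\tub
POOL_S\t --> s_c\t\tPools\t0\t3
R1\ts_c + n_c --> p_c + m_c\tg1 and g2\tPath
R2\tm_c <=> n_c\tg3\tPath
SINK_P\tp_c --> \t\tPools
"""

#: (table, objective reaction, expected optimum)
TOY_CASES = [
    (TOY_CHAIN, "SINK_B", 5.0),
    (TOY_BRANCH, "SINK_B", 4.0),
    (TOY_COFACTOR, "SINK_P", 3.0),
]


@pytest.fixture(scope="session")
def reference_model() -> MetabolicModel:
    return build_reference_model()


@pytest.fixture(scope="session")
def prepared_model(reference_model: MetabolicModel) -> MetabolicModel:
    """Reference model with RQS appended and default ripening constraints."""
    return apply_ripening_constraints(add_rqs_objective(reference_model), RipeningConfig())


@pytest.fixture(scope="session")
def toy_models():
    return [(parse_reaction_table(text, name=f"toy{i}"), objective, optimum)
            for i, (text, objective, optimum) in enumerate(TOY_CASES)]


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (tests-only oracle bridge)."""
    import cobra

    cm = cobra.Model(model.name)
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment)
            for m in model.metabolites}
    reactions = []
    for reaction in model.reactions:
        cr = cobra.Reaction(reaction.id)
        cr.lower_bound = reaction.lower_bound
        cr.upper_bound = reaction.upper_bound
        reactions.append(cr)
    cm.add_reactions(reactions)
    for reaction in model.reactions:
        cm.reactions.get_by_id(reaction.id).add_metabolites(
            {mets[mid]: coef for mid, coef in reaction.stoichiometry.items()}
        )
    return cm


def cobra_fba_optimum(model: MetabolicModel, objective_id: str,
                      direction: str = "max") -> float:
    """FBA optimum from the independent constraint-based library (GLPK)."""
    cm = to_cobra(model)
    cm.solver = "glpk"
    cm.objective = objective_id
    cm.objective_direction = direction
    solution = cm.optimize()
    assert solution.status == "optimal", solution.status
    return float(solution.objective_value)
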