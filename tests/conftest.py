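"""Shared fixtures: small hand-built models and session-scoped simulations.

The expensive artifacts (the calibrated default community) are computed once
per session and shared by the acceptance tests.
"""

from __future__ import annotations

import pytest

from commfba.metabolic_core import (
    Compartment,
    Metabolite,
    Reaction,
    StoichiometricModel,
)


def chain_model(
    species_id: str = "toy",
    substrate: str = "glc",
    yield_gdw_per_mmol: float = 0.1,
    uptake_lb: float = -10.0,
) -> StoichiometricModel:
    """Minimal uptake -> conversion -> biomass chain.

    With uptake bound ``-10`` and yield 0.1 gDW/mmol the optimal growth rate
    is forced to 1.0 1/h.
    """
    e, c = f"{substrate}_e", f"{substrate}_c"
    mets = [
        Metabolite(e, compartment=Compartment.EXTRACELLULAR),
        Metabolite(c, compartment=Compartment.INTRACELLULAR),
    ]
    rxns = [
        Reaction(f"EX_{substrate}", {e: -1.0}, uptake_lb, 1000.0, is_exchange=True),
        Reaction(f"T_{substrate}", {e: -1.0, c: 1.0}, 0.0, 1000.0),
        Reaction(
            "BIOMASS", {c: -1.0 / yield_gdw_per_mmol}, 0.0, 1000.0, is_biomass=True
        ),
    ]
    return StoichiometricModel(species_id, mets, rxns)


def parallel_pathway_model() -> StoichiometricModel:
    """Two redundant routes of equal yield: a short one and a long one.

    Parsimonious FBA must route all flux through the short pathway.
    """
    mets = [
        Metabolite("s_e", compartment=Compartment.EXTRACELLULAR),
        Metabolite("s_c", compartment=Compartment.INTRACELLULAR),
        Metabolite("mid_c", compartment=Compartment.INTRACELLULAR),
        Metabolite("p_c", compartment=Compartment.INTRACELLULAR),
    ]
    rxns = [
        Reaction("EX_s", {"s_e": -1.0}, -10.0, 1000.0, is_exchange=True),
        Reaction("T_s", {"s_e": -1.0, "s_c": 1.0}, 0.0, 1000.0),
        # short route: one step
        Reaction("SHORT", {"s_c": -1.0, "p_c": 1.0}, 0.0, 1000.0),
        # long route: two steps through an intermediate
        Reaction("LONG1", {"s_c": -1.0, "mid_c": 1.0}, 0.0, 1000.0),
        Reaction("LONG2", {"mid_c": -1.0, "p_c": 1.0}, 0.0, 1000.0),
        Reaction("BIOMASS", {"p_c": -10.0}, 0.0, 1000.0, is_biomass=True),
    ]
    return StoichiometricModel("parallel", mets, rxns)


@pytest.fixture
def toy_chain():
    return chain_model()


@pytest.fixture(scope="session")
def three_member_community():
    from commfba.synthetic_data import three_member_spec, make_toy_community

    spec = three_member_spec()
    configs, fresh = make_toy_community(spec)
    return spec, configs, fresh


@pytest.fixture(scope="session")
def calibrated_community():
    """The default community calibrated to the reference ratio (slow; shared)."""
    from commfba.reproduce import calibration_experiment

    return calibration_experiment()
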