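"""Model I/O and the FBA / parsimonious-FBA solvers.

The LP optimum is cross-checked against (a) brute-force vertex enumeration of
the feasible flux polytope on small random networks and (b) cobrapy on the
toy chain model.
"""

from __future__ import annotations

import itertools
import json

import numpy as np
import pytest
from scipy.linalg import null_space

from commfba.metabolic_core import (
    Compartment,
    Metabolite,
    ModelParseError,
    ModelValidationError,
    Reaction,
    SolverStatus,
    StoichiometricModel,
    UnboundedObjectiveError,
    fba,
    model_from_dict,
    model_to_dict,
    pfba,
    read_model,
    write_model,
)

from conftest import chain_model, parallel_pathway_model


# ---------------------------------------------------------------------------
# structure and I/O
# ---------------------------------------------------------------------------


class TestModelStructure:
    def test_undeclared_metabolite_rejected(self):
        with pytest.raises(ModelValidationError, match="undeclared"):
            StoichiometricModel(
                "bad",
                [Metabolite("a_c")],
                [
                    Reaction("r", {"a_c": -1, "ghost": 1}, 0, 10),
                    Reaction("BIOMASS", {"a_c": -1}, 0, 10, is_biomass=True),
                ],
            )

    def test_exactly_one_biomass_required(self):
        mets = [Metabolite("a_c")]
        with pytest.raises(ModelValidationError, match="biomass"):
            StoichiometricModel("bad", mets, [Reaction("r", {"a_c": -1}, 0, 10)])

    def test_exchange_must_export_single_extracellular(self):
        mets = [Metabolite("a_c", compartment=Compartment.INTRACELLULAR)]
        with pytest.raises(ModelValidationError, match="exchange"):
            StoichiometricModel(
                "bad",
                mets,
                [
                    Reaction("EX_a", {"a_c": -1}, -10, 10, is_exchange=True),
                    Reaction("BIOMASS", {"a_c": -1}, 0, 10, is_biomass=True),
                ],
            )

    def test_bounds_order_enforced(self):
        with pytest.raises(ModelValidationError, match="bound"):
            Reaction("r", {"x": -1}, 5.0, -5.0)


class TestModelIO:
    def test_json_roundtrip_is_canonical(self, toy_chain, tmp_path):
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        write_model(toy_chain, p1)
        again = read_model(p1, format="json")
        write_model(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert again.species_id == toy_chain.species_id
        assert [r.id for r in again.reactions] == [r.id for r in toy_chain.reactions]

    def test_defaults_for_missing_bounds(self):
        model = model_from_dict(
            {
                "species_id": "d",
                "metabolites": [
                    {"id": "x_e", "compartment": "extracellular"},
                    {"id": "x_c", "compartment": "intracellular"},
                ],
                "reactions": [
                    {"id": "EX_x", "stoich": {"x_e": -1}, "is_exchange": True},
                    {"id": "T", "stoich": {"x_e": -1, "x_c": 1}, "reversible": False},
                    {"id": "BIOMASS", "stoich": {"x_c": -1}, "is_biomass": True, "lb": 0},
                ],
            }
        )
        assert model.reaction("EX_x").lower_bound == -1000.0
        assert model.reaction("T").lower_bound == 0.0
        assert model.reaction("T").upper_bound == 1000.0

    def test_malformed_json_names_problem(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelParseError, match="JSON"):
            read_model(path, format="json")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_model(tmp_path / "nope.json")

    def test_validation_error_propagates_from_dict(self):
        doc = {
            "species_id": "bad",
            "metabolites": [{"id": "a_c"}],
            "reactions": [
                {"id": "r", "stoich": {"ghost": 1.0}},
                {"id": "BIOMASS", "stoich": {"a_c": -1}, "is_biomass": True},
            ],
        }
        with pytest.raises(ModelValidationError):
            model_from_dict(doc)

    def test_sbml_reader_matches_json(self, toy_chain, tmp_path):
        cobra = pytest.importorskip("cobra")
        from cobra.io import write_sbml_model

        cm = cobra.Model("toy")
        e = cobra.Metabolite("glc_e", compartment="e")
        c = cobra.Metabolite("glc_c", compartment="c")
        ex = cobra.Reaction("EX_glc", lower_bound=-10, upper_bound=1000)
        ex.add_metabolites({e: -1})
        t = cobra.Reaction("T_glc", lower_bound=0, upper_bound=1000)
        t.add_metabolites({e: -1, c: 1})
        bio = cobra.Reaction("BIOMASS", lower_bound=0, upper_bound=1000)
        bio.add_metabolites({c: -10})
        cm.add_reactions([ex, t, bio])
        cm.objective = "BIOMASS"
        path = tmp_path / "toy.xml"
        write_sbml_model(cm, str(path))

        model = read_model(path, format="sbml")
        sol = fba(model)
        assert sol.status is SolverStatus.OPTIMAL
        assert sol.growth_rate == pytest.approx(1.0, rel=1e-6)


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


class TestFBA:
    def test_forced_chain_growth_rate(self, toy_chain):
        sol = fba(toy_chain)
        assert sol.status is SolverStatus.OPTIMAL
        assert sol.growth_rate == pytest.approx(1.0, abs=1e-9)

    def test_starvation_gives_zero_growth(self, toy_chain):
        sol = fba(toy_chain, {"EX_glc": (0.0, 1000.0)})
        assert sol.growth_rate == pytest.approx(0.0, abs=1e-9)

    def test_exchange_bound_override_scales_growth(self, toy_chain):
        sol = fba(toy_chain, {"EX_glc": (-5.0, 1000.0)})
        assert sol.growth_rate == pytest.approx(0.5, abs=1e-9)

    def test_unknown_exchange_rejected(self, toy_chain):
        with pytest.raises(KeyError):
            fba(toy_chain, {"BIOMASS": (0, 1)})

    def test_unbounded_objective_raises(self):
        mets = [
            Metabolite("x_e", compartment=Compartment.EXTRACELLULAR),
            Metabolite("x_c", compartment=Compartment.INTRACELLULAR),
        ]
        rxns = [
            Reaction("EX_x", {"x_e": -1}, -np.inf, 1000.0, is_exchange=True),
            Reaction("T", {"x_e": -1, "x_c": 1}, -np.inf, np.inf),
            Reaction("BIOMASS", {"x_c": -1}, 0, np.inf, is_biomass=True),
        ]
        model = StoichiometricModel("unb", mets, rxns)
        with pytest.raises(UnboundedObjectiveError, match="cap"):
            fba(model)

    def test_mass_balance_of_optimum(self, toy_chain):
        sol = fba(toy_chain)
        S = toy_chain.stoichiometric_matrix
        v = np.array([sol.fluxes[r.id] for r in toy_chain.reactions])
        assert np.max(np.abs(S @ v)) <= 1e-6

    def test_agrees_with_cobrapy(self, toy_chain):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("toy")
        e = cobra.Metabolite("glc_e", compartment="e")
        c = cobra.Metabolite("glc_c", compartment="c")
        rxns = []
        for rxn in toy_chain.reactions:
            cr = cobra.Reaction(
                rxn.id, lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound
            )
            rxns.append(cr)
        cm.add_reactions(rxns)
        lookup = {"glc_e": e, "glc_c": c}
        for rxn, cr in zip(toy_chain.reactions, rxns):
            cr.add_metabolites(
                {lookup[m]: coef for m, coef in rxn.stoichiometry.items()}
            )
        cm.objective = "BIOMASS"
        expected = cm.optimize().objective_value
        assert fba(toy_chain).growth_rate == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# vertex-enumeration oracle
# ---------------------------------------------------------------------------


def _vertex_enumeration_max(model: StoichiometricModel) -> float | None:
    """Maximum biomass flux over all vertices of {v: S v = 0, lb <= v <= ub}.

    Every vertex of the polytope in the null-space coordinates is the
    solution of d active bound constraints; enumerate all subsets.
    Returns None if the polytope is empty.
    """
    S = model.stoichiometric_matrix
    lb, ub = model.bounds_array()
    N = null_space(S)
    d = N.shape[1]
    if d == 0:
        return 0.0
    j_bio = [r.id for r in model.reactions].index(model.biomass_reaction_id)
    n = len(model.reactions)
    rows = np.vstack([N, -N])  # v_i <= ub_i ; -v_i <= -lb_i
    rhs = np.concatenate([ub, -lb])
    best = None
    for combo in itertools.combinations(range(2 * n), d):
        A = rows[list(combo)]
        if np.linalg.matrix_rank(A) < d:
            continue
        try:
            z = np.linalg.solve(A, rhs[list(combo)])
        except np.linalg.LinAlgError:
            continue
        v = N @ z
        if np.all(v <= ub + 1e-9) and np.all(v >= lb - 1e-9):
            val = v[j_bio]
            if best is None or val > best:
                best = val
    return best


def _random_network(rng: np.random.Generator) -> StoichiometricModel:
    """A random feasible network with <= 6 reactions and bounded fluxes."""
    n_int = rng.integers(1, 3)  # internal metabolites
    n_rxn = int(rng.integers(3, 7))
    mets = [Metabolite("x_e", compartment=Compartment.EXTRACELLULAR)] + [
        Metabolite(f"m{i}_c") for i in range(n_int)
    ]
    rxns = [Reaction("EX_x", {"x_e": -1}, -rng.uniform(1, 10), 1000, is_exchange=True)]
    rxns.append(Reaction("T", {"x_e": -1, "m0_c": 1}, 0, rng.uniform(5, 20)))
    for k in range(n_rxn - 3):
        src = int(rng.integers(0, n_int))
        dst = int(rng.integers(0, n_int))
        if src == dst:
            dst = (dst + 1) % n_int
        if n_int == 1:
            continue
        rxns.append(
            Reaction(
                f"R{k}",
                {f"m{src}_c": -1, f"m{dst}_c": rng.uniform(0.5, 1.5)},
                0,
                rng.uniform(5, 20),
            )
        )
    sink = int(rng.integers(0, n_int))
    rxns.append(
        Reaction(
            "BIOMASS",
            {f"m{sink}_c": -rng.uniform(1, 10)},
            0,
            1000,
            is_biomass=True,
        )
    )
    return StoichiometricModel("rand", mets, rxns)


@pytest.mark.parametrize("seed", range(20))
def test_fba_matches_vertex_enumeration(seed):
    """The LP optimum equals the brute-force maximum over polytope vertices."""
    rng = np.random.default_rng(seed)
    model = _random_network(rng)
    oracle = _vertex_enumeration_max(model)
    sol = fba(model)
    assert sol.status is SolverStatus.OPTIMAL
    assert oracle is not None
    assert sol.growth_rate == pytest.approx(oracle, rel=1e-6, abs=1e-8)


def test_relaxing_uptake_never_decreases_growth():
    """Monotonicity: allowing more uptake cannot hurt the optimum."""
    model = chain_model()
    rates = [0.0, 1.0, 2.5, 7.0, 10.0, 50.0]
    growth = [fba(model, {"EX_glc": (-r, 1000.0)}).growth_rate for r in rates]
    assert all(b >= a - 1e-12 for a, b in zip(growth, growth[1:]))


# ---------------------------------------------------------------------------
# pFBA
# ---------------------------------------------------------------------------


class TestPFBA:
    def test_prefers_short_pathway(self):
        model = parallel_pathway_model()
        sol = pfba(model)
        assert sol.growth_rate == pytest.approx(1.0, abs=1e-8)
        assert sol.fluxes["SHORT"] == pytest.approx(10.0, abs=1e-6)
        assert sol.fluxes["LONG1"] == pytest.approx(0.0, abs=1e-6)
        assert sol.fluxes["LONG2"] == pytest.approx(0.0, abs=1e-6)

    def test_single_pathway_identical_to_fba(self, toy_chain):
        a, b = fba(toy_chain), pfba(toy_chain)
        for rid in a.fluxes:
            assert b.fluxes[rid] == pytest.approx(a.fluxes[rid], abs=1e-7)

    @pytest.mark.parametrize("seed", range(50))
    def test_growth_equals_fba_on_random_models(self, seed):
        rng = np.random.default_rng(1000 + seed)
        model = _random_network(rng)
        assert pfba(model).growth_rate == pytest.approx(
            fba(model).growth_rate, rel=1e-8, abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_l1_norm_not_larger_than_fba(self, seed):
        rng = np.random.default_rng(2000 + seed)
        model = _random_network(rng)
        a, b = fba(model), pfba(model)
        l1_fba = sum(abs(v) for v in a.fluxes.values())
        l1_pfba = sum(abs(v) for v in b.fluxes.values())
        assert l1_pfba <= l1_fba + 1e-6

    @pytest.mark.parametrize("seed", range(20))
    def test_mass_balance_within_tolerance(self, seed):
        rng = np.random.default_rng(3000 + seed)
        model = _random_network(rng)
        sol = pfba(model)
        S = model.stoichiometric_matrix
        v = np.array([sol.fluxes[r.id] for r in model.reactions])
        assert np.max(np.abs(S @ v)) <= 1e-6

    def test_infeasible_reported_not_raised(self, toy_chain):
        # force biomass lower bound above what uptake allows
        mets = list(toy_chain.metabolites)
        rxns = [
            Reaction("EX_glc", {"glc_e": -1}, -1.0, 1000.0, is_exchange=True),
            Reaction("T_glc", {"glc_e": -1, "glc_c": 1}, 0.0, 1000.0),
            Reaction("BIOMASS", {"glc_c": -10.0}, 5.0, 1000.0, is_biomass=True),
        ]
        model = StoichiometricModel("infeasible", mets, rxns)
        sol = pfba(model)
        assert sol.status is SolverStatus.INFEASIBLE
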