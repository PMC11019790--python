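"""Stoichiometric model data types and the FBA / parsimonious-FBA solvers.

A :class:`StoichiometricModel` is a plain reaction network with one biomass
reaction and a set of exchange reactions.  Exchange fluxes follow the
secretion-positive convention: an exchange reaction touches exactly one
extracellular metabolite with coefficient -1, so positive flux exports
(secretes) the metabolite and negative flux imports (takes it up).

Flux distributions are computed with linear programming (HiGHS via
``scipy.optimize.linprog``): :func:`fba` maximizes biomass flux subject to
steady-state mass balance ``S v = 0`` and flux bounds, and :func:`pfba`
additionally minimizes total absolute flux at the growth optimum, which
resolves degenerate optima deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Compartment",
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "FluxSolution",
    "SolverStatus",
    "ModelValidationError",
    "ModelParseError",
    "UnboundedObjectiveError",
    "read_model",
    "write_model",
    "model_from_dict",
    "model_to_dict",
    "fba",
    "pfba",
]

# LP tolerances: tight so that integrated dFBA drift stays far below the
# 1e-6 mass-balance bound asserted on every optimal solution.
FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-9
#: relative tolerance with which the biomass optimum is pinned in pFBA
PFBA_BIOMASS_RTOL = 1e-9

_DEFAULT_BOUND = 1000.0


class Compartment(str, Enum):
    EXTRACELLULAR = "extracellular"
    INTRACELLULAR = "intracellular"


class SolverStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


class ModelParseError(ValueError):
    """A model file could not be parsed under the named format."""


class UnboundedObjectiveError(RuntimeError):
    """The biomass objective is unbounded; cap the exchange bounds."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: Compartment = Compartment.INTRACELLULAR
    formula: str | None = None


@dataclass(frozen=True)
class Reaction:
    """One reaction; ``stoichiometry`` maps metabolite id -> signed coefficient.

    Bounds are fluxes in mmol/gDW/h (the biomass reaction's flux is 1/h).
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = -_DEFAULT_BOUND
    upper_bound: float = _DEFAULT_BOUND
    is_exchange: bool = False
    is_biomass: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )


@dataclass
class StoichiometricModel:
    """One species' reaction network with a single biomass objective."""

    species_id: str
    metabolites: Sequence[Metabolite]
    reactions: Sequence[Reaction]
    biomass_reaction_id: str = field(init=False, default="")

    def __post_init__(self) -> None:
        self.metabolites = tuple(self.metabolites)
        self.reactions = tuple(self.reactions)
        self._validate()
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._S = self._build_matrix()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        mets = {m.id: m for m in self.metabolites}
        biomass = [r.id for r in self.reactions if r.is_biomass]
        if len(biomass) != 1:
            raise ModelValidationError(
                f"model {self.species_id!r} must have exactly one biomass "
                f"reaction, found {len(biomass)}"
            )
        object.__setattr__(self, "biomass_reaction_id", biomass[0])
        for r in self.reactions:
            for met_id, coef in r.stoichiometry.items():
                if met_id not in mets:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references undeclared metabolite "
                        f"{met_id!r}"
                    )
                if coef == 0:
                    raise ModelValidationError(
                        f"reaction {r.id!r}: zero stoichiometric coefficient "
                        f"for {met_id!r}"
                    )
            if r.is_exchange:
                ext = [
                    (mid, c)
                    for mid, c in r.stoichiometry.items()
                    if mets[mid].compartment is Compartment.EXTRACELLULAR
                ]
                if len(r.stoichiometry) != 1 or len(ext) != 1 or ext[0][1] != -1:
                    raise ModelValidationError(
                        f"exchange reaction {r.id!r} must touch exactly one "
                        "extracellular metabolite with coefficient -1"
                    )

    def _build_matrix(self) -> np.ndarray:
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met_id, coef in r.stoichiometry.items():
                S[self._met_index[met_id], j] = coef
        return S

    # -- convenience -------------------------------------------------------

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        return self._S

    @property
    def exchange_reactions(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.is_exchange)

    def exchanged_metabolite(self, reaction_id: str) -> str:
        """Extracellular metabolite moved by an exchange reaction."""
        rxn = self.reactions[self._rxn_index[reaction_id]]
        if not rxn.is_exchange:
            raise KeyError(f"{reaction_id!r} is not an exchange reaction")
        return next(iter(rxn.stoichiometry))

    def exchange_for(self, metabolite_id: str) -> str | None:
        for r in self.exchange_reactions:
            if metabolite_id in r.stoichiometry:
                return r.id
        return None

    def reaction(self, reaction_id: str) -> Reaction:
        return self.reactions[self._rxn_index[reaction_id]]

    def bounds_array(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub


@dataclass(frozen=True)
class FluxSolution:
    fluxes: Mapping[str, float]
    growth_rate: float
    status: SolverStatus

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


# ---------------------------------------------------------------------------
# JSON / SBML input-output
#
# Native JSON schema:
#   {"species_id": str,
#    "metabolites": [{"id", "name", "compartment", "formula"?}, ...],
#    "reactions":   [{"id", "stoich": {met: coef}, "lb"?, "ub"?,
#                     "reversible"?, "is_exchange", "is_biomass"}, ...]}
# Bounds absent in the file default to [-1000, 1000] for reversible and
# [0, 1000] for irreversible reactions ("reversible" defaults to true).
# ---------------------------------------------------------------------------


def model_from_dict(data: Mapping) -> StoichiometricModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=Compartment(m.get("compartment", "intracellular")),
                formula=m.get("formula"),
            )
            for m in data["metabolites"]
        ]
        rxns = []
        for r in data["reactions"]:
            reversible = bool(r.get("reversible", True))
            lb = r.get("lb", -_DEFAULT_BOUND if reversible else 0.0)
            ub = r.get("ub", _DEFAULT_BOUND)
            rxns.append(
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r["stoich"].items()},
                    lower_bound=float(lb),
                    upper_bound=float(ub),
                    is_exchange=bool(r.get("is_exchange", False)),
                    is_biomass=bool(r.get("is_biomass", False)),
                )
            )
        species_id = data["species_id"]
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ModelValidationError):
            raise
        raise ModelParseError(f"malformed model document: {exc!r}") from exc
    return StoichiometricModel(species_id, mets, rxns)


def model_to_dict(model: StoichiometricModel) -> dict:
    return {
        "species_id": model.species_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment.value,
                **({"formula": m.formula} if m.formula else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": {k: float(v) for k, v in sorted(r.stoichiometry.items())},
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "is_exchange": r.is_exchange,
                "is_biomass": r.is_biomass,
            }
            for r in model.reactions
        ],
    }


def _read_sbml(path: Path) -> StoichiometricModel:
    """Read SBML Level 3 core (+fbc bounds/objective); annotations ignored."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"SBML parse error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError("SBML file contains no model element")

    # compartment heuristic: ids/names containing 'e' / 'extracellular'
    ext_compartments = set()
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        label = (comp.getName() or comp.getId()).lower()
        if label in ("e", "e0", "extracellular", "external", "medium"):
            ext_compartments.add(comp.getId())

    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        comp = (
            Compartment.EXTRACELLULAR
            if sp.getCompartment() in ext_compartments or sp.getBoundaryCondition()
            else Compartment.INTRACELLULAR
        )
        mets.append(Metabolite(id=sp.getId(), name=sp.getName() or "", compartment=comp))

    fbc = sbml_model.getPlugin("fbc")
    objective_ids: set[str] = set()
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        for j in range(obj.getNumFluxObjectives()):
            objective_ids.add(obj.getFluxObjective(j).getReaction())

    def _param(pid: str, default: float) -> float:
        p = sbml_model.getParameter(pid) if pid else None
        return p.getValue() if p is not None else default

    met_ids = {m.id for m in mets}
    rxns = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0 and k in met_ids}
        reversible = rx.getReversible()
        lb, ub = (-_DEFAULT_BOUND if reversible else 0.0), _DEFAULT_BOUND
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None:
            lb = _param(rfbc.getLowerFluxBound(), lb)
            ub = _param(rfbc.getUpperFluxBound(), ub)
        is_exchange = (
            len(stoich) == 1
            and next(iter(stoich.values())) == -1
            and any(
                m.id == next(iter(stoich)) and m.compartment is Compartment.EXTRACELLULAR
                for m in mets
            )
        ) or rx.getId().startswith("EX_")
        rxns.append(
            Reaction(
                id=rx.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                is_exchange=is_exchange,
                is_biomass=rx.getId() in objective_ids
                or (not objective_ids and "biomass" in rx.getId().lower()),
            )
        )
    return StoichiometricModel(sbml_model.getId() or path.stem, mets, rxns)


def read_model(path: str | Path, format: str = "json") -> StoichiometricModel:
    """Read and validate a model from ``path`` (``json`` or ``sbml``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"invalid JSON in {path}: {exc}") from exc
        return model_from_dict(data)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: StoichiometricModel, path: str | Path) -> None:
    """Write the canonicalized JSON form (stable key order, sorted stoich)."""
    Path(path).write_text(
        json.dumps(model_to_dict(model), indent=1, sort_keys=False) + "\n"
    )


# ---------------------------------------------------------------------------
# Linear programming
# ---------------------------------------------------------------------------

_LINPROG_OPTS = {
    "presolve": True,
    "primal_feasibility_tolerance": FEASIBILITY_TOL,
    "dual_feasibility_tolerance": OPTIMALITY_TOL,
}


def _resolve_bounds(
    model: StoichiometricModel,
    exchange_bounds: Mapping[str, tuple[float, float]] | None,
) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = model.bounds_array()
    if exchange_bounds:
        exch_ids = {r.id for r in model.exchange_reactions}
        for rid, (lo, hi) in exchange_bounds.items():
            if rid not in exch_ids:
                raise KeyError(f"{rid!r} is not an exchange reaction of {model.species_id!r}")
            j = model._rxn_index[rid]
            lb[j], ub[j] = lo, hi
    return lb, ub


def fba(
    model: StoichiometricModel,
    exchange_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """Maximize biomass flux subject to ``S v = 0`` and flux bounds.

    ``exchange_bounds`` overrides the bounds of named exchange reactions
    (typically set each dFBA step from the medium state).
    """
    lb, ub = _resolve_bounds(model, exchange_bounds)
    n = len(model.reactions)
    c = np.zeros(n)
    c[model._rxn_index[model.biomass_reaction_id]] = -1.0  # maximize
    res = linprog(
        c,
        A_eq=model._S,
        b_eq=np.zeros(model._S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_LINPROG_OPTS,
    )
    if res.status == 3:
        raise UnboundedObjectiveError(
            f"biomass objective of {model.species_id!r} is unbounded; cap the "
            "exchange bounds (every uptake needs a finite lower bound)"
        )
    if res.status != 0:
        return FluxSolution(fluxes={}, growth_rate=0.0, status=SolverStatus.INFEASIBLE)
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxSolution(
        fluxes=fluxes,
        growth_rate=float(fluxes[model.biomass_reaction_id]),
        status=SolverStatus.OPTIMAL,
    )


def pfba(
    model: StoichiometricModel,
    exchange_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> FluxSolution:
    """Parsimonious FBA: minimize total |flux| at the biomass optimum.

    The biomass flux is first maximized (:func:`fba`), then fixed within a
    relative tolerance of ``PFBA_BIOMASS_RTOL`` while the L1 norm of the flux
    vector is minimized via the standard split into non-negative forward and
    reverse components.  The returned ``growth_rate`` equals the FBA optimum.
    """
    first = fba(model, exchange_bounds)
    if first.status is not SolverStatus.OPTIMAL:
        return first
    mu = first.growth_rate
    lb, ub = _resolve_bounds(model, exchange_bounds)
    j_bio = model._rxn_index[model.biomass_reaction_id]
    # pin biomass to [mu*(1-rtol), mu]; for mu == 0 this fixes it at 0
    lb[j_bio] = max(lb[j_bio], mu - abs(mu) * PFBA_BIOMASS_RTOL)
    ub[j_bio] = min(ub[j_bio], mu)

    n = len(model.reactions)
    # v = p - q with p, q >= 0; bounds: p <= max(ub,0), q <= max(-lb,0)
    p_ub = np.maximum(ub, 0.0)
    q_ub = np.maximum(-lb, 0.0)
    p_lb = np.maximum(lb, 0.0)  # if lb > 0, forward part must carry it
    q_lb = np.maximum(-ub, 0.0)
    A_eq = np.hstack([model._S, -model._S])
    c = np.ones(2 * n)
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=np.column_stack(
            [np.concatenate([p_lb, q_lb]), np.concatenate([p_ub, q_ub])]
        ),
        method="highs",
        options=_LINPROG_OPTS,
    )
    if res.status != 0:  # numerically possible at the pinned optimum; retry loose
        res = linprog(
            c,
            A_eq=A_eq,
            b_eq=np.zeros(A_eq.shape[0]),
            bounds=np.column_stack(
                [np.concatenate([p_lb, q_lb]), np.concatenate([p_ub, q_ub])]
            ),
            method="highs",
        )
    if res.status != 0:
        return first
    v = res.x[:n] - res.x[n:]
    fluxes = {r.id: float(x) for r, x in zip(model.reactions, v)}
    return FluxSolution(fluxes=fluxes, growth_rate=mu, status=SolverStatus.OPTIMAL)
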