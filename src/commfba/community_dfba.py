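"""Well-mixed batch dFBA of a multi-species community with serial transfer.

Each timestep, every species solves a parsimonious FBA problem whose uptake
bounds reflect the current extracellular pools: the uptake bound for a finite
pool ``m`` is ``-min(Vmax, pool_m / (X_consumers * dt * 1.0001))`` where
``Vmax`` is the species' limiting-carbon uptake rate for limiting carbon
sources and its default Vmax otherwise, and ``X_consumers`` is the summed
biomass of all species able to take ``m`` up (the overdraw guard).  Unlimited
metabolites are bounded at the default Vmax and never depleted.  Biomass is
updated with an exponential-Euler step ``X <- X * exp(mu * dt)`` and pools
with an explicit Euler step ``pool <- pool + flux * X * dt``.

Serial transfer follows the growth-dilution experiment: 48-h cycles, after
each of which 10% of the culture is carried into fresh medium (biomass and
pools both scaled/mixed by the dilution factor).

Performance notes (exact, not approximations): the per-species LP solution
depends only on the bound vector, which is piecewise-constant in time, so
solutions are cached per bound vector; and once every species is stationary
(zero growth, zero exchange flux, unchanged bounds) the rest of the cycle is
filled in without further solves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .medium import MediumState, refresh_mix
from .metabolic_core import FluxSolution, SolverStatus, StoichiometricModel, pfba

__all__ = [
    "SpeciesConfig",
    "TransferSpec",
    "CommunityState",
    "Trajectory",
    "SimulationIntegrityError",
    "step",
    "run_passage",
    "dilute",
    "run_serial_transfer",
]

#: pools may dip this far below zero from floating-point residue; anything
#: more negative indicates an integration defect and raises.
POOL_NEGATIVITY_TOL = 1e-9

#: safety factor in the availability cap, preventing overdraw at depletion
OVERDRAW_GUARD = 1.0001

#: pools below this (mmol) after a step are treated as exactly depleted; the
#: overdraw guard otherwise leaves a geometrically decaying residue that
#: never reaches zero
POOL_SNAP = 1e-11

#: availability-derived uptake caps below this (mmol/gDW/h) are treated as
#: zero — a transporter noise floor matching the exchange-network edge
#: epsilon, so sub-detectable trickles cannot drive the solver
UPTAKE_BOUND_FLOOR = 1e-9


def _quantize_down(x: float) -> float:
    """Round a positive cap down to one significant figure.

    Availability caps vary continuously as biomass grows; quantizing them
    (always downward, so pools can never be overdrawn) makes the LP bound
    vector piecewise constant in time, at the cost of delaying a pool's final
    depletion by at most a couple of steps.
    """
    if x <= 0 or math.isinf(x):
        return x
    q = 10.0 ** math.floor(math.log10(x))
    return math.floor(x / q) * q

#: default initial dry mass per species, g
DEFAULT_INITIAL_BIOMASS = 3.9e-7


class SimulationIntegrityError(RuntimeError):
    """A pool went more negative than the integrity tolerance allows."""


@dataclass(frozen=True)
class SpeciesConfig:
    """Per-species simulation parameters.

    ``limiting_uptake_rate`` (mmol/gDW/h) caps every limiting-carbon exchange
    simultaneously; ``default_vmax`` caps all other uptakes.
    """

    model: StoichiometricModel
    limiting_uptake_rate: float
    limiting_carbon_ids: frozenset[str]
    default_vmax: float = 10.0
    initial_biomass: float = DEFAULT_INITIAL_BIOMASS
    #: optional Monod half-saturation constant (mM) applied to finite pools;
    #: None (the default) keeps the plain hard-cap kinetics
    monod_km: float | None = None

    def __post_init__(self) -> None:
        if self.limiting_uptake_rate <= 0 or self.default_vmax <= 0:
            raise ValueError("uptake rates must be positive")
        if self.initial_biomass <= 0:
            raise ValueError("initial biomass must be positive")
        if self.monod_km is not None and self.monod_km <= 0:
            raise ValueError("monod_km must be positive when set")

    @property
    def species_id(self) -> str:
        return self.model.species_id

    def with_rate(self, rate: float) -> "SpeciesConfig":
        return replace(self, limiting_uptake_rate=rate)


@dataclass(frozen=True)
class TransferSpec:
    """Serial-transfer schedule: cycle length, passages, dilution, timestep."""

    cycle_hours: float = 48.0
    n_passages: int = 6
    dilution_factor: float = 0.1
    timestep: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.dilution_factor <= 1:
            raise ValueError("dilution factor must be in (0, 1]")
        if self.n_passages < 1:
            raise ValueError("need at least one passage")
        n = self.cycle_hours / self.timestep
        if abs(n - round(n)) > 1e-9:
            raise ValueError("timestep must divide cycle_hours")

    @property
    def steps_per_cycle(self) -> int:
        return round(self.cycle_hours / self.timestep)


@dataclass(frozen=True)
class CommunityState:
    biomass: Mapping[str, float]
    medium: MediumState
    time: float = 0.0
    passage_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "biomass", dict(self.biomass))
        bad = [s for s, x in self.biomass.items() if x < 0]
        if bad:
            raise ValueError(f"negative biomass for {bad}")

    def fractions(self) -> dict[str, float]:
        total = sum(self.biomass.values())
        if total == 0:
            return {s: 0.0 for s in self.biomass}
        return {s: x / total for s, x in self.biomass.items()}


@dataclass
class Trajectory:
    """One passage of simulated states plus the per-step exchange record.

    ``biomass`` has shape (n_steps + 1, n_species) (state at every step edge),
    ``pools`` (n_steps + 1, n_pool_metabolites), and ``exchange_flux``
    (n_steps, n_species, n_exchange_metabolites) in mmol/gDW/h with the
    secretion-positive convention, applying over ``[t_k, t_k + dt)``.
    """

    species_ids: tuple[str, ...]
    times: np.ndarray
    biomass: np.ndarray
    pool_ids: tuple[str, ...]
    pools: np.ndarray
    exchange_met_ids: tuple[str, ...]
    exchange_flux: np.ndarray
    passage_index: int
    timestep: float
    unlimited_ids: frozenset[str] = field(default_factory=frozenset)
    volume_ml: float = 10.0

    def final_state(self) -> CommunityState:
        pools = {
            m: float(v) for m, v in zip(self.pool_ids, self.pools[-1])
        }
        return CommunityState(
            biomass=dict(zip(self.species_ids, map(float, self.biomass[-1]))),
            medium=MediumState(
                pools=pools, unlimited_ids=self.unlimited_ids, volume_ml=self.volume_ml
            ),
            time=float(self.times[-1]),
            passage_index=self.passage_index,
        )

    def biomass_frame(self) -> pd.DataFrame:
        """Tidy table (time_h, passage, species, biomass_gDW)."""
        rows = []
        for k, t in enumerate(self.times):
            for j, s in enumerate(self.species_ids):
                rows.append((float(t), self.passage_index, s, float(self.biomass[k, j])))
        return pd.DataFrame(rows, columns=["time_h", "passage", "species", "biomass_gDW"])

    def flux_frame(self) -> pd.DataFrame:
        """Tidy table (time_h, passage, species, metabolite, flux_mmol_per_gDW_h)."""
        rows = []
        for k in range(self.exchange_flux.shape[0]):
            for j, s in enumerate(self.species_ids):
                for m_idx, m in enumerate(self.exchange_met_ids):
                    v = self.exchange_flux[k, j, m_idx]
                    if v != 0.0:
                        rows.append((float(self.times[k]), self.passage_index, s, m, float(v)))
        return pd.DataFrame(
            rows,
            columns=["time_h", "passage", "species", "metabolite", "flux_mmol_per_gDW_h"],
        )


# ---------------------------------------------------------------------------
# simulation engine
# ---------------------------------------------------------------------------


class _Runner:
    """Precomputed exchange topology plus an LP-solution cache per species."""

    def __init__(self, configs: Sequence[SpeciesConfig]):
        self.configs = list(configs)
        self.species_ids = tuple(c.species_id for c in configs)
        # per species: list of (exchange reaction, metabolite id)
        self.exchanges: list[list[tuple[str, str, float, float]]] = []
        met_ids: list[str] = []
        seen: set[str] = set()
        for cfg in configs:
            entries = []
            for rxn in cfg.model.exchange_reactions:
                m = next(iter(rxn.stoichiometry))
                entries.append((rxn.id, m, rxn.lower_bound, rxn.upper_bound))
                if m not in seen:
                    seen.add(m)
                    met_ids.append(m)
            self.exchanges.append(entries)
        self.exchange_met_ids = tuple(met_ids)
        self.met_index = {m: i for i, m in enumerate(met_ids)}
        # which species can take a metabolite up (model lb < 0)
        self.consumers: dict[str, list[int]] = {m: [] for m in met_ids}
        for j, entries in enumerate(self.exchanges):
            for _, m, lb, _ in entries:
                if lb < 0:
                    self.consumers[m].append(j)
        self._cache: list[dict[tuple, tuple[float, np.ndarray, FluxSolution]]] = [
            {} for _ in configs
        ]

    def uptake_bounds(
        self,
        j: int,
        pools: Mapping[str, float],
        unlimited: frozenset[str],
        biomass: Mapping[str, float],
        dt: float,
        volume_ml: float = 10.0,
    ) -> tuple[float, ...]:
        """Exchange lower bounds for species ``j`` (aligned with its exchanges)."""
        cfg = self.configs[j]
        out: list[float] = []
        for rid, m, lb, ub in self.exchanges[j]:
            if lb >= 0:  # secretion-only exchange; medium cannot restrict it
                out.append(lb)
                continue
            if m in unlimited:
                cap = cfg.default_vmax
            else:
                pool = pools.get(m, 0.0)
                rate = (
                    cfg.limiting_uptake_rate
                    if m in cfg.limiting_carbon_ids
                    else cfg.default_vmax
                )
                if cfg.monod_km is not None:
                    conc = pool / (volume_ml / 1000.0)  # mmol/L = mM
                    rate = rate * conc / (cfg.monod_km + conc)
                x_cons = 0.0
                for i in self.consumers[m]:
                    x_cons += biomass[self.species_ids[i]]
                if x_cons > 0:
                    avail = pool / (x_cons * dt * OVERDRAW_GUARD)
                    if avail < rate:
                        cap = _quantize_down(avail)
                        if cap < UPTAKE_BOUND_FLOOR:
                            cap = 0.0
                    else:
                        cap = rate
                else:
                    cap = rate
            out.append(max(lb, -cap))
        return tuple(out)

    def solve(
        self, j: int, key: tuple[float, ...]
    ) -> tuple[float, np.ndarray, FluxSolution]:
        """Growth rate + exchange-flux vector (aligned with exchange_met_ids).

        ``key`` is the tuple of exchange lower bounds from
        :meth:`uptake_bounds`; solutions are memoized on it (the upper bounds
        never change), which is exact because the LP depends on nothing else.
        """
        hit = self._cache[j].get(key)
        if hit is not None:
            return hit
        bounds = {
            entry[0]: (lo, entry[3])
            for entry, lo in zip(self.exchanges[j], key)
        }
        sol = pfba(self.configs[j].model, bounds)
        flux_vec = np.zeros(len(self.exchange_met_ids))
        if sol.status is SolverStatus.OPTIMAL:
            mu = sol.growth_rate
            for rid, m, _, _ in self.exchanges[j]:
                flux_vec[self.met_index[m]] = sol.fluxes[rid]
        else:
            mu = 0.0
            warnings.warn(
                f"species {self.species_ids[j]!r}: infeasible LP treated as "
                "zero growth for this step",
                RuntimeWarning,
                stacklevel=2,
            )
            sol = FluxSolution(fluxes={}, growth_rate=0.0, status=SolverStatus.INFEASIBLE)
        result = (mu, flux_vec, sol)
        self._cache[j].setdefault(key, result)
        return result


def _advance(
    runner: _Runner,
    biomass: dict[str, float],
    pools: dict[str, float],
    unlimited: frozenset[str],
    dt: float,
    volume_ml: float = 10.0,
) -> tuple[dict[str, float], dict[str, float], np.ndarray, list[FluxSolution], bool]:
    """One dFBA step; returns new biomass/pools, flux record, solutions, and
    whether the community is fully stationary (state will no longer change)."""
    n_mets = len(runner.exchange_met_ids)
    flux_rec = np.zeros((len(runner.configs), n_mets))
    solutions: list[FluxSolution] = []
    new_biomass = dict(biomass)
    delta = np.zeros(n_mets)
    stationary = True
    for j, cfg in enumerate(runner.configs):
        sid = cfg.species_id
        x = biomass[sid]
        if x == 0.0:
            solutions.append(
                FluxSolution(fluxes={}, growth_rate=0.0, status=SolverStatus.OPTIMAL)
            )
            continue
        key = runner.uptake_bounds(j, pools, unlimited, biomass, dt, volume_ml)
        mu, flux_vec, sol = runner.solve(j, key)
        solutions.append(sol)
        flux_rec[j] = flux_vec
        if mu != 0.0:
            new_biomass[sid] = x * math.exp(mu * dt)
            stationary = False
        if np.any(flux_vec):
            delta += flux_vec * (x * dt)
            stationary = False
    new_pools = dict(pools)
    for i, m in enumerate(runner.exchange_met_ids):
        if m in unlimited or delta[i] == 0.0:
            continue
        v = new_pools.get(m, 0.0) + delta[i]
        if v < 0.0:
            if v < -POOL_NEGATIVITY_TOL:
                raise SimulationIntegrityError(
                    f"pool {m!r} driven to {v:.3e} mmol (below -{POOL_NEGATIVITY_TOL})"
                )
            v = 0.0
        elif v < POOL_SNAP and delta[i] < 0.0:
            v = 0.0
        new_pools[m] = v
    return new_biomass, new_pools, flux_rec, solutions, stationary


def step(
    state: CommunityState,
    species_configs: Sequence[SpeciesConfig],
    dt: float,
) -> tuple[CommunityState, dict[str, FluxSolution]]:
    """Advance the community by one timestep of length ``dt`` hours."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    missing = [s for s in state.biomass if s not in {c.species_id for c in species_configs}]
    if missing:
        raise KeyError(f"no config for species {missing}")
    runner = _Runner(species_configs)
    biomass, pools, _, solutions, _ = _advance(
        runner,
        dict(state.biomass),
        dict(state.medium.pools),
        state.medium.unlimited_ids,
        dt,
        state.medium.volume_ml,
    )
    new_state = CommunityState(
        biomass=biomass,
        medium=state.medium.with_pools(pools),
        time=state.time + dt,
        passage_index=state.passage_index,
    )
    return new_state, dict(zip(runner.species_ids, solutions))


def run_passage(
    state: CommunityState,
    species_configs: Sequence[SpeciesConfig],
    transfer: TransferSpec,
    _runner: _Runner | None = None,
) -> Trajectory:
    """Simulate one growth cycle of ``transfer.cycle_hours`` hours."""
    runner = _runner if _runner is not None else _Runner(species_configs)
    n_steps = transfer.steps_per_cycle
    dt = transfer.timestep
    n_sp = len(runner.species_ids)
    n_mets = len(runner.exchange_met_ids)

    pool_ids = tuple(
        sorted(set(state.medium.pools) | set(runner.exchange_met_ids) - state.medium.unlimited_ids)
    )
    pool_index = {m: i for i, m in enumerate(pool_ids)}

    times = state.time + dt * np.arange(n_steps + 1)
    biomass_arr = np.zeros((n_steps + 1, n_sp))
    pools_arr = np.zeros((n_steps + 1, len(pool_ids)))
    flux_arr = np.zeros((n_steps, n_sp, n_mets))

    biomass = dict(state.biomass)
    pools = {m: state.medium.pool(m) for m in pool_ids}
    unlimited = state.medium.unlimited_ids
    biomass_arr[0] = [biomass[s] for s in runner.species_ids]
    pools_arr[0] = [pools[m] for m in pool_ids]

    for k in range(n_steps):
        biomass, pools, flux_rec, _, stationary = _advance(
            runner, biomass, pools, unlimited, dt, state.medium.volume_ml
        )
        flux_arr[k] = flux_rec
        biomass_arr[k + 1] = [biomass[s] for s in runner.species_ids]
        pools_arr[k + 1] = [pools[m] for m in pool_index]
        if stationary:
            # nothing can change any more this cycle: the state is a fixed
            # point (zero growth and zero exchange for every species)
            biomass_arr[k + 2 :] = biomass_arr[k + 1]
            pools_arr[k + 2 :] = pools_arr[k + 1]
            break

    return Trajectory(
        species_ids=runner.species_ids,
        times=times,
        biomass=biomass_arr,
        pool_ids=pool_ids,
        pools=pools_arr,
        exchange_met_ids=runner.exchange_met_ids,
        exchange_flux=flux_arr,
        passage_index=state.passage_index,
        timestep=dt,
        unlimited_ids=unlimited,
        volume_ml=state.medium.volume_ml,
    )


def dilute(
    state: CommunityState, transfer: TransferSpec, fresh: MediumState
) -> CommunityState:
    """Serial-transfer event: scale biomass and mix medium by the dilution factor."""
    d = transfer.dilution_factor
    return CommunityState(
        biomass={s: x * d for s, x in state.biomass.items()},
        medium=refresh_mix(state.medium, fresh, d),
        time=state.time,
        passage_index=state.passage_index + 1,
    )


def run_serial_transfer(
    species_configs: Sequence[SpeciesConfig],
    transfer: TransferSpec,
    fresh: MediumState,
    initial_biomass: Mapping[str, float] | None = None,
) -> list[Trajectory]:
    """Alternate growth cycles and dilution events for ``n_passages`` passages.

    ``initial_biomass`` overrides the per-config inocula (e.g. to start one
    species 1,000-fold diluted); the medium starts as the fresh medium.
    """
    runner = _Runner(species_configs)
    biomass = {c.species_id: c.initial_biomass for c in species_configs}
    if initial_biomass:
        unknown = set(initial_biomass) - set(biomass)
        if unknown:
            raise KeyError(f"unknown species in initial_biomass: {sorted(unknown)}")
        biomass.update(initial_biomass)
    state = CommunityState(biomass=biomass, medium=fresh, time=0.0, passage_index=0)
    trajectories: list[Trajectory] = []
    for p in range(transfer.n_passages):
        traj = run_passage(state, species_configs, transfer, _runner=runner)
        trajectories.append(traj)
        state = traj.final_state()
        if p < transfer.n_passages - 1:
            state = dilute(state, transfer, fresh)
    return trajectories
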