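"""Synthetic inputs: toy stoichiometric communities and noisy count series.

Toy communities emulate, at laptop scale, a three-member rhizosphere community
growing on a nutrient-rich medium whose glucose and amino acids are the
finite limiting carbon sources.  Each toy species is a minimal network —
exchange, transport and conversion reactions feeding a biomass precursor —
whose biomass yields per substrate are set directly.  Planted cross-feeding
is realized as growth-coupled byproduct secretion (a fixed stoichiometric
ratio to biomass, so secretion survives parsimonious flux minimization) with
an uptake-to-biomass route in the consumers.

Two community designs are provided:

* :func:`three_member_spec` — the default three-member community.  Every species has
  anchor substrates (finite private pools, fully depleted each cycle) that
  give the composition a stable attractor, so 1,000-fold inoculum changes
  converge within a few passages; the two minority species additionally grow
  on a private excess substrate (never depleted at calibrated rates), which
  makes their final fraction a smooth monotone function of the limiting
  uptake rate — the handle the calibration search turns.
* :func:`random_planted_spec` — randomized communities in which the two
  adjustable species grow *only* on their excess substrate, so the
  end-of-run composition depends exponentially on the uptake rate across all
  passages.  That steep response makes the planted rate identifiable to the
  finest calibration decrement, which is what these communities exist to
  demonstrate.

Count series emulate the CFU / qPCR assays: triplicate counts at 0/24/48 h
of each growth-dilution cycle with multiplicative lognormal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community_dfba import SpeciesConfig, TransferSpec, Trajectory
from .medium import AMINO_ACIDS, MediumSpec, MediumState, build_medium
from .metabolic_core import Compartment, Metabolite, Reaction, StoichiometricModel

__all__ = [
    "ToySpecies",
    "ToyCommunitySpec",
    "CountNoiseSpec",
    "make_toy_community",
    "three_member_spec",
    "anchored_spec",
    "random_planted_spec",
    "make_count_series",
    "CELLS_PER_GDW",
]

#: convenience mapping from dry mass to countable cells (counts/gDW)
CELLS_PER_GDW = 5e11

#: oxygen demand of the toy biomass reaction (mmol/gDW)
_O2_PER_BIOMASS = 0.05

#: molecular weight used for the sodium-pyruvate pool (g/mol)
_PYRUVATE_MW = 110.04


@dataclass(frozen=True)
class ToySpecies:
    """Blueprint for one toy species.

    ``substrate_yields`` (gDW/mmol) lists the limiting carbon sources the
    species grows on; ``byproducts`` maps secreted metabolite -> mmol
    secreted per gDW of biomass formed (growth-coupled); ``crossfeed_yields``
    gives growth yields on consumed partner byproducts and ``uptake_caps``
    their uptake rate caps (byproducts are scavenged slowly, mmol/gDW/h).
    """

    species_id: str
    substrate_yields: Mapping[str, float]
    byproducts: Mapping[str, float] = field(default_factory=dict)
    crossfeed_yields: Mapping[str, float] = field(default_factory=dict)
    uptake_caps: Mapping[str, float] = field(default_factory=dict)
    planted_rate: float = 10.0
    adjustable: bool = True

    def __post_init__(self) -> None:
        if not self.substrate_yields and not self.crossfeed_yields:
            raise ValueError(f"species {self.species_id!r} has no carbon route")
        for m, y in {**self.substrate_yields, **self.crossfeed_yields}.items():
            if y <= 0:
                raise ValueError(f"non-positive yield for {m!r}")


@dataclass(frozen=True)
class ToyCommunitySpec:
    """A toy community: species blueprints plus the fresh-medium pools."""

    species: tuple[ToySpecies, ...]
    pools: Mapping[str, float]  # fresh-medium finite pools, mmol
    unlimited_ids: frozenset[str] = frozenset({"o2"})
    volume_ml: float = 10.0
    default_vmax: float = 10.0
    initial_biomass: float = 3.9e-7
    transfer: TransferSpec = TransferSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        for sp in self.species:
            for m, phi in sp.byproducts.items():
                if phi <= 0:
                    raise ValueError("byproduct couplings must be positive")
        declared = {sp.species_id for sp in self.species}
        for sp in self.species:
            produced_somewhere = {
                m for other in self.species for m in other.byproducts
            }
            for m in sp.crossfeed_yields:
                if m not in produced_somewhere and m not in self.pools:
                    raise ValueError(
                        f"{sp.species_id!r} consumes {m!r} which no species "
                        "produces and the medium does not supply"
                    )
        if len(declared) != len(self.species):
            raise ValueError("duplicate species ids")

    @property
    def planted_rates(self) -> dict[str, float]:
        return {sp.species_id: sp.planted_rate for sp in self.species}

    @property
    def adjustable_species(self) -> tuple[str, ...]:
        return tuple(sp.species_id for sp in self.species if sp.adjustable)


def _build_species_model(sp: ToySpecies, unlimited: frozenset[str]) -> StoichiometricModel:
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []

    def ext(m: str) -> str:
        return f"{m}_e"

    def cyt(m: str) -> str:
        return f"{m}_c"

    seen: set[str] = set()

    def add_met(mid: str, compartment: Compartment) -> None:
        if mid not in seen:
            seen.add(mid)
            mets.append(Metabolite(id=mid, compartment=compartment))

    add_met("precursor_c", Compartment.INTRACELLULAR)

    consumed = {**sp.substrate_yields, **sp.crossfeed_yields}
    for m, y in consumed.items():
        add_met(ext(m), Compartment.EXTRACELLULAR)
        add_met(cyt(m), Compartment.INTRACELLULAR)
        rxns.append(
            Reaction(f"EX_{m}", {ext(m): -1.0}, -1000.0, 1000.0, is_exchange=True)
        )
        rxns.append(Reaction(f"T_{m}", {ext(m): -1.0, cyt(m): 1.0}, 0.0, 1000.0))
        rxns.append(
            Reaction(f"CONV_{m}", {cyt(m): -1.0, "precursor_c": y}, 0.0, 1000.0)
        )

    biomass_stoich: dict[str, float] = {"precursor_c": -1.0}
    if "o2" in unlimited:
        add_met("o2_e", Compartment.EXTRACELLULAR)
        add_met("o2_c", Compartment.INTRACELLULAR)
        rxns.append(Reaction("EX_o2", {"o2_e": -1.0}, -1000.0, 1000.0, is_exchange=True))
        rxns.append(Reaction("T_o2", {"o2_e": -1.0, "o2_c": 1.0}, 0.0, 1000.0))
        biomass_stoich["o2_c"] = -_O2_PER_BIOMASS

    for m, phi in sp.byproducts.items():
        add_met(cyt(m), Compartment.INTRACELLULAR)
        add_met(ext(m), Compartment.EXTRACELLULAR)
        biomass_stoich[cyt(m)] = biomass_stoich.get(cyt(m), 0.0) + phi
        rxns.append(Reaction(f"SEC_{m}", {cyt(m): -1.0, ext(m): 1.0}, 0.0, 1000.0))
        if m not in consumed:  # secretion-only exchange: no self-reuptake
            rxns.append(
                Reaction(f"EX_{m}", {ext(m): -1.0}, 0.0, 1000.0, is_exchange=True)
            )

    rxns.append(Reaction("BIOMASS", biomass_stoich, 0.0, 1000.0, is_biomass=True))
    return StoichiometricModel(sp.species_id, mets, rxns)


def make_toy_community(
    spec: ToyCommunitySpec,
) -> tuple[list[SpeciesConfig], MediumState]:
    """Build (species configs with embedded models, fresh medium) from a spec.

    Pure function of the spec (deterministic).  The exchanged metabolite ids
    in the models carry an ``_e`` suffix; the medium pools are keyed the same
    way so the simulator and the exchange-network inference line up.
    """
    configs: list[SpeciesConfig] = []
    unlimited = frozenset(f"{m}_e" for m in spec.unlimited_ids)
    for sp in spec.species:
        model = _build_species_model(sp, spec.unlimited_ids)
        limiting = frozenset(f"{m}_e" for m in sp.substrate_yields)
        cfg = SpeciesConfig(
            model=model,
            limiting_uptake_rate=sp.planted_rate,
            limiting_carbon_ids=limiting,
            default_vmax=spec.default_vmax,
            initial_biomass=spec.initial_biomass,
        )
        if sp.uptake_caps:
            cfg = _with_uptake_caps(cfg, {f"{m}_e": v for m, v in sp.uptake_caps.items()})
        configs.append(cfg)
    fresh = MediumState(
        pools={f"{m}_e": v for m, v in spec.pools.items()},
        unlimited_ids=unlimited,
        volume_ml=spec.volume_ml,
    )
    return configs, fresh


def _with_uptake_caps(cfg: SpeciesConfig, caps: Mapping[str, float]) -> SpeciesConfig:
    """Encode per-metabolite uptake caps in the model's exchange lower bounds."""
    new_rxns = []
    for r in cfg.model.reactions:
        if r.is_exchange:
            m = next(iter(r.stoichiometry))
            if m in caps:
                r = Reaction(
                    r.id,
                    r.stoichiometry,
                    max(r.lower_bound, -caps[m]),
                    r.upper_bound,
                    is_exchange=True,
                )
        new_rxns.append(r)
    model = StoichiometricModel(cfg.model.species_id, cfg.model.metabolites, new_rxns)
    return SpeciesConfig(
        model=model,
        limiting_uptake_rate=cfg.limiting_uptake_rate,
        limiting_carbon_ids=cfg.limiting_carbon_ids,
        default_vmax=cfg.default_vmax,
        initial_biomass=cfg.initial_biomass,
    )


# ---------------------------------------------------------------------------
# the default three-member community
# ---------------------------------------------------------------------------

_GM_ANCHORS = ("ala", "glu", "ser")
_YR_SUBSTRATES = ("pro", "val")
_AP_SUBSTRATES = ("his", "trp")

#: byproduct scavenging cap for the minority species, mmol/gDW/h
_CROSSFEED_CAP = 0.1
#: glycerol scavenging cap for the dominant species; far below the supply
#: rate, so the glycerol pool accumulates and the uptake bound stays constant
_GLYCEROL_CAP = 2e-7


def three_member_spec() -> ToyCommunitySpec:
    """The default three-member toy community with planted exchange topology.

    The dominant species (a Pseudomonas-like "GM17") grows fast on three
    amino-acid pools it exhausts every cycle — its biomass is pinned at the
    pool-conversion level, giving the community a stable backbone — and
    secretes putrescine and xanthine in proportion to growth.  "YR343"
    scavenges both, grows on proline/valine plus glucose, and returns
    glycerol to GM17; "AP49" scavenges putrescine and grows on
    histidine/tryptophan plus pyruvate, secreting niacin that nobody
    consumes.  The minority species never exhaust their substrates at
    calibrated uptake rates, so their end-of-run biomass depends
    exponentially on the limiting uptake rate across all passages — the
    steep, monotone handle the calibration search turns.
    """
    # dominant-species yield keeps mu * dt small even at the 10 mmol/gDW/h
    # start rate, so the exponential-Euler / explicit-Euler pairing stays in
    # its convergent regime (timestep halving moves biomass < 1%)
    # byproduct couplings are kept small so the minority species' growth is
    # dominated by their own substrates (cross-feeding is a signal to detect,
    # not a life line); integrated exchange still sits orders of magnitude
    # above the network inference noise floor
    gm = ToySpecies(
        species_id="GM17",
        substrate_yields={m: 0.01 for m in _GM_ANCHORS},
        byproducts={"putrescine": 0.004, "xanthine": 0.002},
        crossfeed_yields={"glycerol": 0.05},
        uptake_caps={"glycerol": _GLYCEROL_CAP},
        planted_rate=10.0,
        adjustable=False,
    )
    yr = ToySpecies(
        species_id="YR343",
        substrate_yields={**{m: 0.02 for m in _YR_SUBSTRATES}, "glc": 0.11},
        byproducts={"glycerol": 0.05},
        crossfeed_yields={"putrescine": 0.05, "xanthine": 0.05},
        uptake_caps={"putrescine": _CROSSFEED_CAP, "xanthine": _CROSSFEED_CAP},
        planted_rate=0.365,
    )
    ap = ToySpecies(
        species_id="AP49",
        substrate_yields={**{m: 0.005 for m in _AP_SUBSTRATES}, "pyr": 0.11},
        byproducts={"niacin": 0.01},
        crossfeed_yields={"putrescine": 0.05},
        uptake_caps={"putrescine": _CROSSFEED_CAP},
        planted_rate=0.39,
    )
    medium = build_medium(MediumSpec())
    pools = dict(medium.pools)
    pools["pyr"] = 0.3 / _PYRUVATE_MW * (10.0 / 1000.0) * 1000.0  # 0.3 g/L
    return ToyCommunitySpec(species=(gm, yr, ap), pools=pools, seed=0)


def anchored_spec() -> ToyCommunitySpec:
    """A three-member community in which *every* species is pinned by private
    amino-acid pools it fully exhausts each cycle.

    Each species' end-of-cycle biomass equals its pool-conversion capacity
    regardless of inoculum, so the composition converges within a passage or
    two from any starting ratio — the design used to demonstrate that the
    assembled composition is independent of which species is diluted at
    inoculation.
    """
    species = []
    panels = (
        ("GM17", ("ala", "glu", "ser", "gly"), 0.12),
        ("YR343", ("pro", "val", "thr"), 0.03),
        ("AP49", ("his", "trp"), 0.01),
    )
    for sid, aas, y in panels:
        species.append(
            ToySpecies(
                species_id=sid,
                substrate_yields={m: y for m in aas},
                planted_rate=10.0,
                adjustable=sid != "GM17",
            )
        )
    medium = build_medium(MediumSpec())
    return ToyCommunitySpec(species=tuple(species), pools=dict(medium.pools), seed=0)


# ---------------------------------------------------------------------------
# randomized planted-rate communities
# ---------------------------------------------------------------------------


def random_planted_spec(
    seed: int, n_passages: int = 6, cycle_hours: float = 24.0, timestep: float = 0.2
) -> ToyCommunitySpec:
    """A randomized three-member community with planted limiting uptake rates.

    The dominant species is anchored on randomly chosen amino-acid pools; the
    two adjustable species each grow only on a private excess substrate, so
    their end-of-run biomass is exponential in their uptake rate across all
    passages.  Planted rates are drawn on the 0.001 mmol/gDW/h grid with the
    response slope (``total hours x yield``) placed in [55, 95] per unit
    rate, so the 95-105% acceptance band spans one to two finest decrements —
    steep enough that recovering the planted rate requires the 0.001 grid,
    wide enough that the grid cannot step over the band.
    """
    rng = np.random.default_rng(seed)
    aas = sorted(AMINO_ACIDS)
    anchor_aas = list(rng.choice(aas, size=3, replace=False))
    y_dom = rng.uniform(0.08, 0.15)

    total_hours = n_passages * cycle_hours
    dom = ToySpecies(
        species_id="DOM",
        substrate_yields={m: y_dom for m in anchor_aas},
        planted_rate=10.0,
        adjustable=False,
    )
    adjustables = []
    for name, substrate in (("MIN1", "sugar1"), ("MIN2", "sugar2")):
        y_e = rng.uniform(55.0, 95.0) / total_hours
        # end-of-run biomass target: well below the excess-pool pinning level
        # and a small fraction of the community, so the two adjustable
        # species' refinements barely perturb each other's denominator
        x_end = 10 ** rng.uniform(-4.9, -4.2)
        ln_gain = np.log(x_end / 3.9e-7) - (n_passages - 1) * np.log(0.1)
        rate = ln_gain / (total_hours * y_e)
        rate = round(round(rate / 0.001) * 0.001, 9)
        adjustables.append(
            ToySpecies(
                species_id=name,
                substrate_yields={substrate: y_e},
                planted_rate=rate,
            )
        )
    medium = build_medium(MediumSpec())
    pools = dict(medium.pools)
    pools["sugar1"] = 0.05
    pools["sugar2"] = 0.05
    return ToyCommunitySpec(
        species=(dom, *adjustables),
        pools=pools,
        transfer=TransferSpec(
            cycle_hours=cycle_hours, n_passages=n_passages, timestep=timestep
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# count series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountNoiseSpec:
    """Noise/sampling model for emulated CFU or qPCR assays.

    ``sampling_times`` are hours within each growth cycle; multiplicative
    lognormal noise with coefficient of variation ``cv`` (mean 1) is applied
    per replicate and counts are floored at ``detection_floor`` (counts/mL).
    """

    sampling_times: tuple[float, ...] = (0.0, 24.0, 48.0)
    replicates: int = 3
    cv: float = 0.1
    detection_floor: float = 1.0
    method: str = "CFU"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.method not in ("CFU", "qPCR"):
            raise ValueError("method must be CFU or qPCR")


def make_count_series(
    source: Sequence[Trajectory] | Trajectory | pd.DataFrame,
    noise: CountNoiseSpec,
    cells_per_gdw: float = CELLS_PER_GDW,
    volume_ml: float = 10.0,
):
    """Emulate replicate plate counts / qPCR from simulated biomass.

    ``source`` is one or more dFBA trajectories (sampled at the noise spec's
    within-cycle times) or a wide abundance table indexed by time (one column
    per species, e.g. a gLV simulation, sampled at every row).  Counts are
    ``biomass * cells_per_gdw / volume_ml`` (counts/mL) times lognormal noise
    with mean 1, floored at the detection floor.  Pure function of
    (source, spec): the spec's seed fixes the noise.
    """
    from .growth_stats import AbundanceTimeSeries

    rng = np.random.default_rng(noise.seed)
    rows: list[dict] = []

    if isinstance(source, pd.DataFrame):
        samples = [
            (float(t), None, {s: float(v) * cells_per_gdw / volume_ml for s, v in row.items()})
            for t, row in source.iterrows()
        ]
    else:
        trajs = [source] if isinstance(source, Trajectory) else list(source)
        samples = []
        for traj in trajs:
            t_start = float(traj.times[0])
            for t_rel in noise.sampling_times:
                # skip the duplicate cycle-start sample except in passage 0
                if t_rel == 0.0 and traj.passage_index > 0:
                    continue
                k = int(np.argmin(np.abs(traj.times - (t_start + t_rel))))
                samples.append(
                    (
                        float(traj.times[k]),
                        traj.passage_index,
                        {
                            s: float(traj.biomass[k, j]) * cells_per_gdw / volume_ml
                            for j, s in enumerate(traj.species_ids)
                        },
                    )
                )

    if noise.cv > 0:
        sigma = float(np.sqrt(np.log1p(noise.cv**2)))
        mu_ln = -0.5 * sigma**2  # mean-1 lognormal
    for t, passage, by_species in samples:
        for rep in range(1, noise.replicates + 1):
            for s, base in by_species.items():
                factor = (
                    float(rng.lognormal(mu_ln, sigma)) if noise.cv > 0 else 1.0
                )
                row = {
                    "species": s,
                    "time_h": t,
                    "replicate": rep,
                    "count": max(base * factor, noise.detection_floor),
                    "method": noise.method,
                }
                if passage is not None:
                    row["passage"] = passage
                rows.append(row)
    return AbundanceTimeSeries(pd.DataFrame(rows))
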