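"""Interspecies metabolite-exchange inference from dFBA trajectories.

Per-step exchange fluxes are integrated over an analysis window into total
secretion and uptake per (species, metabolite).  A directed edge
(producer, metabolite, consumer) is proposed whenever one species' integrated
secretion and another's integrated uptake of the same metabolite both exceed
a noise floor; the edge weight is the conservative bound
``min(secretion, uptake)`` (molecule-level attribution is ill-posed in a
well-mixed pool).  Edges whose metabolite is absent from the fresh medium
(zero pool, not unlimited) are flagged as *potential interspecies exchanges*;
metabolites the medium supplies (e.g. amino acids) still yield edges but are
not considered absolute interspecies exchanges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .community_dfba import Trajectory
from .medium import MediumState

__all__ = [
    "EDGE_EPSILON",
    "NetExchangeTable",
    "ExchangeEdge",
    "ExchangeNetwork",
    "integrate_exchanges",
    "infer_network",
    "monoculture_secretions",
]

#: noise floor (mmol) below LP tolerance leakage for edge existence
EDGE_EPSILON = 1e-9


@dataclass
class NetExchangeTable:
    """Integrated secretion/uptake per (species, metabolite) over a window."""

    table: pd.DataFrame  # columns: species, metabolite, secretion_mmol, uptake_mmol
    window: tuple[float, float]

    def secretion(self, species: str, metabolite: str) -> float:
        return self._lookup(species, metabolite, "secretion_mmol")

    def uptake(self, species: str, metabolite: str) -> float:
        return self._lookup(species, metabolite, "uptake_mmol")

    def _lookup(self, species: str, metabolite: str, col: str) -> float:
        sel = self.table[
            (self.table.species == species) & (self.table.metabolite == metabolite)
        ]
        return float(sel[col].iloc[0]) if len(sel) else 0.0


@dataclass(frozen=True)
class ExchangeEdge:
    producer: str
    metabolite: str
    consumer: str
    mmol: float
    medium_absent: bool


@dataclass
class ExchangeNetwork:
    edges: list[ExchangeEdge]
    dangling_secretions: list[tuple[str, str]] = field(default_factory=list)

    def edge_set(self, medium_absent_only: bool = False) -> set[tuple[str, str, str]]:
        return {
            (e.producer, e.metabolite, e.consumer)
            for e in self.edges
            if e.medium_absent or not medium_absent_only
        }

    def to_frame(self, monoculture: dict[tuple[str, str], bool] | None = None) -> pd.DataFrame:
        rows = []
        for e in self.edges:
            row = {
                "producer": e.producer,
                "metabolite": e.metabolite,
                "consumer": e.consumer,
                "mmol": e.mmol,
                "medium_absent": e.medium_absent,
            }
            if monoculture is not None:
                row["secreted_in_monoculture"] = monoculture.get(
                    (e.producer, e.metabolite), False
                )
            rows.append(row)
        return pd.DataFrame(
            rows,
            columns=["producer", "metabolite", "consumer", "mmol", "medium_absent"]
            + (["secreted_in_monoculture"] if monoculture is not None else []),
        )

    def to_graph(self) -> nx.MultiDiGraph:
        """Species-level multigraph for visualization/export (GraphML-safe)."""
        g = nx.MultiDiGraph()
        for e in self.edges:
            g.add_edge(
                e.producer,
                e.consumer,
                key=e.metabolite,
                metabolite=e.metabolite,
                mmol=e.mmol,
                medium_absent=e.medium_absent,
            )
        for species, met in self.dangling_secretions:
            g.add_node(species)
        return g


def integrate_exchanges(
    trajectories: Trajectory | Sequence[Trajectory],
    window: tuple[float, float] | None = None,
) -> NetExchangeTable:
    """Integrate per-step exchange fluxes into mmol totals over ``window``.

    ``secretion = sum over steps of max(flux, 0) * biomass * dt`` and
    analogously for uptake with ``max(-flux, 0)``; biomass is the
    start-of-step value, matching the simulator's pool bookkeeping exactly.
    Accepts one trajectory or a sequence (e.g. all six passages).
    """
    trajs = [trajectories] if isinstance(trajectories, Trajectory) else list(trajectories)
    if not trajs:
        raise ValueError("no trajectories given")
    t_min = min(float(t.times[0]) for t in trajs)
    t_max = max(float(t.times[-1]) for t in trajs)
    if window is None:
        window = (t_min, t_max)
    t0, t1 = window
    if not (t_min <= t0 < t1 <= t_max):
        raise ValueError(f"empty or out-of-span window {window} for span ({t_min}, {t_max})")

    acc: dict[tuple[str, str], list[float]] = {}
    for traj in trajs:
        dt = traj.timestep
        n_steps = traj.exchange_flux.shape[0]
        for k in range(n_steps):
            t = float(traj.times[k])
            if t < t0 - 1e-12 or t >= t1 - 1e-12:
                continue
            for j, species in enumerate(traj.species_ids):
                x = traj.biomass[k, j]
                if x == 0.0:
                    continue
                row = traj.exchange_flux[k, j]
                for m_idx, flux in enumerate(row):
                    if flux == 0.0:
                        continue
                    key = (species, traj.exchange_met_ids[m_idx])
                    cell = acc.setdefault(key, [0.0, 0.0])
                    amount = abs(flux) * x * dt
                    if flux > 0:
                        cell[0] += amount
                    else:
                        cell[1] += amount

    rows = [
        {"species": s, "metabolite": m, "secretion_mmol": v[0], "uptake_mmol": v[1]}
        for (s, m), v in sorted(acc.items())
    ]
    table = pd.DataFrame(
        rows, columns=["species", "metabolite", "secretion_mmol", "uptake_mmol"]
    )
    return NetExchangeTable(table=table, window=(t0, t1))


def infer_network(
    table: NetExchangeTable,
    fresh: MediumState,
    epsilon: float = EDGE_EPSILON,
) -> ExchangeNetwork:
    """Classify integrated exchanges into a directed cross-feeding network."""
    df = table.table
    edges: list[ExchangeEdge] = []
    producers = df[df.secretion_mmol > epsilon]
    consumers = df[df.uptake_mmol > epsilon]
    consumed_mets: set[str] = set(consumers.metabolite)
    for _, prod in producers.iterrows():
        m = prod.metabolite
        absent = fresh.pool(m) == 0.0 and m not in fresh.unlimited_ids
        for _, cons in consumers[consumers.metabolite == m].iterrows():
            if cons.species == prod.species:
                continue
            edges.append(
                ExchangeEdge(
                    producer=prod.species,
                    metabolite=m,
                    consumer=cons.species,
                    mmol=float(min(prod.secretion_mmol, cons.uptake_mmol)),
                    medium_absent=absent,
                )
            )
    dangling = [
        (r.species, r.metabolite)
        for _, r in producers.iterrows()
        if r.metabolite not in consumed_mets
        or not any(
            c.species != r.species
            for _, c in consumers[consumers.metabolite == r.metabolite].iterrows()
        )
    ]
    return ExchangeNetwork(edges=edges, dangling_secretions=sorted(dangling))


def monoculture_secretions(
    species_configs,
    transfer,
    fresh: MediumState,
    epsilon: float = EDGE_EPSILON,
) -> dict[tuple[str, str], bool]:
    """Whether each (species, metabolite) secretion also occurs in monoculture.

    Runs each species alone under identical settings — the check that
    community secretions are not emergent fluxes of co-culture.
    """
    from .community_dfba import run_serial_transfer

    out: dict[tuple[str, str], bool] = {}
    for cfg in species_configs:
        trajs = run_serial_transfer([cfg], transfer, fresh)
        mono = integrate_exchanges(trajs)
        for _, row in mono.table.iterrows():
            out[(row.species, row.metabolite)] = bool(row.secretion_mmol > epsilon)
    return out
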