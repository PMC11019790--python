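"""Coarse-to-fine search over limiting-nutrient uptake rates.

The search drives the simulated end-of-run community composition into a
95%-105% band around a reference composition (e.g. the qPCR-measured
stabilized community).  Phase 1 sweeps every adjustable species' limiting
uptake rate down *jointly* — from the start rate in coarse steps to the
coarse floor, then in mid steps — evaluating the full serial-transfer
simulation after every move, and stops as soon as any adjustable species'
achieved/reference ratio falls below the band.  Phase 2 then refines each
adjustable species separately: its rate is restored to the last value before
the undershoot and descended again with the next finer decrement, finishing
with the finest decrement, until its ratio sits inside the band.  Because
adjusting one species shifts every other species' fraction through the
common denominator, phase 2 makes repeated passes (most abundant adjustable
first) and a species pushed back out of the band re-enters its refinement,
climbing on its current grid when it was pushed below the band.

All rates ever evaluated lie on the grid generated by the decrement
schedule; the evaluation count is capped by ``max_evaluations``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .community_dfba import SpeciesConfig, TransferSpec, run_serial_transfer
from .medium import MediumState

__all__ = [
    "ReferenceComposition",
    "CalibrationSchedule",
    "CalibrationResult",
    "evaluate",
    "calibrate",
]


@dataclass(frozen=True)
class ReferenceComposition:
    """Target final biomass fractions (sum to 1), e.g. from ratio 1.0:0.126:0.013."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fractions", dict(self.fractions))
        if any(f <= 0 for f in self.fractions.values()):
            raise ValueError("reference fractions must be positive")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"reference fractions must sum to 1, got {total}")

    @classmethod
    def from_ratio(
        cls, species_ids: Sequence[str], ratio: Sequence[float] | str
    ) -> "ReferenceComposition":
        """Build from a ratio such as ``"1.0:0.126:0.013"`` or ``[1, 0.126, 0.013]``."""
        if isinstance(ratio, str):
            parts = [float(x) for x in ratio.split(":")]
        else:
            parts = [float(x) for x in ratio]
        if len(parts) != len(species_ids):
            raise ValueError("ratio length does not match species count")
        total = sum(parts)
        return cls({s: p / total for s, p in zip(species_ids, parts)})

    @property
    def dominant(self) -> str:
        return max(self.fractions, key=self.fractions.get)  # type: ignore[arg-type]


@dataclass(frozen=True)
class CalibrationSchedule:
    """Decrement grid and acceptance band for the rate search."""

    start_rate: float = 10.0
    coarse_step: float = 1.0
    mid_step: float = 0.1
    fine_steps: tuple[float, ...] = (0.01, 0.001)
    coarse_floor: float = 1.0
    acceptance_band: tuple[float, float] = (0.95, 1.05)
    adjustable_species: tuple[str, ...] | None = None
    max_evaluations: int = 500

    def __post_init__(self) -> None:
        steps = (self.coarse_step, self.mid_step, *self.fine_steps)
        if any(b <= a for a, b in zip(steps[1:], steps)) is False:
            pass
        if not all(a > b for a, b in zip(steps, steps[1:])):
            raise ValueError("decrement steps must be strictly decreasing")
        lo, hi = self.acceptance_band
        if not lo < 1 < hi:
            raise ValueError("acceptance band must contain 1")

    @property
    def all_steps(self) -> tuple[float, ...]:
        return (self.coarse_step, self.mid_step, *self.fine_steps)


@dataclass
class CalibrationResult:
    rates: dict[str, float]
    achieved_fractions: dict[str, float]
    band_ratios: dict[str, float]
    n_simulations: int
    converged: bool
    evaluation_log: list[dict] = field(default_factory=list)
    diagnostic: str = ""

    def log_frame(self):
        import pandas as pd

        rows = []
        for entry in self.evaluation_log:
            row = {f"rate_{s}": r for s, r in entry["rates"].items()}
            row.update({f"fraction_{s}": f for s, f in entry["fractions"].items()})
            rows.append(row)
        return pd.DataFrame(rows)


def evaluate(
    rates: Mapping[str, float],
    species_configs: Sequence[SpeciesConfig],
    transfer: TransferSpec,
    fresh: MediumState,
) -> dict[str, float]:
    """Run the full serial-transfer simulation at the given limiting uptake
    rates and return end-of-last-passage biomass fractions."""
    if any(r <= 0 for r in rates.values()):
        raise ValueError("uptake rates must be positive")
    configs = [
        c.with_rate(rates[c.species_id]) if c.species_id in rates else c
        for c in species_configs
    ]
    trajectories = run_serial_transfer(configs, transfer, fresh)
    return trajectories[-1].final_state().fractions()


def calibrate(
    species_configs: Sequence[SpeciesConfig],
    transfer: TransferSpec,
    fresh: MediumState,
    reference: ReferenceComposition,
    schedule: CalibrationSchedule = CalibrationSchedule(),
    evaluate_fn: Callable[[Mapping[str, float]], dict[str, float]] | None = None,
) -> CalibrationResult:
    """Calibrate limiting-carbon uptake rates to a reference composition.

    ``evaluate_fn`` may replace the simulator (used in unit tests with
    analytic response surfaces); by default :func:`evaluate` is used.
    """
    species_ids = [c.species_id for c in species_configs]
    missing = set(reference.fractions) - set(species_ids)
    if missing:
        raise KeyError(f"reference species absent from configs: {sorted(missing)}")

    if schedule.adjustable_species is not None:
        adjustable = list(schedule.adjustable_species)
    else:
        adjustable = [s for s in species_ids if s != reference.dominant]
    # most abundant adjustable first: its placement perturbs the others least
    adjustable.sort(key=lambda s: reference.fractions.get(s, 0.0), reverse=True)

    lo, hi = schedule.acceptance_band
    # adjustable species start at the schedule's start rate; every other
    # species keeps its configured limiting uptake rate throughout
    rates = {c.species_id: c.limiting_uptake_rate for c in species_configs}
    for s in adjustable:
        rates[s] = schedule.start_rate
    log: list[dict] = []
    n_eval = 0

    if evaluate_fn is None:
        def evaluate_fn(r: Mapping[str, float]) -> dict[str, float]:
            return evaluate(r, species_configs, transfer, fresh)

    def run(current: Mapping[str, float]) -> dict[str, float]:
        nonlocal n_eval
        n_eval += 1
        fractions = evaluate_fn(dict(current))
        log.append({"rates": dict(current), "fractions": dict(fractions)})
        return fractions

    def ratios(fractions: Mapping[str, float]) -> dict[str, float]:
        return {s: fractions[s] / reference.fractions[s] for s in reference.fractions}

    def in_band(r: Mapping[str, float]) -> bool:
        return all(lo <= v <= hi for v in r.values())

    def result(fractions, band, converged, diagnostic="") -> CalibrationResult:
        return CalibrationResult(
            rates=dict(rates),
            achieved_fractions=dict(fractions),
            band_ratios=dict(band),
            n_simulations=n_eval,
            converged=converged,
            evaluation_log=log,
            diagnostic=diagnostic,
        )

    fractions = run(rates)
    band = ratios(fractions)
    if in_band(band):
        return result(fractions, band, True)
    if not adjustable:
        return result(fractions, band, False, "no adjustable species")

    # ---- phase 1: joint sweep (coarse to the floor, then mid steps) -------
    prev_rate = schedule.start_rate
    undershot = False
    while n_eval < schedule.max_evaluations and not undershot:
        current = rates[adjustable[0]] if adjustable else schedule.start_rate
        step_size = (
            schedule.coarse_step if current > schedule.coarse_floor else schedule.mid_step
        )
        new_rate = round(current - step_size, 9)
        if new_rate <= 0:
            return result(
                fractions, band, False, "joint sweep exhausted the rate grid"
            )
        prev_rate = current
        for s in adjustable:
            rates[s] = new_rate
        fractions = run(rates)
        band = ratios(fractions)
        if in_band(band):
            return result(fractions, band, True)
        undershot = any(band[s] < lo for s in adjustable)

    # ---- phase 2: per-species refinement with the finer decrements --------
    # start each adjustable species from the last value before the undershoot
    restart = {
        s: (prev_rate if band[s] < lo else rates[s]) for s in adjustable
    }
    # remaining step sizes per species, coarsest first
    joint_step = schedule.coarse_step if prev_rate > schedule.coarse_floor else schedule.mid_step
    finer = [st for st in schedule.all_steps if st < joint_step]
    step_idx = {s: 0 for s in adjustable}
    for s in adjustable:
        rates[s] = restart[s]

    if not finer:
        return result(fractions, band, False, "decrement schedule exhausted")

    def refine(s: str) -> bool:
        """Place species ``s`` inside the band by descending its own grid.

        Returns True if any rate move was made.  Uses the current ``band``
        (from the most recent evaluation) and keeps it up to date.
        """
        nonlocal fractions, band
        moved = False
        while n_eval < schedule.max_evaluations:
            r = band[s]
            if lo <= r <= hi:
                return moved
            step_size = finer[step_idx[s]]
            if r > hi:
                new_rate = round(rates[s] - step_size, 9)
                if new_rate <= 0:
                    return moved
            else:
                # undershoot: back up one step and continue on the finer grid
                new_rate = round(rates[s] + step_size, 9)
                if step_idx[s] < len(finer) - 1:
                    step_idx[s] += 1
                elif moved_up.get(s):
                    # oscillating on the finest grid: band narrower than step
                    return moved
                moved_up[s] = True
            rates[s] = new_rate
            moved = True
            fractions = run(rates)
            band = ratios(fractions)
        return moved

    moved_up: dict[str, bool] = {}
    while n_eval < schedule.max_evaluations:
        if in_band(band):
            return result(fractions, band, True)
        moved_up = {}
        progressed = False
        for s in adjustable:
            progressed |= refine(s)
            if in_band(band):
                return result(fractions, band, True)
        if not progressed:
            return result(
                fractions,
                band,
                False,
                "refinement stalled: acceptance band unreachable on the grid "
                "(non-monotone response or band narrower than the finest step)",
            )

    warnings.warn("calibration hit max_evaluations without converging", RuntimeWarning)
    return result(fractions, band, False, "max_evaluations reached")
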