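"""End-to-end reproduction experiments on the synthetic community.

Each function runs one headline experiment from scratch — building the toy
community, simulating, calibrating — and returns plain numbers:

* ``calibration_experiment``: calibrate the three-member community to the
  qPCR-measured stabilized composition 1.0 : 0.126 : 0.013 and report the
  achieved band ratios and the final YR343:GM17 biomass ratio.
* ``convergence_experiment``: start the calibrated community once with equal
  inocula and once with the dominant member 1,000-fold diluted, and report
  the first passage at whose end the two compositions agree within 5% per
  species.
* ``dilution_experiment``: measure the factor by which the serial-transfer
  operator scales each species' biomass.
"""

from __future__ import annotations

from dataclasses import dataclass

from .calibration import (
    CalibrationResult,
    CalibrationSchedule,
    ReferenceComposition,
    calibrate,
)
from .community_dfba import (
    CommunityState,
    SpeciesConfig,
    TransferSpec,
    dilute,
    run_serial_transfer,
)
from .medium import MediumState
from .synthetic_data import three_member_spec, make_toy_community

__all__ = [
    "REFERENCE_RATIO",
    "CalibratedCommunity",
    "calibration_experiment",
    "convergence_experiment",
    "dilution_experiment",
]

#: the qPCR-measured stabilized composition (GM17 : YR343 : AP49)
REFERENCE_RATIO = "1.0:0.126:0.013"

#: 1,000-fold-diluted inoculum, g dry mass
DILUTED_INOCULUM = 3.9e-10


@dataclass
class CalibratedCommunity:
    configs: list[SpeciesConfig]
    fresh: MediumState
    transfer: TransferSpec
    reference: ReferenceComposition
    result: CalibrationResult

    @property
    def species_ids(self) -> list[str]:
        return [c.species_id for c in self.configs]


def calibration_experiment(
    schedule: CalibrationSchedule | None = None,
) -> CalibratedCommunity:
    """Calibrate the default three-member community to the reference ratio."""
    spec = three_member_spec()
    configs, fresh = make_toy_community(spec)
    reference = ReferenceComposition.from_ratio(
        [c.species_id for c in configs], REFERENCE_RATIO
    )
    result = calibrate(
        configs, spec.transfer, fresh, reference, schedule or CalibrationSchedule()
    )
    calibrated = [c.with_rate(result.rates[c.species_id]) for c in configs]
    return CalibratedCommunity(
        configs=calibrated,
        fresh=fresh,
        transfer=spec.transfer,
        reference=reference,
        result=result,
    )


def convergence_experiment(
    community: CalibratedCommunity,
    diluted_species: str = "GM17",
    tolerance: float = 0.05,
) -> dict:
    """First passage at which the 1,000-fold-diluted run matches the
    equal-inoculum run's composition within ``tolerance`` per species
    (relative difference of biomass fractions at the passage end)."""
    equal = run_serial_transfer(community.configs, community.transfer, community.fresh)
    diluted = run_serial_transfer(
        community.configs,
        community.transfer,
        community.fresh,
        initial_biomass={diluted_species: DILUTED_INOCULUM},
    )
    deviations = []
    converged_at = None
    for p, (a, b) in enumerate(zip(equal, diluted)):
        fa, fb = a.final_state().fractions(), b.final_state().fractions()
        dev = max(abs(fb[s] - fa[s]) / fa[s] for s in fa)
        deviations.append(dev)
        if converged_at is None and dev < tolerance:
            converged_at = p
    return {
        "converged_at_passage": converged_at,
        "per_passage_max_deviation": deviations,
        "equal_final_fractions": equal[-1].final_state().fractions(),
        "diluted_final_fractions": diluted[-1].final_state().fractions(),
    }


def dilution_experiment(community: CalibratedCommunity | None = None) -> dict:
    """Measure the biomass scaling applied by one serial-transfer event."""
    if community is None:
        spec = three_member_spec()
        configs, fresh = make_toy_community(spec)
        transfer = spec.transfer
    else:
        configs, fresh, transfer = (
            community.configs,
            community.fresh,
            community.transfer,
        )
    before = CommunityState(
        biomass={c.species_id: 1e-3 * (i + 1) for i, c in enumerate(configs)},
        medium=fresh,
    )
    after = dilute(before, transfer, fresh)
    factors = {s: after.biomass[s] / before.biomass[s] for s in before.biomass}
    return {"factors": factors, "dilution_factor": transfer.dilution_factor}
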