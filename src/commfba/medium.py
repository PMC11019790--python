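"""Shared extracellular environment construction and serial-transfer mixing.

The nutrient-rich medium is modelled as finite molar pools for the limiting
carbon sources (glucose plus amino acids) and an unlimited set for everything
else (inorganic ions, gases, growth factors).  Amino acids are assumed to be
equally distributed by weight across the peptide-derived components (peptone,
casamino acids, yeast extract); each listed amino acid receives an equal mass
share which is converted to mmol by its molecular weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "R2A_COMPONENTS",
    "PEPTIDE_COMPONENTS",
    "GLUCOSE_MW",
    "MediumSpec",
    "MediumState",
    "build_medium",
    "refresh_mix",
]

#: the 20 proteinogenic amino acids with molecular weights (g/mol)
AMINO_ACIDS: dict[str, float] = {
    "ala": 89.09,
    "arg": 174.20,
    "asn": 132.12,
    "asp": 133.10,
    "cys": 121.16,
    "gln": 146.15,
    "glu": 147.13,
    "gly": 75.07,
    "his": 155.15,
    "ile": 131.17,
    "leu": 131.17,
    "lys": 146.19,
    "met": 149.21,
    "phe": 165.19,
    "pro": 115.13,
    "ser": 105.09,
    "thr": 119.12,
    "trp": 204.23,
    "tyr": 181.19,
    "val": 117.15,
}

GLUCOSE_MW = 180.16  # g/mol

#: standard R2A recipe, g/L (overridable in any spec)
R2A_COMPONENTS: dict[str, float] = {
    "proteose peptone": 0.5,
    "casamino acids": 0.5,
    "yeast extract": 0.5,
    "glucose": 0.5,
    "soluble starch": 0.5,
    "sodium pyruvate": 0.3,
    "K2HPO4": 0.3,
    "MgSO4": 0.05,
}

#: components whose mass is treated as amino-acid material
PEPTIDE_COMPONENTS = ("proteose peptone", "peptone", "casamino acids", "yeast extract")

#: default unlimited metabolites (ions, gases, growth factors)
DEFAULT_UNLIMITED = frozenset({"o2", "h2o", "h", "nh4", "pi", "so4", "k", "mg2"})


@dataclass(frozen=True)
class MediumSpec:
    """Recipe for the fresh medium.

    ``component_masses`` is in g/L.  Glucose and the amino acids (derived from
    the peptide components) become finite limiting pools; everything in
    ``unlimited_ids`` is never depleted; remaining components (e.g. starch,
    pyruvate, salts) are ignored unless listed as unlimited.
    """

    component_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(R2A_COMPONENTS)
    )
    amino_acid_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(AMINO_ACIDS)
    )
    amino_acid_list: Sequence[str] = field(
        default_factory=lambda: tuple(sorted(AMINO_ACIDS))
    )
    unlimited_ids: frozenset[str] = DEFAULT_UNLIMITED
    volume_ml: float = 10.0
    glucose_id: str = "glc"
    glucose_mw: float = GLUCOSE_MW

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("volume must be positive")
        for name, mass in self.component_masses.items():
            if mass < 0:
                raise ValueError(f"negative mass for component {name!r}")
        peptide_mass = sum(
            self.component_masses.get(c, 0.0) for c in PEPTIDE_COMPONENTS
        )
        if peptide_mass > 0 and not self.amino_acid_list:
            raise ValueError(
                "amino_acid_list must be non-empty when peptide components "
                "have nonzero mass"
            )


@dataclass(frozen=True)
class MediumState:
    """Finite molar pools (mmol) plus the unlimited-id set, at fixed volume."""

    pools: Mapping[str, float]
    unlimited_ids: frozenset[str]
    volume_ml: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pools", dict(self.pools))
        bad = [m for m, v in self.pools.items() if v < 0]
        if bad:
            raise ValueError(f"negative pools: {bad}")
        overlap = set(self.pools) & self.unlimited_ids
        if overlap:
            raise ValueError(f"unlimited metabolites may not carry pools: {sorted(overlap)}")

    def pool(self, metabolite_id: str) -> float:
        return self.pools.get(metabolite_id, 0.0)

    def with_pools(self, pools: Mapping[str, float]) -> "MediumState":
        return replace(self, pools=dict(pools))

    def to_frame(self) -> pd.DataFrame:
        """Dump as a tidy (metabolite, mmol) table."""
        return pd.DataFrame(
            sorted(self.pools.items()), columns=["metabolite", "mmol"]
        )


def build_medium(spec: MediumSpec) -> MediumState:
    """Construct the fresh-medium state from a recipe.

    Glucose pool = (g/L) / MW * volume(L) * 1000 mmol.  The total
    peptide-component mass is split equally (by weight) over the amino-acid
    list and converted per amino acid by its molecular weight.
    """
    litres = spec.volume_ml / 1000.0
    pools: dict[str, float] = {}

    glc_mass = spec.component_masses.get("glucose", 0.0)
    pools[spec.glucose_id] = glc_mass / spec.glucose_mw * litres * 1000.0

    peptide_mass = sum(spec.component_masses.get(c, 0.0) for c in PEPTIDE_COMPONENTS)
    if spec.amino_acid_list:
        share = peptide_mass / len(spec.amino_acid_list)  # g/L per amino acid
        for aa in spec.amino_acid_list:
            if aa not in spec.amino_acid_weights:
                raise KeyError(f"no molecular weight for amino acid {aa!r}")
            pools[aa] = share / spec.amino_acid_weights[aa] * litres * 1000.0

    return MediumState(
        pools=pools,
        unlimited_ids=frozenset(spec.unlimited_ids),
        volume_ml=spec.volume_ml,
    )


def refresh_mix(
    current: MediumState, fresh: MediumState, transfer_fraction: float
) -> MediumState:
    """Mix a transferred culture into fresh medium.

    ``pools = f * current + (1 - f) * fresh`` for transfer fraction ``f``.
    Metabolites absent from one side (e.g. secreted byproducts not present in
    fresh medium) are treated as 0 mmol there; the unlimited sets and volumes
    must agree.
    """
    if not 0 < transfer_fraction <= 1:
        raise ValueError("transfer_fraction must be in (0, 1]")
    if current.unlimited_ids != fresh.unlimited_ids:
        raise ValueError("mismatched unlimited-metabolite sets")
    if current.volume_ml != fresh.volume_ml:
        raise ValueError("mismatched volumes")
    f = transfer_fraction
    keys = set(current.pools) | set(fresh.pools)
    mixed = {m: f * current.pool(m) + (1 - f) * fresh.pool(m) for m in keys}
    return MediumState(
        pools=mixed, unlimited_ids=current.unlimited_ids, volume_ml=current.volume_ml
    )
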