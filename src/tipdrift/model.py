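"""Reaction-model containers: species, mass-action reactions, conserved moieties.

A :class:`ReactionModel` is pure data — species with compartments and diffusion
constants, mass-action reactions (molecularity <= 2) with an optional
membrane-only region restriction, declared conserved moieties, and a parameter
table.  Units are fixed package-wide: micrometres, seconds, molecules.
Bimolecular rate constants are volumetric (um^3/s) for cytosol-cytosol
reactions and areal (um^2/s) for membrane-membrane or mixed membrane-cytosol
reactions executed in membrane voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = ["SpeciesSpec", "ReactionSpec", "ReactionModel", "AVOGADRO_UM"]

# molecules per micromolar per cubic micrometre: N_A * 1e-6 mol/L * 1e-15 L/um^3
AVOGADRO_UM = 602.214076


def molar_to_mesoscopic(k_per_molar_s: float, molarity: str = "uM") -> float:
    """Convert a bimolecular rate constant from 1/(M s)-style units to um^3/s.

    ``molarity`` selects the concentration unit of the input ('M' or 'uM').
    """
    if molarity == "uM":
        return k_per_molar_s / AVOGADRO_UM
    if molarity == "M":
        return k_per_molar_s / (AVOGADRO_UM * 1e6)
    raise ValueError(f"unknown molarity unit {molarity!r}")


@dataclass(frozen=True)
class SpeciesSpec:
    """A chemical species with its compartment and diffusion constants."""

    name: str
    compartment: str  # 'membrane' | 'cytoplasm'
    D_cyt: float = 0.0  # um^2/s, cytoplasmic (volume) diffusion
    D_mem: float = 0.0  # um^2/s, lateral surface diffusion

    def __post_init__(self):
        if self.compartment not in ("membrane", "cytoplasm"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.D_cyt < 0 or self.D_mem < 0:
            raise ValueError("diffusion constants must be >= 0")
        if self.compartment == "membrane" and self.D_cyt != 0:
            raise ValueError("membrane species must have D_cyt = 0")
        if self.compartment == "cytoplasm" and self.D_mem != 0:
            raise ValueError("cytoplasmic species must have D_mem = 0")


@dataclass(frozen=True)
class ReactionSpec:
    """One mass-action reaction.

    ``field`` optionally names a static per-voxel scalar field that multiplies
    the propensity (used for the frozen active-Cdc42 drive and similar external
    inputs).
    """

    name: str
    reactants: tuple  # ((species, count), ...)
    products: tuple
    rate: float
    region: str = "membrane_only"  # 'membrane_only' | 'everywhere'
    field: Optional[str] = None

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError(f"reaction {self.name}: rate must be >= 0")
        if self.region not in ("membrane_only", "everywhere"):
            raise ValueError(f"reaction {self.name}: bad region {self.region!r}")
        if self.order > 2:
            raise ValueError(f"reaction {self.name}: molecularity > 2 not supported")

    @property
    def order(self) -> int:
        return sum(c for _, c in self.reactants)

    def net_change(self) -> dict[str, int]:
        delta: dict[str, int] = {}
        for s, c in self.reactants:
            delta[s] = delta.get(s, 0) - c
        for s, c in self.products:
            delta[s] = delta.get(s, 0) + c
        return {s: d for s, d in delta.items() if d != 0}


@dataclass
class ReactionModel:
    """Species, reactions, conserved moieties and parameters of one model."""

    name: str
    species: list  # [SpeciesSpec]
    reactions: list  # [ReactionSpec]
    moieties: dict = field(default_factory=dict)  # name -> set of species names
    parameters: dict = field(default_factory=dict)
    initial_totals: dict = field(default_factory=dict)  # species -> int copies
    # species split used by polarized initial conditions (membrane species in
    # the cap, cytosolic remainder scattered); falls back to initial_totals
    initial_totals_polarized: dict = field(default_factory=dict)
    fields: dict = field(default_factory=dict)  # field name -> (K,) array

    def __post_init__(self):
        self.validate()

    @property
    def S(self) -> int:
        return len(self.species)

    @property
    def M(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def spec_of(self, name: str) -> SpeciesSpec:
        return self.species[self.species_index(name)]

    def validate(self) -> None:
        names = self.species_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        for r in self.reactions:
            for s, c in r.reactants + r.products:
                if s not in names:
                    raise ValueError(f"reaction {r.name}: unknown species {s!r}")
                if c < 1:
                    raise ValueError(f"reaction {r.name}: stoichiometry must be >= 1")
        for mname, members in self.moieties.items():
            unknown = set(members) - set(names)
            if unknown:
                raise ValueError(f"moiety {mname}: unknown species {sorted(unknown)}")
            for r in self.reactions:
                net = sum(d for s, d in r.net_change().items() if s in members)
                if net != 0:
                    raise ValueError(
                        f"moiety {mname} is not conserved by reaction {r.name} "
                        f"(net change {net})"
                    )
        for totals in (self.initial_totals, self.initial_totals_polarized):
            for s, n in totals.items():
                if s not in names:
                    raise ValueError(f"initial total for unknown species {s!r}")
                if int(n) != n or n < 0:
                    raise ValueError(
                        f"initial total for {s} must be a nonnegative integer")
        if self.initial_totals and self.initial_totals_polarized:
            for mname, members in self.moieties.items():
                a = sum(v for s, v in self.initial_totals.items() if s in members)
                b = sum(v for s, v in self.initial_totals_polarized.items()
                        if s in members)
                if a != b:
                    raise ValueError(
                        f"moiety {mname}: polarized initial totals ({b}) differ "
                        f"from scattered totals ({a})")

    def moiety_matrix(self) -> np.ndarray:
        """0/1 matrix (n_moieties x S) selecting the species of each moiety."""
        mat = np.zeros((len(self.moieties), self.S), dtype=np.int64)
        for k, members in enumerate(self.moieties.values()):
            for s in members:
                mat[k, self.species_index(s)] = 1
        return mat

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            "name": self.name,
            "species": [
                {
                    "name": s.name,
                    "compartment": s.compartment,
                    "D_cyt": s.D_cyt,
                    "D_mem": s.D_mem,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "name": r.name,
                    "reactants": [list(x) for x in r.reactants],
                    "products": [list(x) for x in r.products],
                    "rate": r.rate,
                    "region": r.region,
                    **({"field": r.field} if r.field else {}),
                }
                for r in self.reactions
            ],
            "moieties": {k: sorted(v) for k, v in self.moieties.items()},
            "parameters": dict(self.parameters),
            "initial_totals": {k: int(v) for k, v in self.initial_totals.items()},
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ReactionModel":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            name=data["name"],
            species=[SpeciesSpec(**s) for s in data["species"]],
            reactions=[
                ReactionSpec(
                    name=r["name"],
                    reactants=tuple((s, int(c)) for s, c in r["reactants"]),
                    products=tuple((s, int(c)) for s, c in r["products"]),
                    rate=float(r["rate"]),
                    region=r.get("region", "membrane_only"),
                    field=r.get("field"),
                )
                for r in data["reactions"]
            ],
            moieties={k: set(v) for k, v in data.get("moieties", {}).items()},
            parameters=data.get("parameters", {}),
            initial_totals=data.get("initial_totals", {}),
        )
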