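"""Per-molecule electronic-structure records.

The interchange document is a JSON object per molecule::

    {
      "molecule_id": "mol-1",
      "units": {"energy": "eV", "length": "angstrom"},
      "level_tag": "ZINDO/1",
      "atoms": [{"index": 1, "element": "C", "mass": 12.011,
                 "xyz": [0.0, 0.0, 0.0], "net_charge": -0.12}, ...],
      "mos": [{"energy": -10.0, "occupied": true,
               "populations": {"1": 0.6, "2": 0.4}}, ...]
    }

Energies are stored internally in eV, lengths in angstrom, masses in amu.
A ``hartree`` (or ``au``) energy tag converts eigenvalues on load.

Raw per-MO electron populations may carry Mulliken artefacts: negative
values and values that do not sum to one. :func:`normalize_populations`
clamps negatives, zeroes populations at or below a threshold (default
0.01 e) and rescales each MO to unit total, recording every correction.
All index computation downstream assumes a normalized structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import DegenerateMOError, OrderingError, SchemaError

HARTREE_TO_EV = 27.2114

#: Electron populations at or below this value (in e) are treated as zero.
DEFAULT_POPULATION_THRESHOLD = 0.01


@dataclass(frozen=True)
class AtomRecord:
    """One atom: 1-based ordinal, element symbol, mass (amu),
    Cartesian coordinates (angstrom) and net charge Q (e, signed)."""

    index: int
    element: str
    mass: float
    coords: tuple[float, float, float]
    net_charge: float = 0.0

    def __post_init__(self):
        if self.mass <= 0:
            raise SchemaError(
                f"atom {self.index}: mass must be positive, got {self.mass}"
            )
        if len(self.coords) != 3:
            raise SchemaError(f"atom {self.index}: coords must be a triplet")


@dataclass(frozen=True)
class MolecularOrbital:
    """One MO: eigenvalue (eV), occupancy flag and the per-atom electron
    populations of this MO, keyed by 1-based atom index.

    After normalization the populations of each retained MO are
    nonnegative and sum to one; they are then the Fukui indices F(i, m).
    """

    energy: float
    occupied: bool
    populations: Mapping[int, float]

    def population(self, atom_index: int) -> float:
        return self.populations.get(atom_index, 0.0)


@dataclass(frozen=True)
class ElectronicStructure:
    """A molecule's atoms and MO spectrum, energy-ordered.

    Invariants enforced at construction: at least one occupied and one
    empty MO; energies ascending; every occupied MO below every empty MO;
    unique atom indices.
    """

    molecule_id: str
    atoms: Sequence[AtomRecord]
    mos: Sequence[MolecularOrbital]
    level_tag: str = "synthetic"
    normalized: bool = False
    corrections: tuple = field(default_factory=tuple, compare=False)

    def __post_init__(self):
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise SchemaError(
                f"{self.molecule_id}: duplicate atom indices in atom list"
            )
        occ = [mo for mo in self.mos if mo.occupied]
        emp = [mo for mo in self.mos if not mo.occupied]
        if not occ or not emp:
            raise SchemaError(
                f"{self.molecule_id}: need at least one occupied and one "
                f"empty MO (got {len(occ)} occupied, {len(emp)} empty)"
            )
        energies = [mo.energy for mo in self.mos]
        if any(b < a for a, b in zip(energies, energies[1:])):
            raise OrderingError(
                f"{self.molecule_id}: MO energies are not sorted ascending"
            )
        highest_occ = max(mo.energy for mo in occ)
        lowest_emp = min(mo.energy for mo in emp)
        seen_empty = False
        for mo in self.mos:
            if not mo.occupied:
                seen_empty = True
            elif seen_empty:
                raise OrderingError(
                    f"{self.molecule_id}: occupied MO at {mo.energy} eV lies "
                    f"above an empty MO (highest occupied {highest_occ}, "
                    f"lowest empty {lowest_emp})"
                )

    @property
    def mass_total(self) -> float:
        """Molecular mass M (amu): sum of atomic masses."""
        return sum(a.mass for a in self.atoms)

    @property
    def atom_indices(self) -> list[int]:
        return [a.index for a in self.atoms]

    def atom(self, index: int) -> AtomRecord:
        for a in self.atoms:
            if a.index == index:
                return a
        raise KeyError(f"{self.molecule_id}: no atom with index {index}")

    def occupied_mos(self) -> list[tuple[int, MolecularOrbital]]:
        """(ordinal, MO) pairs for occupied MOs, energy ascending."""
        return [(i, mo) for i, mo in enumerate(self.mos) if mo.occupied]

    def empty_mos(self) -> list[tuple[int, MolecularOrbital]]:
        """(ordinal, MO) pairs for empty MOs, energy ascending."""
        return [(i, mo) for i, mo in enumerate(self.mos) if not mo.occupied]


_REQUIRED_TOP = ("molecule_id", "atoms", "mos")
_REQUIRED_ATOM = ("index", "element", "mass", "xyz")
_REQUIRED_MO = ("energy", "occupied", "populations")


def _energy_scale(units: Mapping | None) -> float:
    tag = (units or {}).get("energy", "eV").lower()
    if tag in ("ev",):
        return 1.0
    if tag in ("hartree", "au", "a.u."):
        return HARTREE_TO_EV
    raise SchemaError(f"unknown energy unit tag {tag!r}")


def structure_from_dict(doc: Mapping) -> ElectronicStructure:
    """Build a validated structure from an interchange dictionary.

    Eigenvalues tagged hartree are converted to eV; MOs are sorted by
    energy ascending before invariant checks.
    """
    for key in _REQUIRED_TOP:
        if key not in doc:
            raise SchemaError(f"interchange document missing field {key!r}")
    scale = _energy_scale(doc.get("units"))
    atoms = []
    for raw in doc["atoms"]:
        for key in _REQUIRED_ATOM:
            if key not in raw:
                raise SchemaError(
                    f"atom record missing field {key!r}: {raw!r}"
                )
        atoms.append(
            AtomRecord(
                index=int(raw["index"]),
                element=str(raw["element"]),
                mass=float(raw["mass"]),
                coords=tuple(float(x) for x in raw["xyz"]),
                net_charge=float(raw.get("net_charge", 0.0)),
            )
        )
    mos = []
    for raw in doc["mos"]:
        for key in _REQUIRED_MO:
            if key not in raw:
                raise SchemaError(f"MO record missing field {key!r}")
        mos.append(
            MolecularOrbital(
                energy=float(raw["energy"]) * scale,
                occupied=bool(raw["occupied"]),
                populations={
                    int(k): float(v) for k, v in raw["populations"].items()
                },
            )
        )
    mos.sort(key=lambda mo: (mo.energy, not mo.occupied))
    return ElectronicStructure(
        molecule_id=str(doc["molecule_id"]),
        atoms=tuple(atoms),
        mos=tuple(mos),
        level_tag=str(doc.get("level_tag", "unknown")),
        normalized=bool(doc.get("normalized", False)),
    )


def structure_to_dict(structure: ElectronicStructure) -> dict:
    """Serialize to the interchange schema (energies in eV)."""
    return {
        "molecule_id": structure.molecule_id,
        "units": {"energy": "eV", "length": "angstrom"},
        "level_tag": structure.level_tag,
        "normalized": structure.normalized,
        "atoms": [
            {
                "index": a.index,
                "element": a.element,
                "mass": a.mass,
                "xyz": list(a.coords),
                "net_charge": a.net_charge,
            }
            for a in structure.atoms
        ],
        "mos": [
            {
                "energy": mo.energy,
                "occupied": mo.occupied,
                "populations": {str(k): v for k, v in mo.populations.items()},
            }
            for mo in structure.mos
        ],
    }


def read_structure(path: str | Path) -> ElectronicStructure:
    """Read one interchange JSON document."""
    with open(path) as fh:
        return structure_from_dict(json.load(fh))


def write_structure(structure: ElectronicStructure, path: str | Path) -> None:
    """Write the interchange JSON document (floats at full precision,
    so write-then-read round-trips bit-equal)."""
    with open(path, "w") as fh:
        json.dump(structure_to_dict(structure), fh, indent=1)


@dataclass(frozen=True)
class PopulationCorrection:
    """Record of one correction applied while normalizing an MO."""

    mo_ordinal: int
    atom_index: int
    action: str  # "clamped_negative" | "zeroed_below_threshold" | "rescaled"
    before: float
    after: float


def normalize_populations(
    structure: ElectronicStructure,
    threshold: float = DEFAULT_POPULATION_THRESHOLD,
) -> ElectronicStructure:
    """Clean raw MO populations into Fukui indices.

    Per MO: negative populations are clamped to zero; populations at or
    below ``threshold`` (e) are set to zero; the survivors are rescaled
    to sum to one. Zeroing and rescaling are repeated to a fixed point so
    the operation is idempotent (a value can drop through the threshold
    when a heavy MO is scaled down). Every correction is logged on the
    returned structure's ``corrections`` tuple.

    Raises
    ------
    DegenerateMOError
        If every population of some MO is at or below the threshold, so
        no renormalization target remains.
    """
    new_mos = []
    log: list[PopulationCorrection] = []
    for ordinal, mo in enumerate(structure.mos):
        pops = dict(mo.populations)
        for idx, v in list(pops.items()):
            if v < 0:
                log.append(
                    PopulationCorrection(ordinal, idx, "clamped_negative", v, 0.0)
                )
                pops[idx] = 0.0
        while True:
            changed = False
            for idx, v in list(pops.items()):
                if 0 < v <= threshold:
                    log.append(
                        PopulationCorrection(
                            ordinal, idx, "zeroed_below_threshold", v, 0.0
                        )
                    )
                    pops[idx] = 0.0
                    changed = True
            total = sum(pops.values())
            if total <= 0:
                raise DegenerateMOError(
                    f"{structure.molecule_id}: MO #{ordinal} at "
                    f"{mo.energy} eV has no population above the "
                    f"{threshold} e threshold; cannot renormalize"
                )
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-12):
                for idx, v in list(pops.items()):
                    if v > 0:
                        log.append(
                            PopulationCorrection(
                                ordinal, idx, "rescaled", v, v / total
                            )
                        )
                        pops[idx] = v / total
                changed = changed or any(
                    0 < v <= threshold for v in pops.values()
                )
            if not changed:
                break
        new_mos.append(
            MolecularOrbital(
                energy=mo.energy,
                occupied=mo.occupied,
                populations={k: v for k, v in pops.items() if v > 0},
            )
        )
    return replace(
        structure,
        mos=tuple(new_mos),
        normalized=True,
        corrections=tuple(log),
    )


def fukui_index(
    structure: ElectronicStructure, atom: int, mo: int
) -> float:
    """Fukui index F(i, m): the fraction of MO ``mo``'s electron density
    on atom ``atom``. Requires a normalized structure; sums to one over
    atoms within each MO. An atom thresholded out of an MO returns 0.
    """
    if not structure.normalized:
        raise ValueError(
            f"{structure.molecule_id}: normalize_populations must be "
            "applied before querying Fukui indices"
        )
    if not 0 <= mo < len(structure.mos):
        raise KeyError(
            f"{structure.molecule_id}: no MO with ordinal {mo} "
            f"(have {len(structure.mos)})"
        )
    if atom not in set(structure.atom_indices):
        raise KeyError(f"{structure.molecule_id}: no atom with index {atom}")
    return structure.mos[mo].population(atom)


def read_activities(path: str | Path) -> pd.Series:
    """Read observed activities (log K) from a CSV with columns
    ``molecule_id`` and ``log_K``; returns a Series indexed by id."""
    frame = pd.read_csv(path)
    for col in ("molecule_id", "log_K"):
        if col not in frame.columns:
            raise SchemaError(f"activities table missing column {col!r}")
    if frame["molecule_id"].duplicated().any():
        dupes = frame.loc[
            frame["molecule_id"].duplicated(), "molecule_id"
        ].tolist()
        raise SchemaError(f"duplicate molecule_id in activities: {dupes}")
    return frame.set_index("molecule_id")["log_K"].astype(float)


def structure_from_parsed(
    parsed,
    populations,
    molecule_id: str,
    masses=None,
    level_tag: str = "parsed-qm-log",
) -> ElectronicStructure:
    """Converter stub from a parsed QM-log object to the interchange schema.

    ``parsed`` is duck-typed against the attribute names standard
    computational-chemistry log parsers expose: ``moenergies`` (eV, first
    spin channel used), ``homos`` (index of the highest occupied MO),
    ``atomnos``/``atommasses``/``atomcoords`` and optionally
    ``atomcharges['mulliken']``. ``populations`` supplies the per-MO
    per-atom electron populations as an (n_mos, n_atoms) array, which log
    parsers do not provide directly.
    """
    import numpy as np

    energies = np.asarray(parsed.moenergies[0], dtype=float)
    homo = int(parsed.homos[0])
    coords = np.asarray(parsed.atomcoords[-1], dtype=float)
    numbers = list(parsed.atomnos)
    if masses is None:
        masses = list(parsed.atommasses)
    charges = getattr(parsed, "atomcharges", {}).get(
        "mulliken", [0.0] * len(numbers)
    )
    symbols = {1: "H", 6: "C", 7: "N", 8: "O", 16: "S"}
    pops = np.asarray(populations, dtype=float)
    doc = {
        "molecule_id": molecule_id,
        "units": {"energy": "eV", "length": "angstrom"},
        "level_tag": level_tag,
        "atoms": [
            {
                "index": i + 1,
                "element": symbols.get(int(z), f"Z{int(z)}"),
                "mass": float(masses[i]),
                "xyz": [float(x) for x in coords[i]],
                "net_charge": float(charges[i]),
            }
            for i, z in enumerate(numbers)
        ],
        "mos": [
            {
                "energy": float(energies[m]),
                "occupied": m <= homo,
                "populations": {
                    str(i + 1): float(pops[m, i])
                    for i in range(pops.shape[1])
                    if pops[m, i] != 0.0
                },
            }
            for m in range(len(energies))
        ],
    }
    return structure_from_dict(doc)
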