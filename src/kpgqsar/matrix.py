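"""Frontier variable ordering and descriptor-matrix assembly.

Molecules in a congeneric series do not populate the same absolute MOs
at an equivalent skeleton atom: atom i may carry density in (HOMO-2,
HOMO) in one molecule and (HOMO-1, HOMO) in another. Because the
receptor interacts through the MOs that *exist* on the atom, the
MO-resolved descriptors are compacted before regression: per atom, the
occupied MOs with nonzero population are relabelled HOMO, HOMO-1, ...
counting down from the highest such MO and skipping unpopulated ones,
and the empty MOs LUMO, LUMO+1, ... counting up. Relabelling moves
values between labels; it never changes a value.

The assembled matrix has one row per molecule and one column per
(skeleton atom, descriptor) pair — net charge Q, superdelocalizability
totals S_E/S_N, the frontier indices mu/eta/sigma/omega/Q_max, and the
MO-resolved F/S_E/S_N at each relative level up to a depth — plus one
column per substituent orientational parameter and, optionally, the
molecular mass. A column undefined for any molecule is dropped (with the
reason logged), never imputed; all-constant columns are dropped too,
since they carry no regression information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .electronic_structure import ElectronicStructure
from .errors import AssemblyError, SchemaError
from .orientation import SubstituentDefinition, orientational_parameters
from .reactivity import AtomReactivityProfile, atom_profile

DEFAULT_DEPTH = 3


@dataclass(frozen=True)
class SkeletonMap:
    """Per-molecule mapping skeleton-atom label -> molecule atom index.

    Every molecule must map exactly the same label set, each label once.
    """

    mapping: Mapping[str, Mapping[str, int]]

    def __post_init__(self):
        label_sets = {
            mol: frozenset(m.keys()) for mol, m in self.mapping.items()
        }
        if len(set(label_sets.values())) > 1:
            raise SchemaError(
                "skeleton map: molecules do not share one label set: "
                f"{sorted(set(map(tuple, map(sorted, label_sets.values()))))}"
            )
        for mol, m in self.mapping.items():
            if len(set(m.values())) != len(m):
                raise SchemaError(
                    f"skeleton map: molecule {mol} maps two labels to the "
                    "same atom index"
                )

    @property
    def labels(self) -> list[str]:
        first = next(iter(self.mapping.values()))

        def key(lbl: str):
            return (0, int(lbl)) if lbl.isdigit() else (1, lbl)

        return sorted(first.keys(), key=key)

    def atom(self, molecule_id: str, label: str) -> int:
        return self.mapping[molecule_id][label]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SkeletonMap":
        """Build from a table with columns molecule_id, skeleton_label,
        atom_index."""
        for col in ("molecule_id", "skeleton_label", "atom_index"):
            if col not in frame.columns:
                raise SchemaError(f"skeleton map table missing column {col!r}")
        mapping: dict[str, dict[str, int]] = {}
        for _, row in frame.iterrows():
            mol = str(row["molecule_id"])
            lbl = str(row["skeleton_label"])
            if lbl in mapping.setdefault(mol, {}):
                raise SchemaError(
                    f"skeleton map: label {lbl} mapped twice for {mol}"
                )
            mapping[mol][lbl] = int(row["atom_index"])
        return cls(mapping)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SkeletonMap":
        return cls.from_frame(pd.read_csv(path))


def occupied_relative_labels(n: int) -> list[str]:
    """HOMO, HOMO-1, ... for the n highest populated occupied MOs."""
    return ["HOMO" if j == 0 else f"HOMO-{j}" for j in range(n)]


def empty_relative_labels(n: int) -> list[str]:
    """LUMO, LUMO+1, ... for the n lowest populated empty MOs."""
    return ["LUMO" if j == 0 else f"LUMO+{j}" for j in range(n)]


def order_frontier_variables(
    profile: AtomReactivityProfile,
) -> AtomReactivityProfile:
    """Compact an atom's MO-resolved descriptors onto relative frontier
    labels.

    The profile's F and orbital-superdelocalizability maps arrive keyed
    by absolute MO ordinal (energy order); only ordinals with nonzero
    population are present. Occupied ordinals are relabelled HOMO,
    HOMO-1, ... from the highest down; empty ordinals LUMO, LUMO+1, ...
    from the lowest up. Values are untouched.
    """
    occ_ordinals = sorted(profile.F_occ.keys(), reverse=True)
    emp_ordinals = sorted(profile.F_emp.keys())
    occ_labels = dict(
        zip(occ_ordinals, occupied_relative_labels(len(occ_ordinals)))
    )
    emp_labels = dict(
        zip(emp_ordinals, empty_relative_labels(len(emp_ordinals)))
    )
    return replace(
        profile,
        F_occ={occ_labels[m]: v for m, v in profile.F_occ.items()},
        F_emp={emp_labels[m]: v for m, v in profile.F_emp.items()},
        S_E_orbital={
            occ_labels[m]: v for m, v in profile.S_E_orbital.items()
        },
        S_N_orbital={
            emp_labels[m]: v for m, v in profile.S_N_orbital.items()
        },
    )


_SCALAR_UNITS = {
    "Q": "e",
    "S_E": "e/eV",
    "S_N": "e/eV",
    "mu": "eV",
    "eta": "eV",
    "sigma": "1/eV",
    "omega": "eV",
    "q_max": "e",
}


@dataclass
class DescriptorMatrix:
    """Molecules x descriptors regression matrix with provenance.

    ``values``: DataFrame indexed by molecule_id; ``provenance``: per
    retained column, its unit and source (skeleton atom + index +
    relative level, or substituent); ``dropped``: per dropped column,
    the reason.
    """

    values: pd.DataFrame
    provenance: dict[str, dict] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path: str | Path) -> None:
        """CSV plus a .provenance.json sidecar."""
        path = Path(path)
        self.values.to_csv(path, index_label="molecule_id")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        with open(sidecar, "w") as fh:
            json.dump(
                {"provenance": self.provenance, "dropped": self.dropped},
                fh,
                indent=1,
            )

    @classmethod
    def read(cls, path: str | Path) -> "DescriptorMatrix":
        path = Path(path)
        values = pd.read_csv(path, index_col="molecule_id")
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        provenance, dropped = {}, {}
        if sidecar.exists():
            with open(sidecar) as fh:
                doc = json.load(fh)
            provenance = doc.get("provenance", {})
            dropped = doc.get("dropped", {})
        return cls(values=values, provenance=provenance, dropped=dropped)


def _atom_columns(
    label: str, profile: AtomReactivityProfile, depth: int
) -> tuple[dict[str, float], dict[str, dict]]:
    """One skeleton atom's cells and their provenance, NaN for missing."""
    cells: dict[str, float] = {}
    prov: dict[str, dict] = {}

    def put(col, value, index_name, level=None, unit=""):
        cells[col] = np.nan if value is None else value
        prov[col] = {
            "atom_label": label,
            "index": index_name,
            "level": level,
            "unit": unit,
        }

    put(f"{label}:Q", profile.Q, "Q", unit="e")
    put(f"{label}:S_E", profile.S_E_total, "S_E", unit="e/eV")
    put(f"{label}:S_N", profile.S_N_total, "S_N", unit="e/eV")
    fr = profile.frontier
    for name in ("mu", "eta", "sigma", "omega", "q_max"):
        put(
            f"{label}:{name}",
            getattr(fr, name) if fr else None,
            name,
            unit=_SCALAR_UNITS[name],
        )
    for lvl in occupied_relative_labels(depth):
        put(
            f"{label}:F({lvl})",
            profile.F_occ.get(lvl),
            "F",
            level=lvl,
            unit="1",
        )
        put(
            f"{label}:S_E({lvl})",
            profile.S_E_orbital.get(lvl),
            "S_E",
            level=lvl,
            unit="e/eV",
        )
    for lvl in empty_relative_labels(depth):
        put(
            f"{label}:F({lvl})",
            profile.F_emp.get(lvl),
            "F",
            level=lvl,
            unit="1",
        )
        put(
            f"{label}:S_N({lvl})",
            profile.S_N_orbital.get(lvl),
            "S_N",
            level=lvl,
            unit="e/eV",
        )
    return cells, prov


def build_matrix(
    structures: Sequence[ElectronicStructure],
    skeleton: SkeletonMap,
    subs: Mapping[str, Sequence[SubstituentDefinition]] | None = None,
    activities: pd.Series | None = None,
    depth: int = DEFAULT_DEPTH,
    include_mass: bool = False,
) -> DescriptorMatrix:
    """Assemble the regression matrix over the common skeleton.

    ``subs`` maps molecule_id to that molecule's substituent definitions
    (orientational parameters become O(name) columns). When
    ``activities`` is given, every molecule must appear in it. Columns
    with a missing entry for any molecule, or constant across all
    molecules, are dropped with a logged reason.
    """
    ids = [s.molecule_id for s in structures]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AssemblyError(f"duplicate molecule_id(s): {dupes}")
    if activities is not None:
        missing = [i for i in ids if i not in activities.index]
        if missing:
            raise AssemblyError(
                f"molecules absent from activities table: {missing}"
            )

    rows: list[dict[str, float]] = []
    provenance: dict[str, dict] = {}
    sub_names: list[str] = []
    if subs:
        seen = set()
        for defs in subs.values():
            for d in defs:
                if d.name not in seen:
                    seen.add(d.name)
                    sub_names.append(d.name)

    for s in structures:
        if s.molecule_id not in skeleton.mapping:
            raise AssemblyError(
                f"molecule {s.molecule_id} absent from skeleton map"
            )
        row: dict[str, float] = {}
        for label in skeleton.labels:
            atom = skeleton.atom(s.molecule_id, label)
            profile = order_frontier_variables(atom_profile(s, atom, label))
            cells, prov = _atom_columns(label, profile, depth)
            row.update(cells)
            provenance.update(prov)
        if subs:
            params = orientational_parameters(
                s, subs.get(s.molecule_id, ())
            )
            for name in sub_names:
                col = f"O({name})"
                row[col] = params.get(name, np.nan)
                provenance[col] = {
                    "substituent": name,
                    "index": "O",
                    "unit": "amu*angstrom^2",
                }
        if include_mass:
            row["M"] = s.mass_total
            provenance["M"] = {"index": "M", "unit": "amu"}
        rows.append(row)

    frame = pd.DataFrame(rows, index=pd.Index(ids, name="molecule_id"))
    # deterministic column order: skeleton-atom blocks, then O, then M
    frame = frame[[c for c in provenance.keys() if c in frame.columns]]

    dropped: dict[str, str] = {}
    keep = []
    for col in frame.columns:
        series = frame[col]
        if series.isna().any():
            absent = series.index[series.isna()].tolist()
            dropped[col] = f"missing for molecule(s) {absent}"
        elif series.nunique() <= 1:
            dropped[col] = "constant across all molecules"
        else:
            keep.append(col)
    frame = frame[keep]
    provenance = {c: provenance[c] for c in keep}
    return DescriptorMatrix(
        values=frame, provenance=provenance, dropped=dropped
    )
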