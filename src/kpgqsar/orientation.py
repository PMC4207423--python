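"""Substituent orientational parameters.

The rotational term of the affinity model is approximated by a sum of
substituent properties: for substituent t with member atoms i of mass
m(i) (amu) at distance R(i) (angstrom) from the skeleton atom bearing
the substituent,

    O(t) = sum_i m(i) * R(i)**2     [amu * angstrom**2]

O(t) is a moment-of-inertia-like measure of how much mass the
substituent swings away from its attachment point; it stands in for the
fraction of molecules attaining the binding orientation. It is invariant
to rigid motion of the whole molecule and scales as s**2 when all member
distances are scaled by s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .electronic_structure import ElectronicStructure
from .errors import SchemaError


@dataclass(frozen=True)
class SubstituentDefinition:
    """A named substituent: the skeleton atom it is attached to and the
    indices of its member atoms (attachment atom excluded)."""

    name: str
    attachment_atom: int
    member_atoms: tuple[int, ...]

    def __post_init__(self):
        if not self.member_atoms:
            raise SchemaError(f"substituent {self.name}: empty member list")
        if self.attachment_atom in self.member_atoms:
            raise SchemaError(
                f"substituent {self.name}: attachment atom "
                f"{self.attachment_atom} cannot be a member"
            )
        if len(set(self.member_atoms)) != len(self.member_atoms):
            raise SchemaError(
                f"substituent {self.name}: duplicate member atoms"
            )


@dataclass(frozen=True)
class OrientationalParameter:
    name: str
    value: float  # amu * angstrom**2


def orientational_parameter(
    structure: ElectronicStructure, sub: SubstituentDefinition
) -> OrientationalParameter:
    """O(t) = sum over member atoms of mass times squared distance to
    the attachment atom.

    A member atom coincident with the attachment atom (R = 0) is
    degenerate for anything heavier than a bonded hydrogen; it draws a
    warning and contributes nothing.
    """
    anchor = structure.atom(sub.attachment_atom)
    ax, ay, az = anchor.coords
    total = 0.0
    for idx in sub.member_atoms:
        member = structure.atom(idx)
        x, y, z = member.coords
        r2 = (x - ax) ** 2 + (y - ay) ** 2 + (z - az) ** 2
        if r2 == 0.0:
            warnings.warn(
                f"{structure.molecule_id}: substituent {sub.name} member "
                f"atom {idx} coincides with attachment atom "
                f"{sub.attachment_atom}; contributes 0",
                stacklevel=2,
            )
            continue
        total += member.mass * r2
    return OrientationalParameter(name=sub.name, value=total)


def orientational_parameters(
    structure: ElectronicStructure, subs: Sequence[SubstituentDefinition]
) -> dict[str, float]:
    """All O(t) of one molecule, keyed by substituent name."""
    return {
        sub.name: orientational_parameter(structure, sub).value
        for sub in subs
    }
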