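"""Orientational parameters of two substituents on a toy scaffold.

O(t) = sum over the substituent's atoms of mass x (distance to the
attachment atom)^2, in amu*angstrom^2 — a moment-of-inertia-like proxy
for how hard it is for the molecule to attain its binding orientation.
A bulky substituent far from its attachment point scores high; a lone
hydrogen scores ~1.
"""

from kpgqsar import (
    AtomRecord,
    ElectronicStructure,
    MolecularOrbital,
    SubstituentDefinition,
    orientational_parameter,
)

# atoms 1-2: skeleton; 3: H on atom 1; 4-6: methyl-like group on atom 2
structure = ElectronicStructure(
    molecule_id="demo",
    atoms=(
        AtomRecord(1, "C", 12.011, (0.0, 0.0, 0.0)),
        AtomRecord(2, "C", 12.011, (1.5, 0.0, 0.0)),
        AtomRecord(3, "H", 1.008, (-1.0, 0.3, 0.0)),
        AtomRecord(4, "C", 12.011, (2.6, 1.1, 0.0)),
        AtomRecord(5, "H", 1.008, (3.5, 1.0, 0.8)),
        AtomRecord(6, "H", 1.008, (3.0, 1.3, -1.0)),
    ),
    mos=(
        MolecularOrbital(-10.0, True, {1: 1.0}),
        MolecularOrbital(2.0, False, {1: 1.0}),
    ),
)

r1 = SubstituentDefinition("R1", attachment_atom=1, member_atoms=(3,))
r2 = SubstituentDefinition("R2", attachment_atom=2, member_atoms=(4, 5, 6))

for sub in (r1, r2):
    o = orientational_parameter(structure, sub)
    print(f"O({o.name}) = {o.value:8.3f} amu*angstrom^2")

print(
    "\nR1 is a single hydrogen about 1 angstrom out (O close to 1); R2's "
    "three atoms spread 1.6-2.6 angstrom from the ring carbon, so its "
    "orientational burden is ~40x larger."
)
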