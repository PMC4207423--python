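"""Local atomic reactivity indices of a small three-atom molecule.

Builds an electronic-structure record by hand (three atoms, three
occupied and two empty MOs), cleans the raw Mulliken-style populations,
and prints each atom's indices: net charge Q, the electrophilic and
nucleophilic superdelocalizability totals S_E/S_N (e/eV), and the
frontier-derived local chemical potential mu, hardness eta, softness
sigma, electrophilicity omega (eV-scale) and maximal acceptable charge
Q_max (e). An atom with no populated empty MO has no defined frontier
and reports NA rather than a fabricated zero.
"""

from kpgqsar import (
    AtomRecord,
    ElectronicStructure,
    MolecularOrbital,
    global_indices,
    normalize_populations,
    reactivity_report,
)

structure = ElectronicStructure(
    molecule_id="demo",
    atoms=(
        AtomRecord(1, "C", 12.011, (0.0, 0.0, 0.0), net_charge=-0.15),
        AtomRecord(2, "N", 14.007, (1.4, 0.0, 0.0), net_charge=0.25),
        AtomRecord(3, "O", 15.999, (2.6, 0.9, 0.0), net_charge=-0.32),
    ),
    mos=(
        # raw populations carry a negative artefact and a 0.008 e trace;
        # normalization clamps, zeroes and rescales them
        MolecularOrbital(-14.2, True, {1: 0.52, 2: 0.50, 3: -0.02}),
        MolecularOrbital(-11.0, True, {1: 0.30, 2: 0.70}),
        MolecularOrbital(-9.1, True, {1: 0.992, 3: 0.008}),
        MolecularOrbital(1.8, False, {1: 0.45, 2: 0.55}),
        MolecularOrbital(3.5, False, {2: 0.25, 3: 0.75}),
    ),
    level_tag="hand-built",
)

clean = normalize_populations(structure, threshold=0.01)
print(f"corrections applied during normalization: {len(clean.corrections)}")

report = reactivity_report(clean)
print(report.round(4).to_string(na_rep="NA"))

g = global_indices(clean)
print(
    f"\nmolecular chemical potential mu = {g.mu:.2f} eV, "
    f"hardness eta = {g.eta:.2f} eV (HOMO {g.e_homo:.1f}, LUMO {g.e_lumo:.1f})"
)
print(
    "Every local eta is at least the molecular eta: an atom's populated "
    "frontier levels can only sit at or inside the HOMO-LUMO gap."
)
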