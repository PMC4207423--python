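import numpy as np
import pytest

from kpgqsar.electronic_structure import (
    AtomRecord,
    ElectronicStructure,
    MolecularOrbital,
    normalize_populations,
)


def make_structure(
    mos,
    n_atoms=None,
    molecule_id="toy",
    normalize=True,
    masses=None,
    charges=None,
    coords=None,
):
    """Build a small structure from (energy, occupied, {atom: pop})
    triples; atoms are inferred from the populations unless n_atoms is
    given."""
    if n_atoms is None:
        n_atoms = max(max(p.keys()) for _, _, p in mos)
    atoms = tuple(
        AtomRecord(
            index=i + 1,
            element="C",
            mass=(masses or {}).get(i + 1, 12.011),
            coords=(coords or {}).get(i + 1, (float(i), 0.0, 0.0)),
            net_charge=(charges or {}).get(i + 1, 0.0),
        )
        for i in range(n_atoms)
    )
    orbitals = tuple(
        MolecularOrbital(energy=e, occupied=occ, populations=dict(pops))
        for e, occ, pops in sorted(mos, key=lambda t: t[0])
    )
    s = ElectronicStructure(
        molecule_id=molecule_id, atoms=atoms, mos=orbitals
    )
    return normalize_populations(s) if normalize else s


@pytest.fixture
def two_level_structure():
    """One atom, one occupied MO at -10 eV, one empty at +2 eV."""
    return make_structure(
        [(-10.0, True, {1: 1.0}), (2.0, False, {1: 1.0})]
    )


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One default synthetic dataset, shared across tests (seed 11)."""
    from kpgqsar.synthetic import SyntheticSpec, generate

    return generate(SyntheticSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
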