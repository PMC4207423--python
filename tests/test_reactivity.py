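import numpy as np
import pytest

from kpgqsar.errors import NearZeroEigenvalueError, UndefinedFrontierError
from kpgqsar.reactivity import (
    atom_profile,
    global_indices,
    local_frontier_indices,
    reactivity_report,
    superdelocalizability,
)
from kpgqsar.synthetic import SyntheticSpec, random_structure
from .conftest import make_structure


def sd_oracle(structure, atom, kind):
    """Independent brute force: loop over every MO of the right pool and
    sum population/energy."""
    want_occupied = kind == "electrophilic"
    total = 0.0
    for mo in structure.mos:
        if mo.occupied is not want_occupied:
            continue
        f = mo.populations.get(atom, 0.0)
        if f > 0:
            total += f / mo.energy
    return total


def frontier_oracle(structure, atom):
    """Independent scan of the population table for E_oc*, E_em*."""
    occ = [mo.energy for mo in structure.mos
           if mo.occupied and mo.populations.get(atom, 0.0) > 0]
    emp = [mo.energy for mo in structure.mos
           if not mo.occupied and mo.populations.get(atom, 0.0) > 0]
    if not occ or not emp:
        return None
    return max(occ), min(emp)


class TestSuperdelocalizability:
    def test_single_occupied_term(self, two_level_structure):
        sd = superdelocalizability(two_level_structure, 1, "electrophilic")
        assert sd.components == {0: pytest.approx(-0.10)}
        assert sd.total == pytest.approx(-0.10)

    def test_two_term_sum(self):
        s = make_structure([
            (-10.0, True, {1: 0.5, 2: 0.5}),
            (-5.0, True, {1: 0.5, 2: 0.5}),
            (3.0, False, {1: 1.0}),
        ])
        sd = superdelocalizability(s, 1, "electrophilic")
        # 0.5/(-10) + 0.5/(-5)
        assert sd.total == pytest.approx(-0.15)

    def test_total_is_sum_of_components(self, synthetic_dataset):
        s = synthetic_dataset.structures[0]
        for atom in s.atom_indices[:4]:
            for kind in ("electrophilic", "nucleophilic"):
                sd = superdelocalizability(s, atom, kind)
                assert sd.total == pytest.approx(
                    sum(sd.components.values()), abs=1e-12
                )

    def test_absent_mos_are_absent_not_zero(self):
        s = make_structure([
            (-10.0, True, {1: 1.0}),
            (-5.0, True, {2: 1.0}),
            (3.0, False, {1: 0.5, 2: 0.5}),
        ])
        sd = superdelocalizability(s, 1, "electrophilic")
        assert set(sd.components) == {0}

    def test_near_zero_eigenvalue_raises(self):
        s = make_structure([
            (-10.0, True, {1: 1.0}),
            (1e-9, False, {1: 1.0}),
        ])
        with pytest.raises(NearZeroEigenvalueError):
            superdelocalizability(s, 1, "nucleophilic")

    def test_matches_brute_force_oracle(self, rng):
        spec = SyntheticSpec(n_skeleton_atoms=5, n_occupied=4, n_empty=4,
                             n_substituents=1)
        for i in range(100):
            s, _ = random_structure(rng, spec, f"m{i}")
            for atom in s.atom_indices:
                for kind in ("electrophilic", "nucleophilic"):
                    got = superdelocalizability(s, atom, kind).total
                    assert got == pytest.approx(
                        sd_oracle(s, atom, kind), abs=1e-12
                    )


class TestLocalFrontierIndices:
    def test_closed_form_values(self):
        s = make_structure([(-9.0, True, {1: 1.0}), (1.0, False, {1: 1.0})])
        f = local_frontier_indices(s, 1)
        assert f.mu == pytest.approx(-4.0, abs=1e-10)
        assert f.eta == pytest.approx(10.0, abs=1e-10)
        assert f.sigma == pytest.approx(0.1, abs=1e-10)
        assert f.omega == pytest.approx(0.8, abs=1e-10)
        assert f.q_max == pytest.approx(0.4, abs=1e-10)

    def test_symmetric_levels_give_zero_potential(self):
        s = make_structure([(-5.0, True, {1: 1.0}), (5.0, False, {1: 1.0})])
        f = local_frontier_indices(s, 1)
        assert f.mu == 0.0 and f.omega == 0.0 and f.q_max == 0.0

    def test_sparse_pattern_picks_populated_levels(self):
        # atom 1 populates only HOMO-2 among occupied and LUMO+1 among
        # empty; those are its frontier levels
        s = make_structure([
            (-12.0, True, {1: 1.0}),
            (-10.0, True, {2: 1.0}),
            (-8.0, True, {2: 1.0}),
            (1.0, False, {2: 1.0}),
            (2.0, False, {1: 0.5, 2: 0.5}),
        ])
        f = local_frontier_indices(s, 1)
        assert f.e_oc == -12.0 and f.e_em == 2.0

    def test_missing_side_is_undefined_not_zero(self):
        s = make_structure([
            (-10.0, True, {1: 1.0, 2: 0.0}),
            (2.0, False, {1: 0.3, 2: 0.7}),
        ])
        with pytest.raises(UndefinedFrontierError):
            local_frontier_indices(s, 2)
        assert atom_profile(s, 2).frontier is None

    def test_identity_invariants_on_random_structures(self, rng):
        spec = SyntheticSpec(n_skeleton_atoms=5, n_occupied=4, n_empty=4,
                             n_substituents=1)
        for i in range(50):
            s, _ = random_structure(rng, spec, f"m{i}")
            for atom in s.atom_indices:
                oracle = frontier_oracle(s, atom)
                if oracle is None:
                    continue
                f = local_frontier_indices(s, atom)
                assert (f.e_oc, f.e_em) == oracle
                assert f.sigma * f.eta == pytest.approx(1.0, abs=1e-10)
                assert f.omega == pytest.approx(
                    f.mu**2 / (2 * f.eta), abs=1e-10
                )
                assert f.q_max == pytest.approx(-f.mu / f.eta, abs=1e-10)
                assert f.omega >= 0.0


class TestGlobalIndices:
    def test_homo_lumo_midpoint_and_gap(self):
        s = make_structure([(-6.0, True, {1: 1.0}), (-1.0, False, {1: 1.0})])
        g = global_indices(s)
        assert g.mu == pytest.approx(-3.5)
        assert g.eta == pytest.approx(5.0)

    def test_two_level_case(self, two_level_structure):
        g = global_indices(two_level_structure)
        assert g.mu == pytest.approx(-4.0)
        assert g.eta == pytest.approx(12.0)

    def test_local_hardness_dominates_global(self, rng):
        spec = SyntheticSpec(n_skeleton_atoms=6, n_occupied=5, n_empty=5,
                             n_substituents=1)
        for i in range(60):
            s, _ = random_structure(rng, spec, f"m{i}")
            g = global_indices(s)
            for atom in s.atom_indices:
                try:
                    f = local_frontier_indices(s, atom)
                except UndefinedFrontierError:
                    continue
                assert f.eta >= g.eta - 1e-12


class TestSignConventions:
    def test_zindo_convention_sign_of_totals(self, synthetic_dataset):
        # all empty eigenvalues positive, all occupied negative
        for s in synthetic_dataset.structures[:4]:
            for atom in s.atom_indices:
                e = superdelocalizability(s, atom, "electrophilic").total
                n = superdelocalizability(s, atom, "nucleophilic").total
                assert e <= 0.0
                assert n >= 0.0


class TestReactivityReport:
    def test_one_row_per_atom_with_missing_marker(self):
        s = make_structure([
            (-10.0, True, {1: 1.0}),
            (2.0, False, {1: 0.4, 2: 0.6}),
        ])
        report = reactivity_report(s)
        assert list(report.index) == [1, 2]
        assert np.isnan(report.loc[2, "eta"])  # atom 2: no occupied MO
        csv = report.to_csv(na_rep="NA")
        assert "NA" in csv
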