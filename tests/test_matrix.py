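import numpy as np
import pandas as pd
import pytest

from kpgqsar.errors import AssemblyError, SchemaError
from kpgqsar.matrix import (
    DescriptorMatrix,
    SkeletonMap,
    build_matrix,
    order_frontier_variables,
)
from kpgqsar.reactivity import atom_profile, reactivity_report
from kpgqsar.synthetic import SyntheticSpec, generate, random_structure
from .conftest import make_structure


def relabel_oracle(ordinals, descending):
    """Independent sort-and-filter relabelling: ordinal -> relative label."""
    ordered = sorted(ordinals, reverse=descending)
    if descending:
        return {
            m: ("HOMO" if j == 0 else f"HOMO-{j}")
            for j, m in enumerate(ordered)
        }
    return {
        m: ("LUMO" if j == 0 else f"LUMO+{j}")
        for j, m in enumerate(ordered)
    }


class TestFrontierOrdering:
    def test_compaction_skips_unpopulated_levels(self):
        s = make_structure([
            (-12.0, True, {1: 1.0}),             # H-2: populated
            (-10.0, True, {2: 1.0}),             # H-1: absent for atom 1
            (-8.0, True, {1: 0.5, 2: 0.5}),      # H: populated
            (1.0, False, {2: 1.0}),              # L: absent for atom 1
            (2.0, False, {1: 1.0}),              # L+1: populated
        ])
        p = order_frontier_variables(atom_profile(s, 1))
        assert set(p.F_occ) == {"HOMO", "HOMO-1"}
        assert p.F_occ["HOMO"] == pytest.approx(0.5)   # from absolute H
        assert p.F_occ["HOMO-1"] == pytest.approx(1.0)  # from absolute H-2
        assert set(p.F_emp) == {"LUMO"}                 # from absolute L+1
        assert set(p.S_N_orbital) == {"LUMO"}

    def test_fully_populated_atom_keeps_absolute_frontier(self):
        s = make_structure([
            (-10.0, True, {1: 0.5, 2: 0.5}),
            (-8.0, True, {1: 0.5, 2: 0.5}),
            (1.0, False, {1: 0.5, 2: 0.5}),
            (2.0, False, {1: 0.5, 2: 0.5}),
        ])
        p = order_frontier_variables(atom_profile(s, 1))
        assert set(p.F_occ) == {"HOMO", "HOMO-1"}
        assert set(p.F_emp) == {"LUMO", "LUMO+1"}

    def test_matches_sort_and_filter_oracle(self, rng):
        spec = SyntheticSpec(n_skeleton_atoms=6, n_occupied=5, n_empty=5,
                             sparsity=0.5, n_substituents=1)
        for i in range(150):
            s, _ = random_structure(rng, spec, f"m{i}")
            for atom in s.atom_indices:
                raw = atom_profile(s, atom)
                got = order_frontier_variables(raw)
                occ_map = relabel_oracle(raw.F_occ.keys(), descending=True)
                emp_map = relabel_oracle(raw.F_emp.keys(), descending=False)
                assert got.F_occ == {
                    occ_map[m]: v for m, v in raw.F_occ.items()
                }
                assert got.F_emp == {
                    emp_map[m]: v for m, v in raw.F_emp.items()
                }
                assert got.S_E_orbital == {
                    occ_map[m]: v for m, v in raw.S_E_orbital.items()
                }
                assert got.S_N_orbital == {
                    emp_map[m]: v for m, v in raw.S_N_orbital.items()
                }

    def test_relabelling_preserves_value_multiset(self, rng):
        spec = SyntheticSpec(n_skeleton_atoms=5, sparsity=0.4,
                             n_substituents=1)
        s, _ = random_structure(rng, spec, "m")
        for atom in s.atom_indices:
            raw = atom_profile(s, atom)
            got = order_frontier_variables(raw)
            for a, b in [(raw.F_occ, got.F_occ), (raw.F_emp, got.F_emp),
                         (raw.S_E_orbital, got.S_E_orbital),
                         (raw.S_N_orbital, got.S_N_orbital)]:
                assert sorted(a.values()) == sorted(b.values())


def two_molecule_inputs():
    s1 = make_structure([
        (-10.0, True, {1: 0.6, 2: 0.4}),
        (2.0, False, {1: 0.3, 2: 0.7}),
    ], molecule_id="m1", charges={1: -0.2, 2: 0.1})
    s2 = make_structure([
        (-9.0, True, {1: 0.5, 2: 0.5}),
        (3.0, False, {1: 0.8, 2: 0.2}),
    ], molecule_id="m2", charges={1: -0.1, 2: 0.3})
    skeleton = SkeletonMap({"m1": {"a": 1, "b": 2}, "m2": {"a": 1, "b": 2}})
    return [s1, s2], skeleton


class TestBuildMatrix:
    def test_shape_contract_depth_one(self):
        structures, skeleton = two_molecule_inputs()
        m = build_matrix(structures, skeleton, depth=1)
        assert m.values.shape[0] == 2
        produced = set(m.columns) | set(m.dropped)
        for label in ("a", "b"):
            for idx in ("Q", "S_E", "S_N", "mu", "eta", "sigma", "omega",
                        "q_max", "F(HOMO)", "S_E(HOMO)", "F(LUMO)",
                        "S_N(LUMO)"):
                assert f"{label}:{idx}" in produced

    def test_column_missing_for_one_molecule_dropped_with_reason(self):
        structures, skeleton = two_molecule_inputs()
        m = build_matrix(structures, skeleton, depth=3)
        # neither molecule has a LUMO+2 level, and no molecule has HOMO-1
        assert "a:F(LUMO+2)" not in m.columns
        assert "missing" in m.dropped["a:F(LUMO+2)"]

    def test_values_match_reactivity_report(self, synthetic_dataset):
        ds = synthetic_dataset
        m = ds.matrix
        for s in ds.structures[:3]:
            report = reactivity_report(s)
            mapping = ds.skeleton.mapping[s.molecule_id]
            for label, atom in mapping.items():
                for idx in ("Q", "S_E", "S_N", "mu", "eta", "sigma",
                            "omega", "q_max"):
                    col = f"{label}:{idx}"
                    if col in m.columns:
                        assert m.values.loc[s.molecule_id, col] == (
                            pytest.approx(report.loc[atom, idx])
                        )

    def test_row_permutation_only_permutes_rows(self):
        structures, skeleton = two_molecule_inputs()
        m1 = build_matrix(structures, skeleton, depth=1)
        m2 = build_matrix(structures[::-1], skeleton, depth=1)
        assert list(m2.values.index) == list(m1.values.index)[::-1]
        pd.testing.assert_frame_equal(
            m1.values, m2.values.loc[m1.values.index]
        )

    def test_duplicate_molecule_rejected(self):
        structures, skeleton = two_molecule_inputs()
        with pytest.raises(AssemblyError, match="duplicate"):
            build_matrix([structures[0], structures[0]], skeleton)

    def test_molecule_missing_from_activities_rejected(self):
        structures, skeleton = two_molecule_inputs()
        y = pd.Series({"m1": 0.5})
        with pytest.raises(AssemblyError, match="m2"):
            build_matrix(structures, skeleton, activities=y)

    def test_every_column_has_provenance(self, synthetic_dataset):
        m = synthetic_dataset.matrix
        assert set(m.columns) == set(m.provenance)
        for col, prov in m.provenance.items():
            assert "index" in prov

    def test_write_read_round_trip(self, synthetic_dataset, tmp_path):
        m = synthetic_dataset.matrix
        path = tmp_path / "matrix.csv"
        m.write(path)
        back = DescriptorMatrix.read(path)
        pd.testing.assert_frame_equal(back.values, m.values)
        assert back.dropped == m.dropped


class TestSkeletonMap:
    def test_label_sets_must_agree(self):
        with pytest.raises(SchemaError, match="label set"):
            SkeletonMap({"m1": {"a": 1}, "m2": {"a": 1, "b": 2}})

    def test_labels_must_map_to_distinct_atoms(self):
        with pytest.raises(SchemaError, match="same atom"):
            SkeletonMap({"m1": {"a": 1, "b": 1}})

    def test_csv_round_trip(self, tmp_path):
        p = tmp_path / "skel.csv"
        p.write_text(
            "molecule_id,skeleton_label,atom_index\n"
            "m1,1,3\nm1,2,5\nm2,1,2\nm2,2,4\n"
        )
        sk = SkeletonMap.read_csv(p)
        assert sk.atom("m1", "2") == 5
        assert sk.labels == ["1", "2"]
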