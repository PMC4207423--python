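"""Synthetic electronic structures with known regression ground truth.

The generator emulates the inputs of the full pipeline: a congeneric
series of molecules sharing a skeleton, each with an energy-ordered MO
spectrum, sparse per-atom per-MO electron populations, net charges,
3D coordinates with named substituents, and activities produced by a
known linear model on the derived descriptors plus Gaussian noise.

Defaults mirror the study conditions of the morphine-core series: 16
molecules, ZINDO/1-like eigenvalue convention (every empty MO positive),
activity noise SD 0.1 log units, two true predictors. Setting
``dft_like=True`` draws empty eigenvalues from a range straddling zero,
which exercises the near-zero-eigenvalue error paths of the
superdelocalizability sums.

Everything is drawn from one integer-seeded numpy PCG64 generator, so a
spec plus seed reproduces the dataset bit-for-bit; the ground-truth
record carries the algorithm identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .electronic_structure import (
    AtomRecord,
    ElectronicStructure,
    MolecularOrbital,
    normalize_populations,
)
from .errors import GenerationError
from .matrix import DescriptorMatrix, SkeletonMap, build_matrix
from .orientation import SubstituentDefinition

_MASSES = (1.008, 12.011, 14.007, 15.999)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-design parameters of one synthetic dataset.

    ``sparsity`` is the probability that an atom is absent from an MO's
    population list. ``true_model`` maps descriptor column labels to
    coefficients; when None, ``n_true`` retained columns are chosen at
    random and given effects comparable to the activity spread.
    """

    n_molecules: int = 16
    n_skeleton_atoms: int = 10
    n_occupied: int = 6
    n_empty: int = 6
    occupied_range: tuple[float, float] = (-20.0, -5.0)
    empty_range: tuple[float, float] = (1.0, 10.0)
    sparsity: float = 0.3
    n_substituents: int = 2
    true_model: Mapping[str, float] | None = None
    n_true: int = 2
    intercept: float | None = None
    noise_sd: float = 0.1
    seed: int = 0
    depth: int = 3
    threshold: float = 0.01
    dft_like: bool = False

    def __post_init__(self):
        if not 0 <= self.sparsity < 1:
            raise GenerationError("sparsity must lie in [0, 1)")
        if self.n_occupied < 1 or self.n_empty < 1:
            raise GenerationError("need at least one occupied and one empty MO")

    @property
    def effective_empty_range(self) -> tuple[float, float]:
        # dft_like swaps in a zero-straddling default; an explicitly
        # chosen range always wins
        if self.dft_like and self.empty_range == (1.0, 10.0):
            return (-2.0, 8.0)
        return self.empty_range


@dataclass
class SyntheticDataset:
    """Generated structures plus every table the pipeline consumes and
    the ground truth behind the activities."""

    spec: SyntheticSpec
    structures: list[ElectronicStructure]
    skeleton: SkeletonMap
    substituents: dict[str, list[SubstituentDefinition]]
    matrix: DescriptorMatrix
    activities: pd.Series
    ground_truth: dict = field(default_factory=dict)


def random_structure(
    rng: np.random.Generator, spec: SyntheticSpec, molecule_id: str
) -> tuple[ElectronicStructure, list[SubstituentDefinition]]:
    """One normalized random structure (plus its substituent
    definitions) under ``spec``, drawn from ``rng``."""
    n_skel = spec.n_skeleton_atoms
    sub_defs: list[SubstituentDefinition] = []
    atoms: list[AtomRecord] = []
    coords = rng.uniform(-3.0, 3.0, size=(n_skel, 3))
    for i in range(n_skel):
        atoms.append(
            AtomRecord(
                index=i + 1,
                element="C",
                mass=float(rng.choice(_MASSES[1:])),
                coords=tuple(coords[i]),
                net_charge=float(rng.normal(0.0, 0.2)),
            )
        )
    next_index = n_skel + 1
    for t in range(spec.n_substituents):
        attachment = t + 1  # skeleton atoms 1, 2, ...
        members = []
        for _ in range(int(rng.integers(1, 4))):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = float(rng.uniform(0.9, 2.2))
            pos = np.asarray(atoms[attachment - 1].coords) + dist * direction
            atoms.append(
                AtomRecord(
                    index=next_index,
                    element="H",
                    mass=float(rng.choice(_MASSES)),
                    coords=tuple(pos),
                    net_charge=float(rng.normal(0.0, 0.1)),
                )
            )
            members.append(next_index)
            next_index += 1
        sub_defs.append(
            SubstituentDefinition(
                name=f"R{t + 1}",
                attachment_atom=attachment,
                member_atoms=tuple(members),
            )
        )
    n_atoms = len(atoms)

    occ_e = np.sort(rng.uniform(*spec.occupied_range, size=spec.n_occupied))
    emp_e = np.sort(
        rng.uniform(*spec.effective_empty_range, size=spec.n_empty)
    )
    # raw populations: uniform in (0.2, 1) keeps every retained entry
    # above the 0.01 e threshold after renormalization for <= ~16 atoms
    mos: list[MolecularOrbital] = []
    present = rng.random((spec.n_occupied + spec.n_empty, n_atoms))
    raw = rng.uniform(0.2, 1.0, size=(spec.n_occupied + spec.n_empty, n_atoms))
    occupancy = [True] * spec.n_occupied + [False] * spec.n_empty
    energies = np.concatenate([occ_e, emp_e])
    pops_rows = []
    for m in range(len(energies)):
        pops = {
            i + 1: float(raw[m, i])
            for i in range(n_atoms)
            if present[m, i] >= spec.sparsity
        }
        if not pops:
            pops = {int(rng.integers(1, n_atoms + 1)): 1.0}
        pops_rows.append(pops)
    # every skeleton atom must populate >= 1 occupied and >= 1 empty MO
    # so its frontier indices exist on every molecule
    for i in range(1, n_skel + 1):
        occ_rows = range(spec.n_occupied)
        emp_rows = range(spec.n_occupied, spec.n_occupied + spec.n_empty)
        if not any(i in pops_rows[m] for m in occ_rows):
            pops_rows[int(rng.integers(0, spec.n_occupied))][i] = float(
                rng.uniform(0.2, 1.0)
            )
        if not any(i in pops_rows[m] for m in emp_rows):
            m = spec.n_occupied + int(rng.integers(0, spec.n_empty))
            pops_rows[m][i] = float(rng.uniform(0.2, 1.0))
    for m, energy in enumerate(energies):
        mos.append(
            MolecularOrbital(
                energy=float(energy),
                occupied=occupancy[m],
                populations=pops_rows[m],
            )
        )
    structure = ElectronicStructure(
        molecule_id=molecule_id,
        atoms=tuple(atoms),
        mos=tuple(mos),
        level_tag="synthetic",
    )
    return normalize_populations(structure, spec.threshold), sub_defs


#: auto-chosen true predictors must be distinguishable: at most this
#: squared correlation between the true columns themselves ...
_TRUE_MUTUAL_R2 = 0.5
#: ... and with any other candidate column (descriptor sets contain
#: near-deterministic transforms of one another, e.g. local hardness
#: and local softness of the same atom; planting one of those would
#: make "exact recovery" ill-posed)
_TRUE_DUPLICATE_R2 = 0.8


def _choose_true_model(
    rng: np.random.Generator, matrix: DescriptorMatrix, spec: SyntheticSpec
) -> dict[str, float]:
    """Pick identifiable true columns and give them effects comparable
    to the activity spread (coefficient = amplitude / column SD, with
    amplitude ~ U(0.5, 1.5) log-K units and random sign)."""
    columns = sorted(matrix.values.columns)
    if len(columns) < spec.n_true:
        raise GenerationError(
            f"only {len(columns)} derivable columns; cannot plant "
            f"{spec.n_true} true predictors"
        )
    # pairwise correlations are only informative with enough molecules;
    # below that any two columns look collinear and the screen is
    # meaningless, so it is skipped
    screen = spec.n_molecules >= 8
    if screen:
        r2 = matrix.values[columns].corr().to_numpy() ** 2
        np.fill_diagonal(r2, 0.0)
        max_other = r2.max(axis=1)
    for _ in range(200):
        chosen = sorted(
            rng.choice(len(columns), size=spec.n_true, replace=False)
        )
        if not screen:
            break
        if any(max_other[j] > _TRUE_DUPLICATE_R2 for j in chosen):
            continue
        if any(
            r2[a, b] > _TRUE_MUTUAL_R2
            for i, a in enumerate(chosen)
            for b in chosen[i + 1:]
        ):
            continue
        break
    else:
        raise GenerationError(
            f"no identifiable set of {spec.n_true} true predictors found "
            "(candidate columns are too strongly inter-correlated)"
        )
    true_model = {}
    for j in chosen:
        col = columns[j]
        scale = float(matrix.values[col].std(ddof=1))
        amplitude = float(rng.uniform(0.5, 1.5))
        sign = float(rng.choice((-1.0, 1.0)))
        true_model[col] = sign * amplitude / scale
    return true_model


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a full dataset under ``spec``.

    Raises
    ------
    GenerationError
        If a requested true-model column is not derivable (missing or
        constant) under the spec's sparsity, naming the column.
    """
    rng = np.random.default_rng(spec.seed)
    structures = []
    substituents: dict[str, list[SubstituentDefinition]] = {}
    skeleton_mapping: dict[str, dict[str, int]] = {}
    for i in range(spec.n_molecules):
        mol_id = f"mol-{i + 1:02d}"
        structure, sub_defs = random_structure(rng, spec, mol_id)
        structures.append(structure)
        substituents[mol_id] = sub_defs
        skeleton_mapping[mol_id] = {
            str(j + 1): j + 1 for j in range(spec.n_skeleton_atoms)
        }
    skeleton = SkeletonMap(skeleton_mapping)
    matrix = build_matrix(
        structures,
        skeleton,
        subs=substituents,
        depth=spec.depth,
    )

    if spec.true_model is not None:
        true_model = dict(spec.true_model)
        for col in true_model:
            if col not in matrix.values.columns:
                reason = matrix.dropped.get(col, "never produced")
                raise GenerationError(
                    f"true-model column {col!r} is not derivable under "
                    f"this spec ({reason})"
                )
    else:
        true_model = _choose_true_model(rng, matrix, spec)
    intercept = (
        spec.intercept
        if spec.intercept is not None
        else float(rng.uniform(-1.0, 1.0))
    )

    y = pd.Series(intercept, index=matrix.values.index, dtype=float)
    for col, coef in true_model.items():
        y = y + coef * matrix.values[col]
    if spec.noise_sd > 0:
        y = y + spec.noise_sd * rng.standard_normal(len(y))
    y.name = "log_K"

    return SyntheticDataset(
        spec=spec,
        structures=structures,
        skeleton=skeleton,
        substituents=substituents,
        matrix=matrix,
        activities=y,
        ground_truth={
            "true_model": true_model,
            "intercept": intercept,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
            "rng": "numpy default_rng (PCG64)",
        },
    )
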