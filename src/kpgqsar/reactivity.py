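"""Local atomic and global reactivity indices.

For a normalized structure with Fukui indices F(i, m) and MO eigenvalues
E(m) (eV), the indices computed per atom i are:

* orbital electrophilic superdelocalizability  S_E(i, m) = F(i, m)/E(m)
  over occupied MOs, and its sum S_E(i), the total electron-donating
  capacity of the atom (e/eV);
* orbital nucleophilic superdelocalizability  S_N(i, m') = F(i, m')/E(m')
  over empty MOs, and its sum S_N(i), the total electron-accepting
  capacity (e/eV);
* the local frontier eigenvalues E_oc*(i) (highest occupied MO with
  nonzero population on i) and E_em*(i) (lowest empty MO with nonzero
  population on i), from which

  - local electronic chemical potential  mu(i) = (E_oc* + E_em*)/2 (eV),
  - local hardness                       eta(i) = E_em* - E_oc* (eV),
  - local softness                       sigma(i) = 1/eta(i) (1/eV),
  - local electrophilicity               omega(i) = mu(i)^2 / (2 eta(i)) (eV),
  - maximal acceptable charge            Q_max(i) = -mu(i)/eta(i) (e).

The molecular analogues use the HOMO/LUMO eigenvalues directly:
mu = (E_HOMO + E_LUMO)/2 and eta = E_LUMO - E_HOMO (Koopmans frontier
estimates of the DFT chemical potential and hardness). Because an atom's
populated frontier levels can only sit at or inside the molecular
frontier, local hardness always dominates global hardness.

Superdelocalizabilities divide by the eigenvalue, so methods whose empty
eigenvalues straddle zero (Hartree-Fock, DFT, CNDO/2) can place an MO
arbitrarily close to the Fermi level and blow the sum up; such MOs raise
:class:`~kpgqsar.errors.NearZeroEigenvalueError` rather than returning a
meaningless number. ZINDO/1-convention spectra (all empty eigenvalues
positive) never trigger it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .electronic_structure import ElectronicStructure
from .errors import NearZeroEigenvalueError, UndefinedFrontierError

#: |E| below this (eV) counts as an algebraic zero at the Fermi level.
EIGENVALUE_TOLERANCE = 1e-6

#: Marker written for undefined descriptors in delimited reports.
MISSING_MARKER = "NA"


@dataclass(frozen=True)
class Superdelocalizability:
    """Orbital-resolved superdelocalizability of one atom, one kind.

    ``components`` maps absolute MO ordinal -> F/E for the MOs where the
    atom has nonzero population (absent MOs are absent, not zero);
    ``total`` is their sum.
    """

    atom: int
    kind: str  # "electrophilic" | "nucleophilic"
    components: Mapping[int, float]
    total: float


@dataclass(frozen=True)
class FrontierIndices:
    """Local frontier-derived indices of one atom (all from E_oc*, E_em*)."""

    atom: int
    e_oc: float  # eV, highest occupied eigenvalue populated by the atom
    e_em: float  # eV, lowest empty eigenvalue populated by the atom
    mu: float
    eta: float
    sigma: float
    omega: float
    q_max: float


@dataclass(frozen=True)
class GlobalIndices:
    """Molecular chemical potential and hardness from the HOMO/LUMO pair."""

    e_homo: float
    e_lumo: float
    mu: float
    eta: float


@dataclass(frozen=True)
class AtomReactivityProfile:
    """Every local index of one atom, MO-resolved values keyed by
    absolute MO ordinal (frontier relabelling happens at the
    descriptor-matrix stage)."""

    atom: int
    label: str
    Q: float
    S_E_orbital: Mapping[int, float]
    S_N_orbital: Mapping[int, float]
    S_E_total: float
    S_N_total: float
    F_occ: Mapping[int, float]
    F_emp: Mapping[int, float]
    frontier: FrontierIndices | None  # None when the frontier is undefined


def _require_normalized(structure: ElectronicStructure) -> None:
    if not structure.normalized:
        raise ValueError(
            f"{structure.molecule_id}: indices require a normalized "
            "structure; apply normalize_populations first"
        )


def superdelocalizability(
    structure: ElectronicStructure,
    atom: int,
    kind: Literal["electrophilic", "nucleophilic"],
) -> Superdelocalizability:
    """Sum F(i, m)/E(m) over the occupied (electrophilic) or empty
    (nucleophilic) MOs where atom ``atom`` has nonzero population.

    Raises
    ------
    NearZeroEigenvalueError
        If any contributing MO eigenvalue has magnitude below
        ``EIGENVALUE_TOLERANCE`` eV.
    """
    _require_normalized(structure)
    if kind not in ("electrophilic", "nucleophilic"):
        raise ValueError(f"unknown superdelocalizability kind {kind!r}")
    if atom not in set(structure.atom_indices):
        raise KeyError(f"{structure.molecule_id}: no atom with index {atom}")
    pool = (
        structure.occupied_mos()
        if kind == "electrophilic"
        else structure.empty_mos()
    )
    components: dict[int, float] = {}
    for ordinal, mo in pool:
        f = mo.population(atom)
        if f == 0.0:
            continue
        if abs(mo.energy) < EIGENVALUE_TOLERANCE:
            raise NearZeroEigenvalueError(
                f"{structure.molecule_id}: MO #{ordinal} eigenvalue "
                f"{mo.energy} eV is an algebraic zero at the Fermi level; "
                f"{kind} superdelocalizability of atom {atom} is undefined "
                f"for this electronic-structure method"
            )
        components[ordinal] = f / mo.energy
    return Superdelocalizability(
        atom=atom,
        kind=kind,
        components=components,
        total=sum(components.values()),
    )


def local_frontier_indices(
    structure: ElectronicStructure, atom: int
) -> FrontierIndices:
    """Locate E_oc* and E_em* for the atom and derive mu, eta, sigma,
    omega and Q_max.

    Raises
    ------
    UndefinedFrontierError
        If the atom populates no occupied or no empty MO after
        thresholding; the caller must treat the descriptors as missing,
        never as zero.
    """
    _require_normalized(structure)
    if atom not in set(structure.atom_indices):
        raise KeyError(f"{structure.molecule_id}: no atom with index {atom}")
    occ = [
        mo.energy
        for _, mo in structure.occupied_mos()
        if mo.population(atom) > 0
    ]
    emp = [
        mo.energy
        for _, mo in structure.empty_mos()
        if mo.population(atom) > 0
    ]
    if not occ or not emp:
        side = "occupied" if not occ else "empty"
        raise UndefinedFrontierError(
            f"{structure.molecule_id}: atom {atom} has no {side} MO with "
            "nonzero population; local frontier indices are undefined"
        )
    e_oc = max(occ)
    e_em = min(emp)
    mu = (e_oc + e_em) / 2.0
    eta = e_em - e_oc
    return FrontierIndices(
        atom=atom,
        e_oc=e_oc,
        e_em=e_em,
        mu=mu,
        eta=eta,
        sigma=1.0 / eta,
        omega=mu * mu / (2.0 * eta),
        q_max=-mu / eta,
    )


def global_indices(structure: ElectronicStructure) -> GlobalIndices:
    """Molecular mu and eta from the HOMO and LUMO eigenvalues
    (independent of per-atom populations)."""
    e_homo = max(mo.energy for _, mo in structure.occupied_mos())
    e_lumo = min(mo.energy for _, mo in structure.empty_mos())
    return GlobalIndices(
        e_homo=e_homo,
        e_lumo=e_lumo,
        mu=(e_homo + e_lumo) / 2.0,
        eta=e_lumo - e_homo,
    )


def atom_profile(
    structure: ElectronicStructure, atom: int, label: str | None = None
) -> AtomReactivityProfile:
    """Assemble every local index of one atom into a profile.

    A missing frontier (atom absent from all occupied or all empty MOs)
    yields ``frontier=None``; superdelocalizability totals over an empty
    pool are 0 with no components.
    """
    _require_normalized(structure)
    sd_e = superdelocalizability(structure, atom, "electrophilic")
    sd_n = superdelocalizability(structure, atom, "nucleophilic")
    f_occ = {
        ordinal: mo.population(atom)
        for ordinal, mo in structure.occupied_mos()
        if mo.population(atom) > 0
    }
    f_emp = {
        ordinal: mo.population(atom)
        for ordinal, mo in structure.empty_mos()
        if mo.population(atom) > 0
    }
    try:
        frontier = local_frontier_indices(structure, atom)
    except UndefinedFrontierError:
        frontier = None
    return AtomReactivityProfile(
        atom=atom,
        label=label if label is not None else str(atom),
        Q=structure.atom(atom).net_charge,
        S_E_orbital=sd_e.components,
        S_N_orbital=sd_n.components,
        S_E_total=sd_e.total,
        S_N_total=sd_n.total,
        F_occ=f_occ,
        F_emp=f_emp,
        frontier=frontier,
    )


def reactivity_report(
    structure: ElectronicStructure,
    atoms: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Tabulate the scalar indices of each atom: one row per atom, one
    column per index, ``NA`` where a frontier is undefined. Suitable for
    ``DataFrame.to_csv(..., na_rep=MISSING_MARKER)``."""
    if atoms is None:
        atoms = structure.atom_indices
    rows = []
    for a in atoms:
        p = atom_profile(structure, a)
        row = {
            "atom": a,
            "Q": p.Q,
            "S_E": p.S_E_total,
            "S_N": p.S_N_total,
        }
        for name in ("mu", "eta", "sigma", "omega", "q_max"):
            row[name] = getattr(p.frontier, name) if p.frontier else None
        rows.append(row)
    return pd.DataFrame(rows).set_index("atom")
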