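"""Bundled observed/calculated affinity tables for the morphine-core
opioid series (16 molecules, mu/delta/kappa receptor binding, at the
semiempirical ZINDO/1 and DFT B3LYP/6-31G(d,p) levels).

The raw per-atom descriptor values behind the published affinity
equations are not available, but the observed and fitted log K columns
are; from them the fit diagnostics (multiple R, residual SD, F) can be
recomputed and checked against the published statistics. Values are
transcribed verbatim; ``printed`` carries the statistics as published.

``LABEL_NOTES`` records two internal inconsistencies of the source
tables: the squared-correlation matrix accompanying the delta-receptor
DFT equation lists variables (F_8(HOMO-2), F_10(HOMO-2), S_11^E, mu_12)
that do not match the equation's own variables, and the kappa-receptor
ZINDO/1 beta table lists S_11^N(HOMO) where the equation text has
S_11^E(HOMO). The equations are taken as authoritative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

_MOLECULES = list(range(1, 17))

_TABLE4 = {
    "observed": [-1.28, -0.14, -0.95, -0.28, 0.57, 0.2, -1.14, -0.79,
                 0.39, -0.61, -0.52, 0.07, -0.55, -0.29, 1.66, 0.72],
    "calculated": {
        "zindo": [-1.32, -0.37, -0.83, -0.21, 0.43, 0.07, -1.19, -0.70,
                  0.69, -0.43, -0.45, -0.02, -0.63, -0.31, 1.60, 0.72],
        "dft": [-1.39, 0.03, -1.06, -0.35, 0.70, 0.25, -0.92, -0.89,
                0.35, -0.49, -0.46, -0.06, -0.52, -0.28, 1.61, 0.54],
    },
    "receptor": "mu",
    "k": {"zindo": 4, "dft": 4},
    "printed": {
        "zindo": {"n": 16, "R": 0.98, "R2": 0.97, "R2_adj": 0.96,
                  "F": 89.10, "F_dof": (4, 11), "SD": 0.16, "outliers": 0},
        "dft": {"n": 16, "R": 0.99, "R2": 0.98, "R2_adj": 0.97,
                "F": 113.62, "F_dof": (4, 11), "SD": 0.14, "outliers": 0},
    },
    "variables": {
        "zindo": ["S_3^N(LUMO+1)", "eta_6", "Q_13", "S_13^N(LUMO+2)"],
        "dft": ["Q_15^max", "eta_5", "F_11(LUMO)", "omega_13"],
    },
}

_TABLE9 = {
    "observed": [0.41, 2.74, 1.77, 1.89, 2.17, 2.76, 0.59, 0.62,
                 2.79, 1.89, 0.91, 2.41, 1.57, -1.6, -0.52, -0.85],
    "calculated": {
        "dft": [0.40, 2.68, 2.16, 1.50, 2.09, 2.39, 0.89, 0.74,
                2.85, 1.98, 0.88, 2.24, 1.81, -1.75, -0.41, -0.89],
    },
    "receptor": "delta",
    "k": {"dft": 4},
    "printed": {
        "dft": {"n": 16, "R": 0.99, "R2": 0.98, "R2_adj": 0.97,
                "F": 107.48, "F_dof": (4, 11), "SD": 0.25, "outliers": 0},
    },
    "variables": {
        "dft": ["S_12^E", "F_13(HOMO)", "S_8^N(LUMO+1)", "S_10^N(LUMO+1)"],
    },
}

_TABLE12 = {
    "observed": [-0.63, 1.04, -0.72, 0.95, -0.33, 0.47, -0.46, -0.53,
                 1.2, -0.61, 0.36, 1.27, 0.44, -0.09, 1.67, 0.46],
    "calculated": {
        "zindo": [-1.00, 1.01, -0.28, 0.96, -0.13, 0.45, -0.43, -0.52,
                  0.73, -0.44, 0.19, 1.23, 0.48, 0.03, 1.85, 0.38],
        "dft": [-0.78, 1.23, -0.36, 1.06, -0.27, 0.33, -0.11, -0.29,
                1.16, -0.78, 0.37, 1.08, 0.07, -0.23, 1.66, 0.34],
    },
    "receptor": "kappa",
    "k": {"zindo": 5, "dft": 4},
    "printed": {
        "zindo": {"n": 16, "R": 0.96, "R2": 0.92, "R2_adj": 0.89,
                  "F": 24.20, "F_dof": (5, 10), "SD": 0.27, "outliers": 0},
        "dft": {"n": 16, "R": 0.96, "R2": 0.93, "R2_adj": 0.91,
                "F": 36.78, "F_dof": (4, 11), "SD": 0.24, "outliers": 0},
    },
    "variables": {
        "zindo": ["S_7^N(LUMO+1)", "S_7^N", "F_16(HOMO-1)",
                  "S_11^N(LUMO+1)", "S_11^E(HOMO)"],
        "dft": ["omega_15", "S_11^N", "S_1^E(HOMO-1)", "F_11(LUMO)"],
    },
}

LABEL_NOTES: Mapping[str, str] = {
    "delta_dft_r2_matrix": (
        "published squared-correlation matrix lists F_8(HOMO-2), "
        "F_10(HOMO-2), S_11^E and mu_12; the equation itself uses "
        "S_12^E, F_13(HOMO), S_8^N(LUMO+1) and S_10^N(LUMO+1); the "
        "equation is taken as authoritative"
    ),
    "kappa_zindo_beta_table": (
        "published beta table lists S_11^N(HOMO); the equation text has "
        "S_11^E(HOMO); the equation is taken as authoritative"
    ),
}

_TABLES = {"table4": _TABLE4, "table9": _TABLE9, "table12": _TABLE12}


@dataclass(frozen=True)
class AffinityTableFixture:
    """One observed/calculated affinity table with its published
    statistics and the variables of the corresponding equation."""

    table_id: str
    receptor: str
    molecules: tuple[int, ...]
    observed: tuple[float, ...]
    calculated: Mapping[str, tuple[float, ...]]  # method -> column
    k: Mapping[str, int]  # method -> number of predictors
    printed: Mapping[str, Mapping]  # method -> published statistics
    variables: Mapping[str, tuple[str, ...]]

    @property
    def methods(self) -> list[str]:
        return list(self.calculated.keys())

    @property
    def n(self) -> int:
        return len(self.observed)


def load_fixture(table_id) -> AffinityTableFixture:
    """Return one bundled affinity table ("table4", "table9",
    "table12"; bare numbers accepted)."""
    key = str(table_id).lower()
    if key.isdigit():
        key = f"table{key}"
    if key not in _TABLES:
        raise KeyError(
            f"unknown fixture {table_id!r}; have {sorted(_TABLES)}"
        )
    raw = _TABLES[key]
    return AffinityTableFixture(
        table_id=key,
        receptor=raw["receptor"],
        molecules=tuple(_MOLECULES),
        observed=tuple(raw["observed"]),
        calculated={m: tuple(v) for m, v in raw["calculated"].items()},
        k=dict(raw["k"]),
        printed={m: dict(v) for m, v in raw["printed"].items()},
        variables={m: tuple(v) for m, v in raw["variables"].items()},
    )


def all_fixture_cases() -> list[tuple[str, str]]:
    """(table_id, method) pairs for every published equation."""
    return [
        (tid, method)
        for tid in ("table4", "table9", "table12")
        for method in _TABLES[tid]["calculated"]
    ]
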