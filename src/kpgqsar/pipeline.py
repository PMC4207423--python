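"""Declarative end-to-end runs: structures in, ranked models out.

A run configuration (YAML) names the input files and stage settings::

    structures: [mol-01.json, mol-02.json, ...]
    skeleton_map: skeleton.csv
    substituents: substituents.yaml     # optional
    activities: activities.csv
    threshold: 0.01
    depth: 3
    include_mass: false
    search: {k_max: 5, collinearity_cap: 0.5, alpha: 0.05}
    outlier_max_removals: 3
    output_dir: out/

The pipeline normalizes populations, assembles the descriptor matrix,
searches for admissible models, runs the outlier protocol on the best
one, and writes: per-molecule index reports, the matrix with provenance
sidecar, ranked models, the outlier trace, and a manifest with input
hashes and echoed settings. Re-running an identical configuration
reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .electronic_structure import (
    normalize_populations,
    read_activities,
    read_structure,
)
from .errors import ConfigError
from .matrix import SkeletonMap, build_matrix
from .orientation import SubstituentDefinition
from .reactivity import MISSING_MARKER, reactivity_report
from .regression import SearchConfig, SearchResult, outlier_protocol, search

logger = logging.getLogger("kpgqsar")


@dataclass
class RunConfig:
    structures: list[Path]
    skeleton_map: Path
    activities: Path
    output_dir: Path
    substituents: Path | None = None
    threshold: float = 0.01
    depth: int = 3
    include_mass: bool = False
    search: SearchConfig = field(default_factory=SearchConfig)
    outlier_max_removals: int = 3
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        base = path.parent
        required = ("structures", "skeleton_map", "activities", "output_dir")
        for key in required:
            if key not in doc:
                raise ConfigError(f"run config missing field {key!r}")
        search_cfg = SearchConfig(**doc.get("search", {}))
        cfg = cls(
            structures=[base / p for p in doc["structures"]],
            skeleton_map=base / doc["skeleton_map"],
            activities=base / doc["activities"],
            output_dir=base / doc["output_dir"],
            substituents=(
                base / doc["substituents"] if doc.get("substituents") else None
            ),
            threshold=float(doc.get("threshold", 0.01)),
            depth=int(doc.get("depth", 3)),
            include_mass=bool(doc.get("include_mass", False)),
            search=search_cfg,
            outlier_max_removals=int(doc.get("outlier_max_removals", 3)),
            log_level=str(doc.get("log_level", "INFO")),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = [
            str(p)
            for p in [*self.structures, self.skeleton_map, self.activities]
            + ([self.substituents] if self.substituents else [])
            if not Path(p).exists()
        ]
        if missing:
            raise ConfigError(f"referenced path(s) do not exist: {missing}")


def read_substituents(path: str | Path) -> dict[str, list[SubstituentDefinition]]:
    """YAML mapping molecule_id -> list of {name, attachment_atom,
    member_atoms} entries."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out: dict[str, list[SubstituentDefinition]] = {}
    for mol, entries in doc.items():
        out[str(mol)] = [
            SubstituentDefinition(
                name=str(e["name"]),
                attachment_atom=int(e["attachment_atom"]),
                member_atoms=tuple(int(a) for a in e["member_atoms"]),
            )
            for e in entries
        ]
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ReportBundle:
    status: str  # "model found" | "no acceptable model"
    search_result: SearchResult
    outlier_trace: object | None
    output_dir: Path
    manifest: dict


def run_pipeline(config: RunConfig, dry_run: bool = False):
    """Execute every stage; see the module docstring for outputs.

    With ``dry_run`` the configuration is validated and echoed together
    with the descriptor-column inventory; nothing is written.
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    t0 = time.perf_counter()

    structures = [
        normalize_populations(read_structure(p), config.threshold)
        for p in config.structures
    ]
    skeleton = SkeletonMap.read_csv(config.skeleton_map)
    activities = read_activities(config.activities)
    subs = (
        read_substituents(config.substituents) if config.substituents else None
    )
    logger.info(
        "loaded %d structures in %.2fs", len(structures),
        time.perf_counter() - t0,
    )

    t1 = time.perf_counter()
    matrix = build_matrix(
        structures,
        skeleton,
        subs=subs,
        activities=activities,
        depth=config.depth,
        include_mass=config.include_mass,
    )
    logger.info(
        "matrix %d x %d (%d columns dropped) in %.2fs",
        len(matrix.molecule_ids), len(matrix.columns),
        len(matrix.dropped), time.perf_counter() - t1,
    )

    if dry_run:
        return {
            "config": {
                k: str(v) if isinstance(v, Path) else v
                for k, v in dataclasses.asdict(config).items()
            },
            "molecules": matrix.molecule_ids,
            "columns": matrix.columns,
            "dropped": matrix.dropped,
        }

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in structures:
        reactivity_report(s).to_csv(
            out / f"indices-{s.molecule_id}.csv", na_rep=MISSING_MARKER
        )
    matrix.write(out / "matrix.csv")

    t2 = time.perf_counter()
    result = search(matrix, activities, config.search)
    logger.info(
        "search examined %s models in %.2fs",
        result.diagnostics.get("models_examined"),
        time.perf_counter() - t2,
    )

    trace = None
    if result.models:
        trace = outlier_protocol(
            matrix,
            activities,
            result.best.selected_columns,
            max_removals=config.outlier_max_removals,
        )
        status = (
            "model found" if trace.status == "clean" else trace.status
        )
    else:
        status = "no acceptable model"

    with open(out / "models.json", "w") as fh:
        json.dump(
            {
                "status": status,
                "models": [m.to_dict() for m in result.models],
                "search_diagnostics": result.diagnostics,
            },
            fh,
            indent=1,
        )
    if trace is not None:
        with open(out / "outlier_trace.json", "w") as fh:
            json.dump(
                {
                    "status": trace.status,
                    "removed": [str(r) for r in trace.removed],
                    "steps": [
                        {
                            "flagged": [str(f) for f in step.flagged],
                            "removed": (
                                str(step.removed) if step.removed else None
                            ),
                            "n": step.report.n,
                            "SD": step.report.SD,
                        }
                        for step in trace.steps
                    ],
                },
                fh,
                indent=1,
            )

    manifest = {
        "inputs": {
            str(p): _sha256(Path(p))
            for p in [*config.structures, config.skeleton_map,
                      config.activities]
            + ([config.substituents] if config.substituents else [])
        },
        "settings": {
            "threshold": config.threshold,
            "depth": config.depth,
            "include_mass": config.include_mass,
            "search": dataclasses.asdict(config.search),
            "outlier_max_removals": config.outlier_max_removals,
        },
        "status": status,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return ReportBundle(
        status=status,
        search_result=result,
        outlier_trace=trace,
        output_dir=out,
        manifest=manifest,
    )
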