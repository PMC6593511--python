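"""Pan-pathway subdivision and carbon/electron/energy flow roles.

The pan-pathway is the non-redundant set of functions (KO-level
annotations) encoded by a pan-genome; it is subdivided with the same
core/dispensable/strain-specific cutoff as the pan-genome.  Functions are
grouped into 18 named metabolic modules (acetate uptake, PHA, glycogen,
the three TCA operating modes, PolyP, ETP, ...), and each module carries a
role in each of the three flows (carbon, electron, energy) per phase of
the anaerobic/aerobic cycle:

``1-pro`` primary provider, ``2-pro`` secondary provider, ``1-con``
primary consumer, ``2-con`` secondary consumer, ``inter`` interconverting,
``none`` no assigned role.

The bundled default configuration encodes the anaerobic/aerobic role
assignments of the polyphosphate-accumulating organism model (acetate,
glycogen and PolyP as primary AN-phase carbon/electron/energy sources; PHA
and oxygen-driven ETP in the AE phase).  The KO membership of each module
is organism- and annotation-pipeline-specific, so the bundled lists are
clearly labelled placeholders; supply real KO sets for production use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .occurrence import OccurrenceMatrix

__all__ = [
    "MODULE_NAMES",
    "ROLES",
    "FlowModule",
    "FunctionOccurrence",
    "FlowConfigError",
    "load_flow_roles",
    "function_occurrence",
    "subdivide_pathway",
    "roles_table",
    "write_edge_list",
]

MODULE_NAMES: dict[int, str] = {
    1: "acetate uptake",
    2: "PHA",
    3: "LCFA",
    4: "AA",
    5: "glutamate/N",
    6: "Gly",
    7: "complete TCA",
    8: "split TCA (reductive branch)",
    9: "split TCA (oxidative branch)",
    10: "partial TCA",
    11: "denitrification/N reduction",
    12: "hydrogenases",
    13: "PolyP",
    14: "P transporters (pst/pit)",
    15: "ETP",
    16: "PL",
    17: "EPS",
    18: "acetate to pyruvate",
}

PHASES = ("AN", "AE")
FLOWS = ("carbon", "electron", "energy")
ROLES = ("1-pro", "2-pro", "1-con", "2-con", "inter", "none")


class FlowConfigError(ValueError):
    """Flow-role configuration is incomplete or inconsistent."""


@dataclass
class FlowModule:
    """One of the 18 functional modules with its per-phase flow roles."""

    module_id: int
    name: str
    function_ids: frozenset[str]
    roles: dict[tuple[str, str], str] = field(default_factory=dict)

    def role(self, phase: str, flow: str) -> str:
        return self.roles.get((phase, flow), "none")


@dataclass
class FunctionOccurrence:
    """A non-redundant function with its genome occurrence and label."""

    function_id: str
    genomes_with: int
    label: str | None = None


def load_flow_roles(path: str | Path | None = None) -> dict[int, FlowModule]:
    """Load a flow-role YAML; the bundled default config when path is None.

    Raises :class:`FlowConfigError` listing the missing modules (by name)
    if any of the 18 is absent, or if a phase's roles are undefined.
    """
    if path is None:
        text = (
            resources.files("traitflow").joinpath("data/flow_roles.yaml").read_text()
        )
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not raw or "modules" not in raw:
        raise FlowConfigError("flow-role config has no 'modules' section")
    modules: dict[int, FlowModule] = {}
    for entry in raw["modules"]:
        mid = int(entry["module_id"])
        roles: dict[tuple[str, str], str] = {}
        raw_roles = entry.get("roles", {})
        for phase in PHASES:
            if phase not in raw_roles:
                raise FlowConfigError(
                    f"module {mid} ({entry.get('name', '?')}): "
                    f"no role mapping for phase {phase}"
                )
            for flow, role in (raw_roles[phase] or {}).items():
                if flow not in FLOWS:
                    raise FlowConfigError(f"module {mid}: unknown flow {flow!r}")
                if role not in ROLES:
                    raise FlowConfigError(f"module {mid}: unknown role {role!r}")
                roles[(phase, flow)] = role
        modules[mid] = FlowModule(
            module_id=mid,
            name=str(entry.get("name", MODULE_NAMES.get(mid, f"module {mid}"))),
            function_ids=frozenset(str(f) for f in entry.get("function_ids", [])),
            roles=roles,
        )
    missing = sorted(set(MODULE_NAMES) - set(modules))
    if missing:
        names = ", ".join(f"{i} ({MODULE_NAMES[i]})" for i in missing)
        raise FlowConfigError(f"flow-role config is missing modules: {names}")
    return modules


def function_occurrence(
    m: OccurrenceMatrix, annot: pd.DataFrame
) -> tuple[list[FunctionOccurrence], list[str]]:
    """Genome occurrence of every annotated function.

    ``annot`` maps gene_id -> function_id; genes are resolved to genomes
    through the matrix's member-gene mapping.  A function's occurrence is
    the number of genomes possessing at least one gene annotated to it.
    Genes that map to no family in the matrix are returned (not fatal).
    """
    if annot.empty:
        raise ValueError("annotation table is empty")
    required = {"gene_id", "function_id"}
    if not required <= set(annot.columns):
        raise ValueError(f"annotation needs columns {sorted(required)}")
    if m.member_genes is None:
        raise ValueError(
            "matrix has no member-gene mapping; load it from a cluster "
            "membership table to use gene-level annotations"
        )
    gene_to_genome: dict[str, str] = {}
    for members in m.member_genes.values():
        for genome_id, gene_id in members:
            gene_to_genome[gene_id] = genome_id

    genomes_by_function: dict[str, set[str]] = {}
    unmapped: list[str] = []
    for gene, func in zip(annot["gene_id"].astype(str), annot["function_id"].astype(str)):
        genome = gene_to_genome.get(gene)
        if genome is None:
            unmapped.append(gene)
            continue
        genomes_by_function.setdefault(func, set()).add(genome)
    occ = [
        FunctionOccurrence(function_id=f, genomes_with=len(gs))
        for f, gs in sorted(genomes_by_function.items())
    ]
    return occ, unmapped


def subdivide_pathway(
    fo: Iterable[FunctionOccurrence], n: int, N: int | None = None
) -> tuple[list[FunctionOccurrence], dict[str, float]]:
    """Label functions with the pan-genome cutoff rule; report fractions."""
    fo = list(fo)
    if N is None:
        N = max(f.genomes_with for f in fo)
    if not 2 <= n <= N:
        raise ValueError(f"cutoff n must satisfy 2 <= n <= N={N}, got {n}")
    for f in fo:
        if f.genomes_with >= n:
            f.label = "core"
        elif f.genomes_with == 1:
            f.label = "strain_specific"
        else:
            f.label = "dispensable"
    total = len(fo)
    fractions = {
        cat: 100.0 * sum(1 for f in fo if f.label == cat) / total
        for cat in ("core", "dispensable", "strain_specific")
    }
    return fo, fractions


def roles_table(modules: Mapping[int, FlowModule]) -> pd.DataFrame:
    """Long-format (module, phase, flow, role) table of all assigned roles."""
    rows = []
    for mid in sorted(modules):
        mod = modules[mid]
        for phase in PHASES:
            for flow in FLOWS:
                role = mod.role(phase, flow)
                if role != "none":
                    rows.append(
                        {"module_id": mid, "name": mod.name,
                         "phase": phase, "flow": flow, "role": role}
                    )
    return pd.DataFrame(rows)


def write_edge_list(modules: Mapping[int, FlowModule], path: str | Path) -> None:
    """Plain edge-list export (module -> phase:flow node, labelled by role)."""
    table = roles_table(modules)
    table["target"] = table["phase"] + ":" + table["flow"]
    table[["name", "target", "role"]].rename(columns={"name": "source"}).to_csv(
        path, sep="\t", index=False
    )
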