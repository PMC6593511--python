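"""Synthetic data with planted truth for every pipeline stage.

Three generators:

* :func:`simulate_pangenome` — a true pan-genome with known
  core/dispensable/strain-specific families, observed through incomplete
  draft genomes: each true presence survives with probability equal to the
  genome's completeness, and contamination can add false presences.
  Families never observed are dropped from the matrix (and reported), as
  they would be in real data.
* :func:`simulate_curve_data` — sampling-curve means from an exponential
  model plus seeded Gaussian noise, for fit-recovery experiments.
* :func:`simulate_expression` — negative-binomial count matrices whose
  module-level expression follows one of the nine balance-pair scenario
  templates (fold-changes applied to the scenario's high/low module sets
  in the stated phase), with AN/AE phase-labelled samples.

Defaults describe a 13-genome draft collection (1800 core families, 3500
dispensable with occupancy uniform on 2..N-1, 250 strain-specific per
genome, completeness uniform on [0.85, 0.98]) and overdispersed RNA counts
(dispersion 0.2, 4x/0.25x module fold-changes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cutoff import GenomeMeta
from .occurrence import OccurrenceMatrix
from .pathway_flows import FlowModule, load_flow_roles
from .transcription import ExpressionMatrix

__all__ = [
    "ExpressionConfig",
    "SyntheticConfig",
    "PangenomeSim",
    "SCENARIOS",
    "scenario_template",
    "simulate_pangenome",
    "simulate_curve_data",
    "simulate_expression",
]

SCENARIOS = tuple(f"{c}{p}" for c in "ABC" for p in "123")

#: per-axis module fold-change templates: (module_id, phase) -> high/low
_CARBON_TEMPLATES: dict[str, dict[tuple[int, str], str]] = {
    "A": {},
    "B": {(7, "AN"): "high", (10, "AN"): "high", (9, "AN"): "low"},
    "C": {
        (3, "AN"): "high", (4, "AN"): "high", (5, "AN"): "high",
        (9, "AN"): "high", (11, "AN"): "high", (12, "AN"): "high",
    },
}
_PHOSPHORUS_TEMPLATES: dict[str, dict[tuple[int, str], str]] = {
    "1": {},
    "2": {
        (7, "AE"): "high", (15, "AE"): "high",
        (13, "AN"): "high", (13, "AE"): "high",
        (14, "AN"): "high", (14, "AE"): "high",
    },
    "3": {
        (13, "AN"): "low", (13, "AE"): "low",
        (14, "AN"): "low", (14, "AE"): "low",
        (6, "AE"): "high", (10, "AE"): "high", (15, "AN"): "high",
    },
}


def scenario_template(scenario: str) -> dict[tuple[int, str], str]:
    """The planted high/low module pattern of one of the nine scenarios."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    template = dict(_CARBON_TEMPLATES[scenario[0]])
    template.update(_PHOSPHORUS_TEMPLATES[scenario[1]])
    return template


@dataclass
class ExpressionConfig:
    """Scenario-structured count-matrix parameters."""

    scenario: str = "A1"
    baseline_mean: float = 200.0     # expected counts for a 1 kb gene
    fold_high: float = 4.0
    fold_low: float = 0.25
    dispersion: float = 0.2          # NB: var = mu + dispersion * mu^2
    samples_per_phase: int = 4
    genes_per_module: int = 8
    background_genes: int = 40
    length_range: tuple[int, int] = (500, 2000)

    def __post_init__(self) -> None:
        if not self.fold_high > 1.0 > self.fold_low > 0.0:
            raise ValueError("need fold_high > 1 > fold_low > 0")


@dataclass
class SyntheticConfig:
    """Planted pan-genome and expression study conditions."""

    n_genomes: int = 13
    core_size: int = 1800
    dispensable_size: int = 3500
    dispensable_occupancy: Literal["uniform"] | Mapping[int, float] = "uniform"
    specific_per_genome: int = 250
    completeness_range: tuple[float, float] = (0.85, 0.98)
    contamination_scale: float = 0.0
    contamination_value: float = 0.02   # per-genome contamination estimate
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    seed: int = 42


@dataclass
class PangenomeSim:
    """Planted truth plus the observed (incomplete) occurrence matrix."""

    truth: dict[str, str]                 # family -> planted category
    true_occupancy: dict[str, int]
    meta: list[GenomeMeta]
    matrix: OccurrenceMatrix
    dropped: list[str]                    # families never observed


def simulate_pangenome(
    cfg: SyntheticConfig | None = None, seed: int | None = None
) -> PangenomeSim:
    """Plant a pan-genome and observe it through incomplete draft genomes."""
    cfg = cfg or SyntheticConfig()
    if cfg.n_genomes < 1:
        raise ValueError("need at least one genome")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    N = cfg.n_genomes
    genome_ids = [f"G{i + 1:02d}" for i in range(N)]

    fams: list[str] = []
    truth: dict[str, str] = {}
    rows: list[np.ndarray] = []

    for i in range(cfg.core_size):
        fam = f"core_{i + 1:05d}"
        fams.append(fam)
        truth[fam] = "core"
        rows.append(np.ones(N, dtype=bool))

    if cfg.dispensable_size and N < 4:
        raise ValueError("dispensable families need N >= 4 (occupancy 2..N-1)")
    occupancies = np.arange(2, N) if N >= 3 else np.array([], dtype=int)
    if cfg.dispensable_occupancy == "uniform":
        weights = np.ones(occupancies.size) / max(occupancies.size, 1)
    else:
        weights = np.array(
            [cfg.dispensable_occupancy.get(int(m), 0.0) for m in occupancies],
            dtype=float,
        )
        weights /= weights.sum()
    for i in range(cfg.dispensable_size):
        fam = f"disp_{i + 1:05d}"
        m = int(rng.choice(occupancies, p=weights))
        hosts = rng.choice(N, size=m, replace=False)
        row = np.zeros(N, dtype=bool)
        row[hosts] = True
        fams.append(fam)
        truth[fam] = "dispensable"
        rows.append(row)

    for g in range(N):
        for i in range(cfg.specific_per_genome):
            fam = f"spec_{genome_ids[g]}_{i + 1:04d}"
            row = np.zeros(N, dtype=bool)
            row[g] = True
            fams.append(fam)
            truth[fam] = "strain_specific"
            rows.append(row)

    true_mat = np.array(rows, dtype=bool)
    true_occupancy = dict(zip(fams, true_mat.sum(axis=1).astype(int).tolist()))

    lo, hi = cfg.completeness_range
    completeness = rng.uniform(lo, hi, size=N)
    meta = [
        GenomeMeta(genome_ids[g], float(completeness[g]), cfg.contamination_value)
        for g in range(N)
    ]

    detected = true_mat & (rng.random(true_mat.shape) < completeness[None, :])
    eps = cfg.contamination_value * cfg.contamination_scale
    if eps > 0:
        false_hits = (~true_mat) & (rng.random(true_mat.shape) < eps)
        observed = detected | false_hits
    else:
        observed = detected

    keep = observed.sum(axis=1) > 0
    dropped = [fam for fam, k in zip(fams, keep) if not k]
    presence = pd.DataFrame(
        observed[keep].astype(np.int8),
        index=[fam for fam, k in zip(fams, keep) if k],
        columns=genome_ids,
    )
    return PangenomeSim(
        truth=truth,
        true_occupancy=true_occupancy,
        meta=meta,
        matrix=OccurrenceMatrix(presence),
        dropped=dropped,
    )


def simulate_curve_data(
    model,
    params: Sequence[float],
    noise_sd: float,
    n_range: Sequence[int],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a curve model on n_range and add seeded Gaussian noise.

    ``model`` is a callable like :func:`traitflow.curves.fc`, called as
    ``model(n, *params)``.
    """
    rng = np.random.default_rng(seed)
    ns = np.asarray(list(n_range), dtype=float)
    ys = np.asarray(model(ns, *params), dtype=float)
    if noise_sd > 0:
        ys = ys + rng.normal(0.0, noise_sd, size=ns.size)
    return ns, ys


def simulate_expression(
    cfg: SyntheticConfig | None = None,
    seed: int | None = None,
    modules: Mapping[int, FlowModule] | None = None,
) -> tuple[ExpressionMatrix, dict[tuple[int, str], str], pd.DataFrame]:
    """Scenario-structured negative-binomial counts with AN/AE samples.

    Returns the expression matrix, the planted template
    ((module, phase) -> high/low) and the gene -> function annotation
    table that links genes to flow modules.
    """
    cfg = cfg or SyntheticConfig()
    ecfg = cfg.expression
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if modules is None:
        modules = load_flow_roles()
    template = scenario_template(ecfg.scenario)

    genes: list[str] = []
    functions: list[str] = []
    gene_module: list[int | None] = []
    for mid in sorted(modules):
        fns = sorted(modules[mid].function_ids)
        for j in range(ecfg.genes_per_module):
            genes.append(f"M{mid:02d}_g{j + 1}")
            functions.append(fns[j % len(fns)])
            gene_module.append(mid)
    for j in range(ecfg.background_genes):
        genes.append(f"BG_g{j + 1}")
        functions.append("K000000")  # annotated, but in no module
        gene_module.append(None)

    lengths = rng.integers(*ecfg.length_range, size=len(genes))
    samples = [f"AN_{i + 1}" for i in range(ecfg.samples_per_phase)] + [
        f"AE_{i + 1}" for i in range(ecfg.samples_per_phase)
    ]
    phases = ["AN"] * ecfg.samples_per_phase + ["AE"] * ecfg.samples_per_phase

    fold = {"high": ecfg.fold_high, "low": ecfg.fold_low}
    mu = np.empty((len(genes), len(samples)))
    for gi, (length, mid) in enumerate(zip(lengths, gene_module)):
        base = ecfg.baseline_mean * (length / 1000.0)
        for si, phase in enumerate(phases):
            f = fold.get(template.get((mid, phase), ""), 1.0) if mid else 1.0
            mu[gi, si] = base * f
    if ecfg.dispersion > 0:
        lam = rng.gamma(shape=1.0 / ecfg.dispersion, scale=mu * ecfg.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)

    e = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=pd.Series(lengths, index=genes, dtype=float),
        sample_meta=pd.DataFrame(
            {"phase": phases, "population": "POP1"}, index=samples
        ),
    )
    annot = pd.DataFrame({"gene_id": genes, "function_id": functions})
    return e, template, annot
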