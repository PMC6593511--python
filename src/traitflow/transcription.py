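"""Transcript normalization to cellular relative activity.

Normalization chain for metatranscriptome read counts of one population:

* RPKM    = reads x 1e9 / (gene length in bp x total reads in sample)
* MRPKM   = RPKM / mean(RPKM over the population's genes in that sample)
* CRPKM   = RPKM / median(RPKM over the population's genes in that sample)
* LCRPKM  = log2(CRPKM + 1)

Dividing by a per-sample population summary removes the population's
abundance from its expression signal ("cellular relative" activity), so
values are comparable across samples and phases regardless of how much of
each metatranscriptome the population contributes.  The median is the
default normalizer (robust to a few dominant transcripts); the mean-scaled
variant is emitted alongside.  An optional per-population DNA-coverage
divisor hooks in matched metagenome depth when available.

Module activity is the mean LCRPKM over a module's genes, averaged over
the samples of a phase (anaerobic AN / aerobic AE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pathway_flows import FlowModule

__all__ = [
    "ExpressionMatrix",
    "NormalizedExpression",
    "ActivityProfile",
    "rpkm",
    "crpkm",
    "module_activity",
    "load_expression",
]

PHASES = ("AN", "AE")


@dataclass
class ExpressionMatrix:
    """Per-gene read counts with gene lengths and phase-labelled samples."""

    counts: pd.DataFrame            # genes x samples, non-negative ints
    gene_lengths: pd.Series         # bp, indexed by gene
    sample_meta: pd.DataFrame       # index sample; columns phase, population

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any():
            missing = list(self.gene_lengths.index[self.gene_lengths.isna()][:5])
            raise ValueError(f"genes without a length: {missing}")
        if (self.gene_lengths <= 0).any():
            bad = list(self.gene_lengths.index[self.gene_lengths <= 0][:5])
            raise ValueError(f"gene lengths must be > 0: {bad}")
        if "phase" not in self.sample_meta.columns:
            raise ValueError("sample metadata needs a 'phase' column")
        meta = self.sample_meta.reindex(self.counts.columns)
        if meta["phase"].isna().any():
            missing = list(meta.index[meta["phase"].isna()][:5])
            raise ValueError(f"samples without a phase label: {missing}")
        bad_phase = set(meta["phase"]) - set(PHASES)
        if bad_phase:
            raise ValueError(f"unknown phases {sorted(bad_phase)}; expected {PHASES}")
        self.sample_meta = meta

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_phase(self, phase: str) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["phase"] == phase])


def load_expression(
    counts_path: str | Path,
    lengths_path: str | Path,
    samples_path: str | Path,
) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from three TSVs (counts, lengths, samples)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    meta = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ExpressionMatrix(counts, lengths, meta)


def rpkm(e: ExpressionMatrix) -> pd.DataFrame:
    """Reads per kilobase of gene per million mapped reads, per gene/sample."""
    totals = e.counts.sum(axis=0)
    if (totals <= 0).any():
        empty = list(totals.index[totals <= 0][:5])
        raise ValueError(f"samples with zero total mapped reads: {empty}")
    return (
        e.counts.mul(1e9)
        .div(e.gene_lengths, axis=0)
        .div(totals, axis=1)
    )


@dataclass
class NormalizedExpression:
    """RPKM and its population-normalized variants, genes x samples."""

    rpkm: pd.DataFrame
    mrpkm: pd.DataFrame
    crpkm: pd.DataFrame
    lcrpkm: pd.DataFrame
    population_genes: list[str] = field(default_factory=list, repr=False)

    def to_long(self) -> pd.DataFrame:
        """Long-format table: gene, sample, rpkm, mrpkm, crpkm, lcrpkm."""
        frames = []
        for name in ("rpkm", "mrpkm", "crpkm", "lcrpkm"):
            df = getattr(self, name).stack().rename(name)
            frames.append(df)
        out = pd.concat(frames, axis=1).reset_index()
        out.columns = ["gene_id", "sample_id", "rpkm", "mrpkm", "crpkm", "lcrpkm"]
        return out


def crpkm(
    rpkm_values: pd.DataFrame,
    population_genes: Sequence[str] | None = None,
    *,
    normalizer: Literal["median", "mean"] = "median",
    dna_coverage: Mapping[str, float] | None = None,
) -> NormalizedExpression:
    """Normalize RPKM within a population to cellular relative activity.

    Parameters
    ----------
    rpkm_values
        Output of :func:`rpkm` (genes x samples).
    population_genes
        The population's gene set used to form the per-sample normalizer;
        all genes when omitted.
    normalizer
        Which summary defines CRPKM ("median" by default; MRPKM, the
        mean-scaled variant, is always emitted too).
    dna_coverage
        Optional per-sample genome coverage from matched metagenomes;
        RPKM is divided by it before normalizing.
    """
    if population_genes is None:
        population_genes = list(rpkm_values.index)
    population_genes = list(population_genes)
    if not population_genes:
        raise ValueError("population gene set is empty")
    pop = rpkm_values.reindex(population_genes)
    if pop.isna().any().any():
        missing = [g for g in population_genes if g not in rpkm_values.index][:5]
        raise ValueError(f"population genes missing from matrix: {missing}")

    values = rpkm_values
    if dna_coverage is not None:
        cov = pd.Series(dna_coverage).reindex(values.columns)
        if cov.isna().any() or (cov <= 0).any():
            raise ValueError("dna_coverage must be positive for every sample")
        values = values.div(cov, axis=1)
        pop = pop.div(cov, axis=1)

    medians = pop.median(axis=0)
    means = pop.mean(axis=0)
    for label, summ in (("median", medians), ("mean", means)):
        dead = summ.index[summ <= 0]
        if len(dead):
            raise ValueError(
                f"population {label} RPKM is zero in sample(s) "
                f"{list(dead[:5])}; cannot form cellular relative activity"
            )
    mrpkm_df = values.div(means, axis=1)
    med_df = values.div(medians, axis=1)
    crpkm_df = med_df if normalizer == "median" else mrpkm_df
    lcrpkm_df = np.log2(crpkm_df + 1.0)
    return NormalizedExpression(
        rpkm=values, mrpkm=mrpkm_df, crpkm=crpkm_df, lcrpkm=lcrpkm_df,
        population_genes=population_genes,
    )


@dataclass
class ActivityProfile:
    """Aggregated module activity per phase, plus the per-gene CRPKM."""

    values: dict[tuple[int, str], float]
    per_gene: pd.DataFrame = field(repr=False, default=None)
    module_ids: list[int] = field(default_factory=list)
    phases: list[str] = field(default_factory=list)

    def activity(self, module_id: int, phase: str) -> float | None:
        """Activity of a module in a phase; None when the module is absent."""
        return self.values.get((module_id, phase))

    def phase_values(self, phase: str) -> dict[int, float]:
        return {
            mid: v for (mid, ph), v in self.values.items() if ph == phase
        }

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"module_id": mid, "phase": ph, "activity": v}
            for (mid, ph), v in sorted(self.values.items())
        ]
        return pd.DataFrame(rows)


def module_activity(
    norm: NormalizedExpression,
    modules: Mapping[int, FlowModule],
    annot: pd.DataFrame,
    sample_meta: pd.DataFrame,
    *,
    aggregate: Literal["mean", "trimmed"] = "mean",
    trim: float = 0.1,
) -> ActivityProfile:
    """Aggregate LCRPKM into per-module, per-phase activity.

    A module's genes are those annotated to any of its function ids.  The
    activity of (module, phase) is the mean LCRPKM over the module's genes,
    averaged over the phase's samples (trimmed mean optional).  Modules with
    no genes in the matrix are reported as absent, not zero.
    """
    gene_function = dict(
        zip(annot["gene_id"].astype(str), annot["function_id"].astype(str))
    )
    lcrpkm = norm.lcrpkm
    values: dict[tuple[int, str], float] = {}
    found_any = False
    for mid, mod in modules.items():
        genes = [
            g for g in lcrpkm.index if gene_function.get(g) in mod.function_ids
        ]
        if not genes:
            continue
        found_any = True
        sub = lcrpkm.loc[genes]
        for phase in PHASES:
            samples = [
                s for s in lcrpkm.columns
                if s in sample_meta.index and sample_meta.loc[s, "phase"] == phase
            ]
            if not samples:
                continue
            per_sample = sub[samples].mean(axis=0)
            if aggregate == "trimmed" and len(samples) > 2:
                agg = float(stats.trim_mean(per_sample, trim))
            else:
                agg = float(per_sample.mean())
            values[(mid, phase)] = agg
    if not found_any:
        raise ValueError("no module gene is present in the expression matrix")
    return ActivityProfile(
        values=values,
        per_gene=norm.crpkm,
        module_ids=sorted({mid for mid, _ in values}),
        phases=sorted({ph for _, ph in values}),
    )
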