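"""FN/FP-controlled core-genome cutoff for incomplete draft genomes.

A gene family truly present in genome *i* is detected with probability equal
to that genome's estimated completeness, independently across genomes; a
family truly absent can optionally be falsely detected through contamination
(``epsilon_i = contamination_i * contamination_scale``, off by default).
The observed occurrence count of a family is therefore Poisson-binomial.

Subdividing the pan-genome at a cutoff *n* (core: observed occurrence >= n;
dispensable: 2..n-1; strain-specific: 1) misclassifies families through
detection error.  The model's error channels mirror the identity structure
FN1 = FP2 and FN2 = FP3: a missed core family surfaces as a dispensable
false positive, a missed dispensable family as a strain-specific false
positive, and a missed strain-specific family disappears entirely
(FN3 = max_i P(genome i fails to detect it) = max_i(1 - completeness_i)).
The cutoff is chosen as the largest n for which every rate the cutoff can
control stays below a threshold (1% by default); the completeness-floor
rates (FN3 and the low-occupancy channel of FN2) do not depend on n and are
reported but, by default, not part of the selection criterion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .occurrence import OccurrenceMatrix, OccurrenceSpectrum, spectrum_weights

__all__ = [
    "GenomeMeta",
    "ErrorRates",
    "PanPartition",
    "CutoffInfeasibleError",
    "load_genome_meta",
    "detection_pmf",
    "category_error_rates",
    "select_cutoff",
    "CutoffSelection",
    "subdivide",
    "score_partition",
    "PanGenomeModel",
    "PanGenomeResults",
]

CATEGORIES = ("core", "dispensable", "strain_specific")
RATE_NAMES = ("fn_core", "fp_core", "fn_disp", "fp_disp", "fn_spec", "fp_spec")
#: rates the choice of n actually controls; the others are completeness floors
ADJUSTABLE_RATES = ("fn_core", "fp_core", "fp_disp")


@dataclass(frozen=True)
class GenomeMeta:
    """Per-genome detection-model parameters (CheckM-style estimates)."""

    genome_id: str
    completeness: float
    contamination: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError(
                f"{self.genome_id}: completeness must be in (0, 1], "
                f"got {self.completeness}"
            )
        if self.contamination < 0.0:
            raise ValueError(
                f"{self.genome_id}: contamination must be >= 0, "
                f"got {self.contamination}"
            )


def load_genome_meta(path: str | Path) -> list[GenomeMeta]:
    """Read a TSV with columns genome_id, completeness, contamination.

    Completeness/contamination given in percent (any value > 1) are
    converted to fractions.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"genome_id", "completeness"}
    if not required <= set(df.columns):
        raise ValueError(f"genome metadata needs columns {sorted(required)}")
    if "contamination" not in df.columns:
        df["contamination"] = 0.0
    out = []
    for _, row in df.iterrows():
        comp = float(row["completeness"])
        cont = float(row["contamination"])
        if comp > 1.0:
            comp /= 100.0
        if cont > 1.0:
            cont /= 100.0
        out.append(GenomeMeta(str(row["genome_id"]), comp, cont))
    return out


@dataclass(frozen=True)
class ErrorRates:
    """Model FN/FP rates of the three categories at candidate cutoff ``n``."""

    n: int
    fn_core: float
    fp_core: float
    fn_disp: float
    fp_disp: float
    fn_spec: float
    fp_spec: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATE_NAMES}

    def max_rate(self, scope: Sequence[str] = RATE_NAMES) -> float:
        return max(getattr(self, name) for name in scope)


class CutoffInfeasibleError(RuntimeError):
    """No candidate cutoff satisfies the error-rate threshold."""

    def __init__(self, message: str, table: pd.DataFrame):
        super().__init__(message)
        self.table = table


def detection_pmf(p: Sequence[float]) -> np.ndarray:
    """Poisson-binomial mass over the observed count k = 0..len(p).

    ``p[i]`` is the detection probability in genome i.  Thin wrapper over
    ``scipy.stats.poisson_binom`` with input validation.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("detection probability vector is empty")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("detection probabilities must lie in [0, 1]")
    return stats.poisson_binom(p).pmf(np.arange(p.size + 1))


def _tail_ge(p: np.ndarray, k: int) -> float:
    """P(observed count >= k) for detection vector p."""
    if k <= 0:
        return 1.0
    if k > p.size:
        return 0.0
    return float(detection_pmf(p)[k:].sum())


def _completeness_sorted(meta: Sequence[GenomeMeta]) -> np.ndarray:
    return np.sort([g.completeness for g in meta])[::-1]  # descending


def category_error_rates(
    meta: Sequence[GenomeMeta],
    n: int,
    *,
    contamination_scale: float = 0.0,
    occupancy_weights: Mapping[int, float] | None = None,
) -> ErrorRates:
    """Model FN/FP rates for all three categories at candidate cutoff ``n``.

    Parameters
    ----------
    meta
        Completeness/contamination of the N genomes.
    n
        Candidate core cutoff, 2 <= n <= N.
    contamination_scale
        Scale s on the per-genome false-presence probability
        epsilon_i = contamination_i * s (default 0: contamination off).
    occupancy_weights
        Prior over the true occupancy m of dispensable families, restricted
        to m in [2, n-1].  Uniform when omitted; pass spectrum-derived
        weights to use the empirical occurrence distribution.

    Notes
    -----
    ``fp_disp = fn_core`` and ``fp_spec = fn_disp`` hold exactly: a core
    family dropping below the cutoff lands in the dispensable bin, a
    dispensable family collapsing to a single observation lands in the
    strain-specific bin.  ``fp_core`` is a worst case over dispensable
    occupancies m in [2, n-1] (the model's dispensable support) and is
    non-zero only through contamination.
    """
    N = len(meta)
    if N < 3:
        raise ValueError(f"need at least 3 genomes, got {N}")
    if not 2 <= n <= N:
        raise ValueError(f"cutoff n must satisfy 2 <= n <= N={N}, got {n}")
    comp_desc = _completeness_sorted(meta)
    comp_asc = comp_desc[::-1]
    eps_by_comp_desc = np.array(
        [g.contamination for g in sorted(meta, key=lambda g: -g.completeness)]
    ) * float(contamination_scale)
    eps_by_comp_asc = eps_by_comp_desc[::-1]

    # core: truly present in all N genomes
    fn_core = 1.0 - _tail_ge(comp_desc, n)

    # fp_core: truly dispensable (occupancy m in [2, n-1], worst case the m
    # most-complete genomes host it) observed >= n; needs contamination.
    fp_core = 0.0
    for m in range(2, n):
        probs = np.concatenate([comp_desc[:m], eps_by_comp_desc[m:]])
        fp_core = max(fp_core, _tail_ge(probs, n))

    # fn_disp: truly in m genomes (worst case the m least-complete host it),
    # observed outside [2, n-1]; averaged over the occupancy prior.
    support = list(range(2, n))
    weights = (
        dict(occupancy_weights)
        if occupancy_weights is not None
        else {m: 1.0 / len(support) for m in support}
    )
    wsum = sum(weights.get(m, 0.0) for m in support)
    fn_disp = 0.0
    if support and wsum > 0:
        for m in support:
            w = weights.get(m, 0.0) / wsum
            if w == 0.0:
                continue
            probs = np.concatenate([comp_asc[:m], eps_by_comp_asc[m:]])
            pmf = detection_pmf(probs)
            outside = float(pmf[:2].sum() + pmf[n:].sum())
            fn_disp += w * outside

    # fn_spec: truly present in one genome only; observed count != 1.
    fn_spec = 0.0
    for i, g in enumerate(sorted(meta, key=lambda g: -g.completeness)):
        eps_others = np.delete(eps_by_comp_desc, i)
        probs = np.concatenate([[comp_desc[i]], eps_others])
        fn_spec = max(fn_spec, 1.0 - float(detection_pmf(probs)[1]))

    return ErrorRates(
        n=n,
        fn_core=fn_core,
        fp_core=fp_core,
        fn_disp=fn_disp,
        fp_disp=fn_core,
        fn_spec=fn_spec,
        fp_spec=fn_disp,
    )


@dataclass
class CutoffSelection:
    """Result of scanning all candidate cutoffs against the threshold."""

    cutoff_n: int | None
    feasible_n: list[int]
    threshold: float
    rate_scope: tuple[str, ...]
    table: pd.DataFrame  # one row per candidate n, six rate columns

    @property
    def feasible(self) -> bool:
        return self.cutoff_n is not None


def error_rate_table(
    meta: Sequence[GenomeMeta],
    *,
    contamination_scale: float = 0.0,
    spectrum: OccurrenceSpectrum | None = None,
) -> pd.DataFrame:
    """Six model rates for every candidate cutoff n = 2..N."""
    N = len(meta)
    rows = []
    for n in range(2, N + 1):
        weights = (
            spectrum_weights(spectrum, range(2, n)) if spectrum and n > 2 else None
        )
        er = category_error_rates(
            meta, n, contamination_scale=contamination_scale,
            occupancy_weights=weights,
        )
        rows.append({"n": n, **er.as_dict()})
    return pd.DataFrame(rows).set_index("n")


def select_cutoff(
    meta: Sequence[GenomeMeta],
    threshold: float = 0.01,
    *,
    contamination_scale: float = 0.0,
    spectrum: OccurrenceSpectrum | None = None,
    rate_scope: Literal["adjustable", "all"] = "adjustable",
    prefer: Literal["largest", "smallest"] = "largest",
) -> CutoffSelection:
    """Scan all candidate cutoffs and pick the most stringent feasible one.

    A candidate n is feasible when every rate in scope is below
    ``threshold``.  The default scope, ``"adjustable"``, binds the rates the
    cutoff controls ({fn_core, fp_core, fp_disp}); ``"all"`` additionally
    binds the completeness-floor rates (fn_disp, fn_spec, fp_spec), which is
    only satisfiable with near-complete genomes.  The full-scan table is
    always attached, feasible or not.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    scope = RATE_NAMES if rate_scope == "all" else ADJUSTABLE_RATES
    table = error_rate_table(
        meta, contamination_scale=contamination_scale, spectrum=spectrum
    )
    feasible = [
        int(n) for n, row in table.iterrows()
        if all(row[name] < threshold for name in scope)
    ]
    if not feasible:
        return CutoffSelection(None, [], threshold, tuple(scope), table)
    chosen = max(feasible) if prefer == "largest" else min(feasible)
    return CutoffSelection(chosen, feasible, threshold, tuple(scope), table)


@dataclass
class PanPartition:
    """Cutoff plus per-family category labels."""

    cutoff_n: int
    labels: dict[str, str]

    def counts(self) -> dict[str, int]:
        out = {cat: 0 for cat in CATEGORIES}
        for lab in self.labels.values():
            out[lab] += 1
        return out

    def fractions(self) -> dict[str, float]:
        counts = self.counts()
        total = sum(counts.values())
        return {cat: counts[cat] / total for cat in CATEGORIES}

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"family_id": list(self.labels), "label": list(self.labels.values())}
        )


def subdivide(m: OccurrenceMatrix, n: int) -> PanPartition:
    """Label every family core / dispensable / strain-specific at cutoff n."""
    N = m.n_genomes
    if not 2 <= n <= N:
        raise ValueError(f"cutoff n must satisfy 2 <= n <= N={N}, got {n}")
    occ = m.occurrences()
    labels = {}
    for fam, k in occ.items():
        if k >= n:
            labels[fam] = "core"
        elif k == 1:
            labels[fam] = "strain_specific"
        else:
            labels[fam] = "dispensable"
    return PanPartition(cutoff_n=n, labels=labels)


def score_partition(
    partition: PanPartition, truth: Mapping[str, str]
) -> pd.DataFrame:
    """Per-category coverage (recall) and accuracy (precision) vs known truth.

    Families present in the truth but absent from the partition (e.g. never
    observed in any draft genome) count as false negatives of their true
    category.
    """
    rows = []
    for cat in CATEGORIES:
        tp = sum(
            1 for fam, lab in partition.labels.items()
            if lab == cat and truth.get(fam) == cat
        )
        fp = sum(
            1 for fam, lab in partition.labels.items()
            if lab == cat and truth.get(fam) != cat
        )
        fn = sum(
            1 for fam, true_lab in truth.items()
            if true_lab == cat and partition.labels.get(fam) != cat
        )
        coverage = tp / (tp + fn) if tp + fn else np.nan
        accuracy = tp / (tp + fp) if tp + fp else np.nan
        rows.append(
            {"category": cat, "tp": tp, "fp": fp, "fn": fn,
             "coverage": coverage, "accuracy": accuracy}
        )
    return pd.DataFrame(rows).set_index("category")


class PanGenomeModel:
    """Pan-genome subdivision model for a set of incomplete draft genomes.

    Combines the occurrence matrix with the per-genome detection-error
    parameters; ``fit`` selects the cutoff and partitions the pan-genome.

    Examples
    --------
    >>> model = PanGenomeModel(matrix, meta)           # doctest: +SKIP
    >>> res = model.fit(threshold=0.01)                # doctest: +SKIP
    >>> res.cutoff_n, res.partition.fractions()        # doctest: +SKIP
    """

    def __init__(
        self,
        matrix: OccurrenceMatrix,
        meta: Sequence[GenomeMeta],
        *,
        contamination_scale: float = 0.0,
        use_spectrum: bool = False,
    ):
        ids = {g.genome_id for g in meta}
        missing = [g for g in matrix.genome_ids if g not in ids]
        if missing:
            raise ValueError(f"no metadata for genomes: {missing}")
        self.matrix = matrix
        self.meta = [g for g in meta if g.genome_id in set(matrix.genome_ids)]
        self.contamination_scale = contamination_scale
        self.use_spectrum = use_spectrum

    @classmethod
    def from_files(
        cls, clusters_path: str | Path, meta_path: str | Path, **kwargs
    ) -> "PanGenomeModel":
        from .occurrence import load_clusters

        return cls(load_clusters(clusters_path), load_genome_meta(meta_path), **kwargs)

    def fit(
        self,
        threshold: float = 0.01,
        *,
        rate_scope: Literal["adjustable", "all"] = "adjustable",
        prefer: Literal["largest", "smallest"] = "largest",
    ) -> "PanGenomeResults":
        from .occurrence import occurrence_spectrum

        spectrum = occurrence_spectrum(self.matrix) if self.use_spectrum else None
        selection = select_cutoff(
            self.meta,
            threshold,
            contamination_scale=self.contamination_scale,
            spectrum=spectrum,
            rate_scope=rate_scope,
            prefer=prefer,
        )
        if not selection.feasible:
            raise CutoffInfeasibleError(
                f"no cutoff n in [2, {len(self.meta)}] keeps the rates "
                f"{list(selection.rate_scope)} below {threshold:g}; "
                "genomes are too incomplete for this threshold",
                selection.table,
            )
        partition = subdivide(self.matrix, selection.cutoff_n)
        return PanGenomeResults(self, selection, partition)


class PanGenomeResults:
    """Fitted pan-genome subdivision: cutoff, rate table and partition."""

    def __init__(
        self,
        model: PanGenomeModel,
        selection: CutoffSelection,
        partition: PanPartition,
    ):
        self.model = model
        self.selection = selection
        self.partition = partition

    @property
    def cutoff_n(self) -> int:
        return self.selection.cutoff_n

    @property
    def error_rates(self) -> pd.DataFrame:
        return self.selection.table

    def score(self, truth: Mapping[str, str]) -> pd.DataFrame:
        return score_partition(self.partition, truth)

    def summary(self) -> str:
        counts = self.partition.counts()
        fracs = self.partition.fractions()
        N = self.model.matrix.n_genomes
        at = self.error_rates.loc[self.cutoff_n]
        lines = [
            "Pan-genome subdivision (FN/FP-controlled cutoff)",
            "=" * 48,
            f"genomes (N):          {N}",
            f"families:             {self.model.matrix.n_families}",
            f"threshold:            {self.selection.threshold:g}"
            f"  (scope: {', '.join(self.selection.rate_scope)})",
            f"feasible cutoffs:     {self.selection.feasible_n}",
            f"selected cutoff (n):  {self.cutoff_n} of {N}",
            "",
            "rates at selected cutoff:",
        ]
        for name in RATE_NAMES:
            lines.append(f"  {name:<10} {at[name]:.4g}")
        lines.append("")
        lines.append("partition:")
        for cat in CATEGORIES:
            lines.append(
                f"  {cat:<16} {counts[cat]:>7}  ({100 * fracs[cat]:.1f}%)"
            )
        return "\n".join(lines)


def enumerate_detection_pmf(p: Sequence[float]) -> np.ndarray:
    """Exhaustive 2^N enumeration of the detection outcome distribution.

    Independent brute-force check of :func:`detection_pmf`; exponential in
    len(p), intended for N <= 12.
    """
    p = np.asarray(p, dtype=float)
    out = np.zeros(p.size + 1)
    for outcome in itertools.product((0, 1), repeat=p.size):
        prob = 1.0
        for pi, o in zip(p, outcome):
            prob *= pi if o else 1.0 - pi
        out[sum(outcome)] += prob
    return out
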