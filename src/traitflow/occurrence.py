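"""Gene-family occurrence matrices and occurrence-frequency spectra.

The substrate of every pan-genome statistic in this package is a binary
family x genome presence/absence matrix.  Two input dialects are accepted
and auto-detected by header:

* a long ortholog-cluster membership table with columns
  ``gene_id``, ``genome_id``, ``cluster_id`` (tab- or comma-separated);
* a roary ``Rtab``-style wide table: first column the family identifier,
  remaining columns one per genome holding 0/1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceMatrix",
    "OccurrenceSpectrum",
    "FormatError",
    "ValidationError",
    "load_clusters",
    "occurrence_spectrum",
    "write_matrix",
    "write_spectrum",
]


class FormatError(ValueError):
    """The input table is not in a recognised dialect."""


class ValidationError(ValueError):
    """The input table parsed but violates an invariant."""


LONG_COLUMNS = {"gene_id", "genome_id", "cluster_id"}


@dataclass
class OccurrenceMatrix:
    """Binary gene-family x genome presence table.

    Parameters
    ----------
    presence
        DataFrame indexed by family id with one 0/1 column per genome.
    member_genes
        Optional mapping family id -> list of (genome_id, gene_id) pairs,
        retained when the matrix was built from a cluster membership table.
    """

    presence: pd.DataFrame
    member_genes: dict[str, list[tuple[str, str]]] | None = field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        vals = self.presence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("presence entries must be 0 or 1")
        if self.presence.index.has_duplicates:
            raise ValidationError("duplicate family ids")
        if self.presence.columns.has_duplicates:
            raise ValidationError("duplicate genome ids")
        zero = vals.sum(axis=1) == 0
        if zero.any():
            bad = list(self.presence.index[zero][:5])
            raise ValidationError(f"families observed in no genome: {bad}")
        self.presence = self.presence.astype(np.int8)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def family_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def n_genomes(self) -> int:
        return self.presence.shape[1]

    @property
    def n_families(self) -> int:
        return self.presence.shape[0]

    def occurrences(self) -> pd.Series:
        """Per-family occurrence frequency (row sums)."""
        return self.presence.sum(axis=1).astype(int)

    def values(self) -> np.ndarray:
        return self.presence.to_numpy()


@dataclass
class OccurrenceSpectrum:
    """counts[k] = number of families present in exactly k genomes."""

    counts: dict[int, int]

    @property
    def n_families(self) -> int:
        return sum(self.counts.values())

    def as_series(self) -> pd.Series:
        ks = sorted(self.counts)
        return pd.Series([self.counts[k] for k in ks], index=ks, name="count")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"empty input file: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"no data rows in {path}")
    return df


def load_clusters(path: str | Path) -> OccurrenceMatrix:
    """Load a cluster membership table or wide presence/absence table.

    Returns one matrix row per cluster/family; ``presence[f, g] = 1`` iff at
    least one member gene of family ``f`` comes from genome ``g``.
    """
    df = _read_table(path)
    cols = set(df.columns)
    if LONG_COLUMNS <= cols:
        return _from_long(df)
    return _from_wide(df)


def _from_long(df: pd.DataFrame) -> OccurrenceMatrix:
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()[:5]
        raise ValidationError(f"duplicate gene_id rows: {list(dups)}")
    df = df.astype({"gene_id": str, "genome_id": str, "cluster_id": str})
    presence = (
        pd.crosstab(df["cluster_id"], df["genome_id"])
        .clip(upper=1)
        .astype(np.int8)
    )
    presence.index.name = None
    presence.columns.name = None
    members: dict[str, list[tuple[str, str]]] = {}
    for fam, sub in df.groupby("cluster_id"):
        members[str(fam)] = list(zip(sub["genome_id"], sub["gene_id"]))
    return OccurrenceMatrix(presence, member_genes=members)


def _from_wide(df: pd.DataFrame) -> OccurrenceMatrix:
    fam_col = df.columns[0]
    genome_cols = list(df.columns[1:])
    if not genome_cols:
        raise FormatError(
            "wide table needs a family column plus >=1 genome column; "
            f"got columns {list(df.columns)}"
        )
    body = df[genome_cols]
    try:
        body = body.astype(np.int8)
    except (TypeError, ValueError) as exc:
        raise FormatError(
            "wide table body must be 0/1 (is this a malformed long table? "
            "expected columns gene_id, genome_id, cluster_id)"
        ) from exc
    presence = body.copy()
    presence.index = df[fam_col].astype(str)
    presence.index.name = None
    return OccurrenceMatrix(presence)


def occurrence_spectrum(m: OccurrenceMatrix) -> OccurrenceSpectrum:
    """Tally how many families occur in exactly k genomes, k = 1..N."""
    counts = Counter(int(k) for k in m.occurrences())
    return OccurrenceSpectrum(dict(sorted(counts.items())))


def write_matrix(m: OccurrenceMatrix, path: str | Path) -> None:
    """Write the matrix in the wide (Rtab-style) dialect."""
    out = m.presence.copy()
    out.insert(0, "family_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def write_spectrum(s: OccurrenceSpectrum, path: str | Path) -> None:
    s.as_series().rename_axis("k").reset_index().to_csv(path, sep="\t", index=False)


def spectrum_weights(
    s: OccurrenceSpectrum, support: Sequence[int]
) -> Mapping[int, float]:
    """Normalised spectrum weights restricted to ``support`` (uniform fallback)."""
    raw = np.array([s.counts.get(k, 0) for k in support], dtype=float)
    if raw.sum() == 0:
        raw[:] = 1.0
    raw /= raw.sum()
    return dict(zip(support, raw))
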