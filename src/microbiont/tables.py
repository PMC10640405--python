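"""ASV count tables and the reductions feeding the network analysis.

The central reduction keeps, for every host species, its k most abundant
ASVs (k = 10 by default) and binarizes the result into a host x ASV
presence/absence interaction matrix.  Supporting summaries -- coverage of
the selection, sharing fractions across species, per-phylum composition --
live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "InteractionMatrix",
    "top_k_per_species",
    "coverage_fraction",
    "sharing_stats",
    "phylum_proportions",
]

#: taxonomy labels removed at load time (host-derived or uninformative reads)
EXCLUDED_TAXA = ("mitochondria", "chloroplast", "unassigned")


@dataclass
class CountTable:
    """Samples x ASVs count matrix plus sample metadata and ASV taxonomy.

    ``counts``: DataFrame, rows = sample ids, columns = ASV ids, values
    non-negative integers.  ``metadata``: DataFrame indexed by sample id with
    columns ``species`` and ``site``.  ``taxonomy``: DataFrame indexed by ASV
    id with columns ``phylum``, ``class``, ``genus`` (possibly "unassigned").
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.index) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        for col in ("species", "site"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks '{col}' column")
        untax = set(self.counts.columns) - set(self.taxonomy.index)
        if untax:
            raise ValueError(f"ASVs without taxonomy: {sorted(untax)[:5]}")

    @property
    def species(self) -> list[str]:
        return sorted(self.metadata.loc[self.counts.index, "species"].unique())

    def samples_of(self, species: str) -> list[str]:
        meta = self.metadata.loc[self.counts.index]
        return list(meta.index[meta["species"] == species])

    def drop_excluded_taxa(self) -> "CountTable":
        """Remove mitochondrial / chloroplast / taxonomically unassigned ASVs."""
        tax = self.taxonomy.reindex(self.counts.columns)
        low = tax.apply(lambda c: c.astype(str).str.lower())
        bad = (
            low["phylum"].isin(EXCLUDED_TAXA)
            | low.get("class", pd.Series("", index=tax.index)).isin(EXCLUDED_TAXA)
            | low.get("family", pd.Series("", index=tax.index)).isin(EXCLUDED_TAXA)
            | low.get("order", pd.Series("", index=tax.index)).isin(EXCLUDED_TAXA)
        )
        keep = [a for a, b in zip(self.counts.columns, bad) if not b]
        return CountTable(
            counts=self.counts[keep],
            metadata=self.metadata,
            taxonomy=self.taxonomy.loc[keep],
        )

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_files(cls, counts_path, metadata_path, taxonomy_path, sep="\t"):
        counts = pd.read_csv(counts_path, sep=sep, index_col=0)
        metadata = pd.read_csv(metadata_path, sep=sep, index_col=0)
        taxonomy = pd.read_csv(taxonomy_path, sep=sep, index_col=0)
        return cls(counts=counts, metadata=metadata, taxonomy=taxonomy)

    def to_files(self, counts_path, metadata_path, taxonomy_path, sep="\t"):
        self.counts.to_csv(counts_path, sep=sep)
        self.metadata.to_csv(metadata_path, sep=sep)
        self.taxonomy.to_csv(taxonomy_path, sep=sep)


@dataclass
class InteractionMatrix:
    """Host x ASV matrix; entries 0/1 (presence) or [0, 1] (posterior weight)."""

    hosts: list[str]
    asvs: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.hosts), len(self.asvs)):
            raise ValueError("interaction matrix shape mismatch")
        if len(set(self.hosts)) != len(self.hosts) or len(set(self.asvs)) != len(self.asvs):
            raise ValueError("duplicate labels")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.hosts, columns=self.asvs)

    def row(self, host: str) -> np.ndarray:
        return self.values[self.hosts.index(host)]


def top_k_per_species(
    table: CountTable, k: int = 10, per_sample_mean: bool = False
) -> tuple[dict[str, list[str]], InteractionMatrix]:
    """Per species, select the k most abundant ASVs; binarize to a matrix.

    Abundance is the total count summed over the species' samples (or the
    per-sample mean when ``per_sample_mean`` -- identical ranking when every
    species has equal sample counts).  Ties break by ASV id so the selection
    is deterministic.  Returns ({species: top-k ASV list}, InteractionMatrix)
    where matrix columns are the union of selections and entry (s, a) = 1 iff
    a is in species s's top k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    selections: dict[str, list[str]] = {}
    for sp in table.species:
        samples = table.samples_of(sp)
        if not samples:
            raise ValueError(f"species {sp!r} has no samples")
        totals = table.counts.loc[samples].sum(axis=0)
        if per_sample_mean:
            totals = totals / len(samples)
        nonzero = totals[totals > 0]
        if len(nonzero) < k:
            warnings.warn(
                f"species {sp!r} has only {len(nonzero)} nonzero ASVs (< k={k})"
            )
        # stable sort: descending abundance, ties by ASV id
        ranked = nonzero.sort_index().sort_values(ascending=False, kind="stable")
        selections[sp] = list(ranked.index[:k])

    union = sorted(set().union(*selections.values()))
    hosts = sorted(selections)
    mat = np.zeros((len(hosts), len(union)))
    for i, sp in enumerate(hosts):
        for a in selections[sp]:
            mat[i, union.index(a)] = 1.0
    return selections, InteractionMatrix(hosts=hosts, asvs=union, values=mat)


def coverage_fraction(table: CountTable, selected) -> tuple[pd.Series, float]:
    """Fraction of each sample's reads that fall in ``selected`` ASVs.

    Returns (per-sample fractions, mean over samples).  Zero-total samples
    are excluded with a warning.
    """
    selected = [a for a in table.counts.columns if a in set(selected)]
    unknown = set(selected) - set(table.counts.columns)
    if unknown:
        raise ValueError(f"selected ASVs absent from table: {sorted(unknown)[:5]}")
    totals = table.counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} zero-total samples")
    sub = table.counts.loc[~zero]
    frac = sub[selected].sum(axis=1) / sub.sum(axis=1)
    return frac, float(frac.mean())


def sharing_stats(matrix: InteractionMatrix, subset=None) -> dict[str, float]:
    """Sharing structure of the interaction matrix columns.

    ``shared``: fraction of all ASV columns present in *every* member of
    ``subset`` (default: all hosts); ``unique``: fraction present in exactly
    one host (of the full matrix); ``by_degree``: fraction of columns present
    in exactly d hosts, for d = 0..n_hosts.
    """
    if matrix.values.size == 0:
        raise ValueError("empty interaction matrix")
    subset = list(subset) if subset is not None else list(matrix.hosts)
    if not subset:
        raise ValueError("empty species subset")
    rows = [matrix.hosts.index(h) for h in subset]
    binary = matrix.values > 0
    n_asvs = len(matrix.asvs)
    shared = binary[rows].all(axis=0).sum() / n_asvs
    degree = binary.sum(axis=0)
    unique = (degree == 1).sum() / n_asvs
    by_degree = {
        int(d): float((degree == d).sum() / n_asvs)
        for d in range(len(matrix.hosts) + 1)
    }
    return {"shared": float(shared), "unique": float(unique), "by_degree": by_degree}


def phylum_proportions(
    table: CountTable, restrict_to=None
) -> pd.DataFrame:
    """Per-species proportional abundance aggregated by phylum (rows sum to 1)."""
    counts = table.counts
    if restrict_to is not None:
        counts = counts[[a for a in counts.columns if a in set(restrict_to)]]
    phyla = table.taxonomy.loc[counts.columns, "phylum"]
    meta = table.metadata.loc[counts.index]
    by_phylum = counts.T.groupby(phyla.values).sum().T
    by_species = by_phylum.groupby(meta["species"].values).sum()
    totals = by_species.sum(axis=1)
    return by_species.div(totals.replace(0, np.nan), axis=0)
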