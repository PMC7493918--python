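"""OTU-table processing and community statistics.

Filters (taxon removal, prevalence/core-microbiome, read and prevalence
selection), relative abundance, taxonomic aggregation, rarefaction, Good's
coverage, and beta-diversity statistics (Bray-Curtis, PCoA, PERMANOVA).
Distance/ordination/permutation machinery is delegated to scipy and
scikit-bio; this module owns the filtering rules and bookkeeping.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import pcoa as _skbio_pcoa

logger = logging.getLogger(__name__)

__all__ = [
    "OTUTable",
    "AbundanceTable",
    "TAXONOMY_RANKS",
    "parse_greengenes_lineage",
    "read_otu_table",
    "remove_taxon_by_label",
    "cmm_filter",
    "relative_abundance",
    "aggregate",
    "rarefy",
    "goods_coverage",
    "bray_curtis",
    "pcoa",
    "permanova",
    "select_otus",
    "select_families",
]

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

_GG_PREFIXES = {"k": "kingdom", "p": "phylum", "c": "class",
                "o": "order", "f": "family", "g": "genus"}


@dataclass
class OTUTable:
    """Animals x OTU count table with a per-OTU taxonomy.

    ``counts`` is a DataFrame (rows = animals, columns = OTU ids) of
    non-negative integers; ``taxonomy`` is indexed by OTU id with rank
    columns (subset of :data:`TAXONOMY_RANKS`).  Every OTU must have a
    taxonomy entry; unknown ranks may be "unclassified".
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate OTU ids in count table")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate animal ids in count table")
        if self.taxonomy.index.duplicated().any():
            raise ValueError("duplicate OTU ids in taxonomy")
        missing = self.counts.columns.difference(self.taxonomy.index)
        if len(missing):
            raise ValueError(f"OTUs without taxonomy entry: {list(missing)[:5]}")

    @property
    def animal_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    def _replace(self, counts: pd.DataFrame) -> "OTUTable":
        return OTUTable(counts, self.taxonomy.loc[counts.columns])


@dataclass
class AbundanceTable:
    """Animals x taxa relative abundances at one taxonomic level."""

    values: pd.DataFrame
    level: str = "otu"

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=1)
        nonempty = sums > 0
        if not np.allclose(sums[nonempty], 1.0, atol=1e-9):
            raise ValueError("abundance rows must sum to 1")


def parse_greengenes_lineage(lineage: str) -> dict:
    """Parse a Greengenes-style "k__Bacteria;p__Firmicutes;..." string.

    Empty or missing fields become "unclassified".
    """
    out = {rank: "unclassified" for rank in TAXONOMY_RANKS}
    for token in str(lineage).split(";"):
        token = token.strip()
        if "__" in token:
            prefix, _, name = token.partition("__")
            rank = _GG_PREFIXES.get(prefix.strip().lower())
            if rank and name:
                out[rank] = name
    return out


def read_otu_table(counts_path, taxonomy_path) -> OTUTable:
    """Read tab-delimited counts (animals x OTUs) and taxonomy tables.

    The taxonomy table is either one rank per column or a single ``lineage``
    column in Greengenes format, which is expanded into rank columns.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    if "lineage" in tax.columns:
        tax = pd.DataFrame(
            [parse_greengenes_lineage(s) for s in tax["lineage"]], index=tax.index
        )
    return OTUTable(counts, tax)


def remove_taxon_by_label(table: OTUTable, rank: str, label: str) -> OTUTable:
    """Drop every OTU whose taxonomy at ``rank`` equals ``label``.

    Used to strip Cyanobacteria (chloroplast 16S remnants) before analysis.
    """
    if rank not in table.taxonomy.columns:
        raise ValueError(f"unknown taxonomy rank {rank!r}")
    tax = table.taxonomy.loc[table.counts.columns]
    keep = tax[rank] != label
    if keep.all():
        return table
    if not keep.any():
        warnings.warn(f"every OTU matched {rank}={label!r}; table is now empty")
    return table._replace(table.counts.loc[:, keep[keep].index])


def cmm_filter(table: OTUTable, prevalence_threshold: float = 0.01) -> OTUTable:
    """Core-measurable-microbiome filter: keep OTUs detected in at least
    ``ceil(prevalence_threshold * n_animals)`` animals (boundary inclusive)."""
    if not 0 < prevalence_threshold <= 1:
        raise ValueError("prevalence threshold must be in (0, 1]")
    n_required = math.ceil(prevalence_threshold * len(table.counts))
    present = (table.counts > 0).sum(axis=0)
    keep = present[present >= n_required].index
    return table._replace(table.counts.loc[:, keep])


def relative_abundance(table: OTUTable, level: str = "otu") -> AbundanceTable:
    """Per-animal relative abundances; errors on an all-zero animal."""
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals[totals == 0].index[0]
        raise ValueError(f"animal {bad!r} has zero reads; cannot normalize")
    return AbundanceTable(table.counts.div(totals, axis=0), level=level)


def aggregate(table: OTUTable, level: str) -> OTUTable:
    """Sum OTU counts into their ``level`` labels (family or phylum).

    Unclassified labels pool into ``unclassified_<level>``.  The aggregated
    table keeps a one-row-per-taxon taxonomy carrying the ranks at or above
    ``level``.
    """
    if level not in table.taxonomy.columns:
        raise ValueError(f"unknown taxonomy rank {level!r}")
    labels = table.taxonomy.loc[table.counts.columns, level].astype(str)
    labels = labels.where(labels != "unclassified", f"unclassified_{level}")
    agg = table.counts.T.groupby(labels.values).sum().T
    # taxonomy for the aggregate: ranks above `level`, first occurrence wins
    upper = [r for r in TAXONOMY_RANKS if r in table.taxonomy.columns]
    upper = upper[: upper.index(level) + 1]
    tax = table.taxonomy.loc[table.counts.columns, upper].copy()
    tax[level] = labels.values
    tax = tax.groupby(level).first()
    tax[level] = tax.index
    return OTUTable(agg, tax.loc[agg.columns])


def rarefy(table: OTUTable, depth: int = 7000, seed: int | None = None) -> OTUTable:
    """Subsample each animal to exactly ``depth`` reads without replacement.

    Animals with fewer than ``depth`` reads are dropped (logged), matching
    common practice for rarefied beta-diversity input.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = totals.index.difference(keep)
    if len(keep) == 0:
        raise ValueError(f"no animal reaches rarefaction depth {depth}")
    if len(dropped):
        logger.info("rarefy: dropping %d animals below %d reads: %s",
                    len(dropped), depth, list(dropped))
    rows = [
        rng.multivariate_hypergeometric(
            table.counts.loc[a].to_numpy().astype(np.int64), depth
        )
        for a in keep
    ]
    counts = pd.DataFrame(rows, index=keep, columns=table.counts.columns)
    return table._replace(counts)


def goods_coverage(counts) -> pd.Series:
    """Good's coverage per animal: 1 - singletons / total reads."""
    counts = counts.counts if isinstance(counts, OTUTable) else pd.DataFrame(counts)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals[totals == 0].index[0]
        raise ValueError(f"animal {bad!r} has zero reads")
    singletons = (counts == 1).sum(axis=1)
    return (1.0 - singletons / totals).rename("goods_coverage")


def bray_curtis(abund: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, D[i,j] = sum|x_i-x_j| / sum(x_i+x_j)."""
    d = squareform(pdist(abund.values.to_numpy(), metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in abund.values.index])


def pcoa(dm: DistanceMatrix):
    """Principal coordinate analysis of a dissimilarity matrix.

    Gower-centered eigendecomposition via scikit-bio; axes with non-positive
    eigenvalues are dropped and the reported fractions are eigenvalues over
    the sum of the positive eigenvalues (so retained fractions sum to 1).
    Returns ``(coordinates, fractions)``.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = _skbio_pcoa(dm, method="eigh")
    eig = res.eigvals.to_numpy()
    pos = eig > 1e-12 * max(eig.max(), 1.0)
    if not pos.any():
        return (
            pd.DataFrame(index=list(dm.ids)),
            pd.Series(dtype=float, name="variance_fraction"),
        )
    coords = res.samples.loc[:, pos].copy()
    coords.index = list(dm.ids)
    coords.columns = [f"PCo{i + 1}" for i in range(pos.sum())]
    fractions = pd.Series(
        eig[pos] / eig[pos].sum(), index=coords.columns, name="variance_fraction"
    )
    return coords, fractions


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = None):
    """Permutational MANOVA on a dissimilarity matrix.

    Returns ``(pseudo_F, p_value)`` with the permutation p-value
    (1 + #{F_perm >= F_obs}) / (1 + n_perm).  Labels are permuted freely
    (no strata).
    """
    groups = pd.Series(list(groups))
    if groups.nunique() < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    res = _skbio_permanova(dm, groups.to_numpy(), permutations=n_perm, seed=seed)
    return float(res["test statistic"]), float(res["p-value"])


def select_otus(table: OTUTable, min_reads: int = 40_000,
                min_prevalence: float = 0.95) -> list:
    """OTUs with >= ``min_reads`` total reads and present in >=
    ``min_prevalence`` of animals (both boundaries inclusive)."""
    totals = table.counts.sum(axis=0)
    prevalence = (table.counts > 0).mean(axis=0)
    keep = (totals >= min_reads) & (prevalence >= min_prevalence)
    return list(table.counts.columns[keep])


def select_families(family_table: OTUTable, min_fraction: float = 0.018,
                    k: int = 12) -> list:
    """Families holding strictly more than ``min_fraction`` of all reads,
    ranked by reads, capped at the top ``k``."""
    totals = family_table.counts.sum(axis=0)
    frac = totals / totals.sum()
    passing = frac[frac > min_fraction]
    ranked = passing.sort_values(ascending=False, kind="stable")
    return list(ranked.index[:k])
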