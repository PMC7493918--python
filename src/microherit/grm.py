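"""Genotype preprocessing and the VanRaden genomic relationship matrix.

The additive genomic relationship matrix (GRM) used throughout the package is

    G = M M' / (2 * sum_j p_j (1 - p_j))

where ``M`` is the animals x SNP dosage matrix centered by twice the allele
frequency of the counted allele at each locus.  ``G`` plays two roles: its
first principal components enter the fixed-effects design of the GBLUP model
(population-structure correction), and its scaled inverse backsolves animal
breeding values into per-SNP marker effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "CenteredGenotypes",
    "GenomicRelationship",
    "impute_missing_mean",
    "allele_frequencies",
    "center_genotypes",
    "vanraden_grm",
    "grm_pca",
]

#: relative eigenvalue floor below which a component of G is treated as null
EIG_FLOOR_RATIO = 1e-8


@dataclass
class GenotypeMatrix:
    """Animals x SNP dosage matrix with a physical SNP map.

    Dosages count copies of one designated allele per SNP and are 0, 1 or 2;
    missing calls are NaN.  ``snp_map`` has columns ``chrom`` (int), ``id``
    (str) and ``bp`` (int), one row per dosage column, sorted by (chrom, bp).
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    animal_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D animals x SNP array")
        n, m = self.dosages.shape
        if len(self.snp_map) != m:
            raise ValueError(
                f"snp_map has {len(self.snp_map)} rows for {m} SNP columns"
            )
        if not self.animal_ids:
            self.animal_ids = [f"animal_{i}" for i in range(n)]
        if len(self.animal_ids) != n:
            raise ValueError("animal_ids length does not match dosage rows")
        if len(set(self.animal_ids)) != n:
            raise ValueError("animal_ids are not unique")
        observed = self.dosages[~np.isnan(self.dosages)]
        # real-valued entries appear only after mean imputation; raw input is 0/1/2
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        key = self.snp_map[["chrom", "bp"]].to_numpy()
        if not (np.lexsort((key[:, 1], key[:, 0])) == np.arange(m)).all():
            raise ValueError("snp_map must be sorted by (chrom, bp)")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snp(self) -> int:
        return self.dosages.shape[1]


@dataclass
class CenteredGenotypes:
    """Allele-frequency-centered dosages ``M`` with the VanRaden scaling.

    ``denom`` is ``2 * sum_j p_j (1 - p_j)``, shared by the GRM and by the
    marker-effect backsolve so the two stay algebraically consistent.
    """

    M: np.ndarray
    p: np.ndarray
    denom: float
    snp_map: pd.DataFrame | None = None
    animal_ids: list[str] | None = None


@dataclass
class GenomicRelationship:
    """Symmetric n x n genomic relationship matrix with its centering info."""

    G: np.ndarray
    p: np.ndarray
    denom: float
    animal_ids: list[str] | None = None

    def eigen(self, floor_ratio: float = EIG_FLOOR_RATIO):
        """Eigendecomposition of G with a relative floor on the eigenvalues.

        Returns ``(eigvals, eigvecs, keep)`` with eigenvalues ascending (as
        from ``eigh``) and ``keep`` a boolean mask of components whose
        eigenvalue exceeds ``floor_ratio * max(eigval)``.  G built from
        in-sample frequencies is singular by construction (rows sum to ~0),
        so at least one component is always floored.
        """
        d, u = np.linalg.eigh(self.G)
        floor = floor_ratio * max(d.max(), 0.0)
        return d, u, d > floor

    def pinv(self, floor_ratio: float = EIG_FLOOR_RATIO) -> np.ndarray:
        """Eigen-floored pseudoinverse of G."""
        d, u, keep = self.eigen(floor_ratio)
        inv = np.zeros_like(d)
        inv[keep] = 1.0 / d[keep]
        return (u * inv) @ u.T


def impute_missing_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the per-SNP mean of observed dosages.

    Raises if any SNP has no observed call, naming the SNP.
    """
    d = g.dosages
    if not np.isnan(d).any():
        return g
    n_obs = (~np.isnan(d)).sum(axis=0)
    if (n_obs == 0).any():
        bad = g.snp_map["id"].iloc[int(np.argmin(n_obs))]
        raise ValueError(f"SNP {bad!r} has no observed genotype calls")
    col_mean = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), col_mean, d)
    return GenotypeMatrix(filled, g.snp_map, list(g.animal_ids))


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """In-sample allele frequency of the counted allele, p_j = mean(dosage_j)/2."""
    if np.isnan(g.dosages).any():
        raise ValueError("impute missing dosages before computing frequencies")
    return g.dosages.mean(axis=0) / 2.0


def center_genotypes(g: GenotypeMatrix, p: np.ndarray | None = None) -> CenteredGenotypes:
    """Center dosages as M[i,j] = dosage[i,j] - 2 p_j (VanRaden).

    ``p`` defaults to in-sample frequencies.  Monomorphic SNPs (p of 0 or 1)
    yield zero columns and contribute nothing to the denominator; they are
    retained so SNP indices stay aligned with the map for windowing.
    """
    p = allele_frequencies(g) if p is None else np.asarray(p, dtype=float)
    if p.shape != (g.n_snp,):
        raise ValueError("allele-frequency vector length does not match SNP count")
    M = g.dosages - 2.0 * p
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all SNPs are monomorphic; the VanRaden denominator is zero")
    return CenteredGenotypes(M=M, p=p, denom=denom, snp_map=g.snp_map,
                             animal_ids=list(g.animal_ids))


def vanraden_grm(cg: CenteredGenotypes) -> GenomicRelationship:
    """G = M M' / (2 sum_j p_j(1-p_j)); symmetric positive semidefinite."""
    G = (cg.M @ cg.M.T) / cg.denom
    G = (G + G.T) / 2.0  # remove floating-point asymmetry
    return GenomicRelationship(G=G, p=cg.p, denom=cg.denom, animal_ids=cg.animal_ids)


def grm_pca(grm: GenomicRelationship, n_components: int | None = None):
    """Principal components of G for population-structure inspection.

    Scores are eigenvector * sqrt(eigenvalue); explained-variance fractions
    are eigenvalues over their sum, with negative eigenvalues clamped to zero.
    Returns ``(scores, fractions)`` as a DataFrame / Series indexed PC1, PC2...
    """
    d, u = np.linalg.eigh(grm.G)
    order = np.argsort(d)[::-1]
    d, u = d[order], u[:, order]
    d_clamped = np.clip(d, 0.0, None)
    total = d_clamped.sum()
    fractions = d_clamped / total if total > 0 else d_clamped
    scores = u * np.sqrt(d_clamped)
    k = n_components or len(d)
    cols = [f"PC{i + 1}" for i in range(k)]
    idx = grm.animal_ids or range(grm.G.shape[0])
    return (
        pd.DataFrame(scores[:, :k], index=idx, columns=cols),
        pd.Series(fractions[:k], index=cols, name="variance_fraction"),
    )
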