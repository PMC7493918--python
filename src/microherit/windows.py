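"""Marker-effect backsolve and 1-Mb window genomic breeding values.

The per-animal additive genetic values u_hat from GBLUP are decomposed into
per-SNP effects

    a_hat = M' G^-1 u_hat / (2 sum_j p_j (1 - p_j))

using the same centered genotypes, allele frequencies and eigen-floored
G pseudoinverse as the fit, which guarantees the reconstruction identity
M a_hat = u_hat (for u_hat in the row space of G).  SNPs are then grouped
into non-overlapping 1-Mb windows anchored at bp 0 (half-open intervals
[k Mb, (k+1) Mb)); each animal's window GEBV is the sum of effect x
centered genotype over the window's SNPs, and windows are ranked by the
across-animal variance of their WGEBV.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grm import EIG_FLOOR_RATIO, CenteredGenotypes, GenomicRelationship

__all__ = [
    "backsolve_marker_effects",
    "assign_windows",
    "window_label",
    "window_gebv",
    "window_variance",
    "window_analysis",
    "select_top_phyla",
    "log1p_pearson",
]


def backsolve_marker_effects(cg: CenteredGenotypes, grm: GenomicRelationship,
                             u_hat,
                             eig_floor_ratio: float = EIG_FLOOR_RATIO) -> np.ndarray:
    """a_hat = M' G^- u_hat / denom with the eigen-floored pseudoinverse of G."""
    u_hat = np.asarray(u_hat, dtype=float).ravel()
    if u_hat.shape[0] != cg.M.shape[0]:
        raise ValueError("u_hat length does not match the number of animals")
    if grm.G.shape[0] != cg.M.shape[0]:
        raise ValueError("G dimension does not match the genotype matrix")
    g_inv_u = grm.pinv(eig_floor_ratio) @ u_hat
    return (cg.M.T @ g_inv_u) / cg.denom


def assign_windows(snp_map: pd.DataFrame,
                   window_size: int = 1_000_000) -> pd.DataFrame:
    """Assign every SNP to its (chromosome, floor(bp / window_size)) window.

    Windows are the half-open intervals [k*ws, (k+1)*ws); only windows that
    contain SNPs are materialized.  Returns a copy of the map with ``window``
    (index within chromosome), ``start_bp``, ``end_bp`` and a human-readable
    ``window_label`` column.
    """
    out = snp_map.copy()
    win = (out["bp"].to_numpy() // window_size).astype(int)
    out["window"] = win
    out["start_bp"] = win * window_size
    out["end_bp"] = (win + 1) * window_size
    out["window_label"] = [
        window_label(c, w, window_size)
        for c, w in zip(out["chrom"], win)
    ]
    return out


def window_label(chrom: int, window: int, window_size: int = 1_000_000) -> str:
    """Label like "27:3.0-4.0Mb" for window index 3 on chromosome 27."""
    mb = window_size / 1e6
    return f"{chrom}:{window * mb:.1f}-{(window + 1) * mb:.1f}Mb"


def window_gebv(cg: CenteredGenotypes, a_hat, windowed_map: pd.DataFrame,
                ) -> pd.DataFrame:
    """Per-animal WGEBV: sum of centered genotype x marker effect per window.

    Rows are animals, columns window labels; row sums over all windows equal
    the total reconstructed GEBV M a_hat exactly (the windows partition the
    SNPs).
    """
    a_hat = np.asarray(a_hat, dtype=float).ravel()
    if len(a_hat) != cg.M.shape[1]:
        raise ValueError("marker-effect length does not match SNP count")
    labels = windowed_map["window_label"].to_numpy()
    order = windowed_map.drop_duplicates("window_label")[
        ["chrom", "window", "window_label"]
    ].sort_values(["chrom", "window"])
    cols = {}
    for lab in order["window_label"]:
        idx = np.flatnonzero(labels == lab)
        cols[lab] = cg.M[:, idx] @ a_hat[idx]
    idx_names = cg.animal_ids or range(cg.M.shape[0])
    return pd.DataFrame(cols, index=idx_names)


def window_variance(wgebv: pd.DataFrame, y, windowed_map: pd.DataFrame | None = None,
                    ) -> pd.DataFrame:
    """Rank windows by the across-animal sample variance of their WGEBV.

    ``pct_phenotypic_variance`` is 100 * var(WGEBV_w) / var(y) with the raw
    phenotype's sample variance in the denominator (n-1 divisor throughout).
    Ties in variance are broken by window label so ranking is deterministic.
    """
    if len(wgebv) < 2:
        raise ValueError("window variance needs at least two animals")
    y = np.asarray(y, dtype=float).ravel()
    var_y = float(np.var(y, ddof=1))
    var_w = wgebv.var(axis=0, ddof=1)
    table = pd.DataFrame({
        "window_label": var_w.index,
        "wgebv_variance": var_w.to_numpy(),
        "pct_phenotypic_variance": 100.0 * var_w.to_numpy() / var_y
        if var_y > 0 else np.nan,
    })
    if windowed_map is not None:
        meta = windowed_map.groupby("window_label").agg(
            chrom=("chrom", "first"), start_bp=("start_bp", "first"),
            end_bp=("end_bp", "first"), n_snp=("id", "size"),
        )
        table = table.join(meta, on="window_label")
    table = table.sort_values(
        ["wgebv_variance", "window_label"], ascending=[False, True],
        kind="stable",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def window_analysis(cg: CenteredGenotypes, grm: GenomicRelationship, u_hat, y,
                    snp_map: pd.DataFrame | None = None,
                    window_size: int = 1_000_000) -> pd.DataFrame:
    """Backsolve, window and rank in one call; returns the window table."""
    snp_map = snp_map if snp_map is not None else cg.snp_map
    if snp_map is None:
        raise ValueError("a SNP map is required for windowing")
    a_hat = backsolve_marker_effects(cg, grm, u_hat)
    wmap = assign_windows(snp_map, window_size)
    wgebv = window_gebv(cg, a_hat, wmap)
    return window_variance(wgebv, y, wmap)


def select_top_phyla(window_tables: dict, k: int = 10) -> list:
    """Rank phyla by their largest window WGEBV variance; return the top k.

    ``window_tables`` maps phylum label -> window table.  Ties are broken by
    phylum label (lexicographic) for determinism.
    """
    if not window_tables:
        raise ValueError("no phylum window tables supplied")
    scored = sorted(
        ((float(t["wgebv_variance"].max()), name) for name, t in window_tables.items()),
        key=lambda s: (-s[0], s[1]),
    )
    return [name for _, name in scored[:k]]


def log1p_pearson(abundances: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of log(1 + x)-transformed abundances.

    Columns are taxa (possibly mixed levels), rows animals.  Zero-variance
    taxa yield missing correlations with a warning.
    """
    if abundances.shape[1] < 2:
        raise ValueError("need at least two taxa to correlate")
    if abundances.shape[0] < 3:
        raise ValueError("need at least three animals to correlate")
    transformed = np.log1p(abundances.astype(float))
    degenerate = transformed.std(ddof=0) == 0
    if degenerate.any():
        warnings.warn(
            "zero-variance taxa have undefined correlations: "
            f"{list(transformed.columns[degenerate])}"
        )
    corr = transformed.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    corr.values[np.ix_(degenerate.to_numpy(), np.ones(len(corr), bool))] = np.nan
    corr.values[np.ix_(np.ones(len(corr), bool), degenerate.to_numpy())] = np.nan
    np.fill_diagonal(corr.values, np.where(degenerate, np.nan, 1.0))
    return corr
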