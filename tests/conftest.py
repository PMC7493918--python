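"""Shared fixtures and dataset builders for the test suite."""

import numpy as np
import pandas as pd
import pytest

from microherit.community import OTUTable
from microherit.grm import GenotypeMatrix, center_genotypes, vanraden_grm
from microherit.simdata import SimulationConfig, simulate_dataset


def toy_genotypes(dosages, chrom=None, bp=None) -> GenotypeMatrix:
    """GenotypeMatrix from a plain array with a minimal sorted map."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    chrom = chrom if chrom is not None else [1] * m
    bp = bp if bp is not None else list(range(1, m + 1))
    snp_map = pd.DataFrame({
        "chrom": chrom, "id": [f"snp{j + 1}" for j in range(m)], "bp": bp,
    })
    return GenotypeMatrix(dosages, snp_map)


def toy_otu_table(counts, taxonomy=None) -> OTUTable:
    """OTUTable from a dict/DataFrame of counts with default taxonomy."""
    counts = pd.DataFrame(counts)
    if taxonomy is None:
        taxonomy = pd.DataFrame(
            {"phylum": "P1", "family": "F1", "genus": "G1"}, index=counts.columns
        )
    return OTUTable(counts, taxonomy)


def recovery_config(h2: float, seed: int, n_animals=400, n_snp=2000,
                    n_chrom=10, chrom_length_bp=20_000_000) -> SimulationConfig:
    """One-trait gaussian-mode config with a single 1-Mb QTL window."""
    return SimulationConfig(
        n_animals=n_animals, n_snp=n_snp, n_chrom=n_chrom,
        chrom_length_bp=chrom_length_bp,
        h2={"trait": h2},
        qtl_spec={"trait": [(n_chrom - 3, 3, 1.0)]} if h2 > 0 else {},
        seed=seed,
    )


def hwe_panel(n=200, m=5000, seed=0) -> GenotypeMatrix:
    """Unstructured Hardy-Weinberg panel (no subpopulations)."""
    cfg = SimulationConfig(n_animals=n, n_snp=m, n_chrom=10,
                           chrom_length_bp=50_000_000, subpop_divergence=0.0,
                           n_subpop=1, h2={}, qtl_spec={}, seed=seed)
    from microherit.simdata import simulate_genotypes

    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def small_gaussian_dataset():
    """Medium gaussian-mode dataset reused by several fitting tests."""
    cfg = recovery_config(h2=0.5, seed=42, n_animals=300, n_snp=1200)
    return simulate_dataset(cfg), cfg


@pytest.fixture(scope="session")
def counts_dataset():
    """Counts-mode dataset with the default (monofamilial-phylum) taxonomy."""
    cfg = SimulationConfig(
        n_animals=120, n_snp=600, n_chrom=10, chrom_length_bp=20_000_000,
        mode="counts", library_size=9000,
        qtl_spec={t: [(7, 3, 1.0)] for t in SimulationConfig().h2},
        seed=7,
    )
    return simulate_dataset(cfg), cfg


@pytest.fixture(scope="session")
def fitted_grm(small_gaussian_dataset):
    ds, _ = small_gaussian_dataset
    cg = center_genotypes(ds.genotypes)
    return cg, vanraden_grm(cg)
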