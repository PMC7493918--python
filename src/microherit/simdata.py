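"""Synthetic genotype + rumen-microbiome datasets with known architecture.

The generator emulates the structure of a beef-cattle rumen GWAS cohort:
~586 animals genotyped at ~62k SNP across 29 autosomes, weak two-
subpopulation structure (Balding-Nichols allele-frequency divergence, first
PC of G around 3% of the variance), cohort (contemporary-group) fixed
effects, and compositional 16S OTU counts in which designated taxa carry
additive genetic signal concentrated in designated 1-Mb QTL windows.

Two phenotype modes:

* ``gaussian`` — each taxon's phenotype is exactly y = Xb + u + e with
  u = M a (marker effects nonzero only inside the QTL windows), scaled to a
  target narrow-sense heritability.  This is model-matched to the GBLUP
  estimator and is what parameter-recovery tests use.
* ``counts`` — the same per-taxon signal is injected into latent OTU
  log-abundances, closed to proportions by a per-animal softmax, and read
  counts drawn multinomially at a Poisson library size.  Compositional
  closure attenuates the realized heritability, as it does in real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community import OTUTable
from .grm import GenotypeMatrix, center_genotypes

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulatedDataset",
    "build_taxonomy",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "hudson_fst",
]

# phyla/families echo dominant rumen taxa; one phylum (Fibrobacteres) is
# deliberately monofamilial so phylum- and family-level abundances coincide
DEFAULT_TAXONOMY = (
    ("Bacteroidetes", "Prevotellaceae", 40),
    ("Bacteroidetes", "S24-7", 25),
    ("Firmicutes", "Ruminococcaceae", 30),
    ("Firmicutes", "Lachnospiraceae", 25),
    ("Fibrobacteres", "Fibrobacteraceae", 8),
    ("Proteobacteria", "Succinivibrionaceae", 12),
)

DEFAULT_H2 = {
    "Prevotellaceae": 0.15,
    "S24-7": 0.10,
    "Ruminococcaceae": 0.15,
    "Lachnospiraceae": 0.10,
    "Fibrobacteraceae": 0.50,
    "Succinivibrionaceae": 0.55,
}

# one 1-Mb QTL window per taxon: (chromosome, window index, variance fraction)
DEFAULT_QTL = {
    "Prevotellaceae": [(23, 0, 1.0)],
    "S24-7": [(27, 3, 1.0)],
    "Ruminococcaceae": [(6, 3, 1.0)],
    "Lachnospiraceae": [(9, 63, 1.0)],
    "Fibrobacteraceae": [(27, 3, 1.0)],
    "Succinivibrionaceae": [(9, 63, 1.0)],
}

# contemporary groups: management-type x year blocks with additive shifts
DEFAULT_COHORTS = {
    "USMARC-H-2013": 0.010,
    "USMARC-S-2014": -0.010,
    "UNL-S-2013": 0.005,
    "UNL-S-2014": -0.005,
    "UNL-S-2015": 0.000,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror the emulated study design."""

    n_animals: int = 586
    n_snp: int = 61_974
    n_chrom: int = 29
    chrom_length_bp: int = 100_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpop: int = 2
    subpop_divergence: float = 0.03
    cohorts: dict = field(default_factory=lambda: dict(DEFAULT_COHORTS))
    taxonomy_spec: tuple = DEFAULT_TAXONOMY
    qtl_spec: dict = field(default_factory=lambda: dict(DEFAULT_QTL))
    h2: dict = field(default_factory=lambda: dict(DEFAULT_H2))
    phenotype_mean: float = 0.20
    phenotype_sd: float = 0.03
    latent_signal_sd: float = 0.7
    library_size: int = 32_000
    window_size: int = 1_000_000
    mode: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.mode not in ("gaussian", "counts"):
            raise ValueError("mode must be 'gaussian' or 'counts'")
        if self.subpop_divergence < 0:
            raise ValueError("subpop_divergence must be >= 0")
        if self.n_snp < self.n_chrom:
            raise ValueError("need at least one SNP per chromosome")
        for taxon, h2 in self.h2.items():
            if not 0 <= h2 <= 1:
                raise ValueError(f"h2 for {taxon!r} outside [0, 1]")
            qtl = self.qtl_spec.get(taxon, [])
            if h2 > 0 and not qtl:
                raise ValueError(
                    f"taxon {taxon!r} has h2={h2} but no QTL windows to carry it"
                )
            if qtl and not np.isclose(sum(f for _, _, f in qtl), 1.0):
                raise ValueError(f"QTL variance fractions for {taxon!r} must sum to 1")
        fam_per_phylum: dict[str, set] = {}
        for phylum, family, n in self.taxonomy_spec:
            fam_per_phylum.setdefault(phylum, set()).add(family)
            if n < 1:
                raise ValueError("each taxonomy_spec entry needs >= 1 OTU")
        if not any(len(f) == 1 for f in fam_per_phylum.values()):
            raise ValueError(
                "taxonomy_spec must contain at least one phylum with exactly one family"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "taxonomy_spec" in d:
            d["taxonomy_spec"] = tuple(tuple(t) for t in d["taxonomy_spec"])
        if "qtl_spec" in d:
            d["qtl_spec"] = {
                k: [tuple(q) for q in v] for k, v in d["qtl_spec"].items()
            }
        return cls(**d)

    def traits(self) -> list[str]:
        return list(self.h2)


@dataclass
class TruthRecord:
    """Ground truth stored alongside a simulated dataset."""

    h2: dict
    u: pd.DataFrame                 # animals x traits, true breeding values
    qtl_windows: dict               # trait -> [(chrom, window index), ...]
    cohort_effects: pd.DataFrame    # cohorts x traits, realized fixed effects
    cohort_of: pd.Series            # animal -> cohort label
    subpop_of: pd.Series            # animal -> subpopulation index


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame | None
    otu_table: OTUTable | None
    metadata: pd.DataFrame
    truth: TruthRecord


def build_taxonomy(taxonomy_spec) -> pd.DataFrame:
    """Expand (phylum, family, n_otus) triples into a per-OTU taxonomy table.

    OTU ids are OTU1..OTUn in spec order; each OTU belongs to exactly one
    family and each family to exactly one phylum.
    """
    if not taxonomy_spec:
        raise ValueError("taxonomy_spec is empty")
    rows, counter = [], 0
    fam_phylum: dict[str, str] = {}
    for phylum, family, n in taxonomy_spec:
        if fam_phylum.setdefault(family, phylum) != phylum:
            raise ValueError(f"family {family!r} assigned to two phyla")
        for _ in range(int(n)):
            counter += 1
            rows.append((f"OTU{counter}", phylum, family, f"g__{family}"))
    tax = pd.DataFrame(rows, columns=["otu", "phylum", "family", "genus"])
    if tax["otu"].duplicated().any():
        raise ValueError("duplicate OTU ids in taxonomy")
    return tax.set_index("otu")


def _subpop_assignment(n_animals: int, n_subpop: int) -> np.ndarray:
    # contiguous equal blocks, like animals sourced per location
    return (np.arange(n_animals) * n_subpop) // n_animals


def _chrom_positions(rng, n: int, length: int) -> np.ndarray:
    """n strictly increasing random bp positions on one chromosome."""
    pos = np.unique(rng.integers(1, length, size=int(n * 1.2) + 16))
    while len(pos) < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a 0/1/2 dosage matrix with Balding-Nichols subpopulation structure.

    Ancestral allele frequencies are uniform on ``maf_range``; each
    subpopulation's frequency is Beta-distributed around the ancestral value
    with variance F p(1-p) where F = ``subpop_divergence``, and genotypes are
    binomial(2, p_subpop) (Hardy-Weinberg within subpopulation).
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_animals, config.n_snp
    p_anc = rng.uniform(*config.maf_range, size=m)
    F = config.subpop_divergence
    if F > 0 and config.n_subpop > 1:
        a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
        p_sub = rng.beta(a, b, size=(config.n_subpop, m))
    else:
        p_sub = np.broadcast_to(p_anc, (max(config.n_subpop, 1), m))
    subpop = _subpop_assignment(n, max(config.n_subpop, 1))
    dosages = rng.binomial(2, p_sub[subpop, :]).astype(float)

    per_chrom = np.full(config.n_chrom, m // config.n_chrom)
    per_chrom[: m % config.n_chrom] += 1
    maps = []
    for c, k in enumerate(per_chrom, start=1):
        bp = _chrom_positions(rng, int(k), config.chrom_length_bp)
        maps.append(pd.DataFrame({
            "chrom": c,
            "id": [f"chr{c}_snp{i + 1}" for i in range(int(k))],
            "bp": bp,
        }))
    snp_map = pd.concat(maps, ignore_index=True)
    animal_ids = [f"animal_{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosages, snp_map, animal_ids)


def _window_members(snp_map: pd.DataFrame, chrom: int, window: int,
                    window_size: int) -> np.ndarray:
    idx = np.flatnonzero(
        (snp_map["chrom"].to_numpy() == chrom)
        & (snp_map["bp"].to_numpy() // window_size == window)
    )
    if idx.size == 0:
        raise ValueError(
            f"QTL window chr{chrom}:[{window} Mb, {window + 1} Mb) holds no "
            "simulated SNPs"
        )
    return idx


def _cohort_design(config: SimulationConfig, n: int):
    labels = list(config.cohorts) or ["cohort_1"]
    cohort_of = pd.Series(
        [labels[i % len(labels)] for i in range(n)],
        index=[f"animal_{i + 1}" for i in range(n)], name="contemporary_group",
    )
    effects = {}
    for lab in labels:
        eff = config.cohorts.get(lab, 0.0)
        effects[lab] = (
            {t: float(eff) for t in config.traits()} if np.isscalar(eff) else dict(eff)
        )
    eff_df = pd.DataFrame(effects).T.reindex(columns=config.traits()).fillna(0.0)
    return cohort_of, eff_df


def _true_breeding_values(M: np.ndarray, snp_map: pd.DataFrame,
                          config: SimulationConfig, rng) -> tuple[pd.DataFrame, dict]:
    """Per-trait u = M a with effects confined to the QTL windows, each
    window's component scaled to its share of unit genetic variance."""
    n = M.shape[0]
    u = {}
    qtl_windows = {}
    for trait in config.traits():
        h2 = config.h2[trait]
        total = np.zeros(n)
        qtl_windows[trait] = [(c, w) for c, w, _ in config.qtl_spec.get(trait, [])]
        if h2 > 0:
            for chrom, window, fraction in config.qtl_spec[trait]:
                idx = _window_members(snp_map, chrom, window, config.window_size)
                a = rng.standard_normal(idx.size)
                comp = M[:, idx] @ a
                sd = comp.std()
                if sd == 0:
                    raise ValueError(
                        f"QTL window chr{chrom}:{window} is monomorphic in this draw"
                    )
                total += comp * np.sqrt(fraction) / sd
            total -= total.mean()
            total /= total.std()  # unit genetic variance before trait scaling
        u[trait] = total
    idx = [f"animal_{i + 1}" for i in range(n)]
    return pd.DataFrame(u, index=idx), qtl_windows


def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimulationConfig):
    """Simulate per-taxon phenotypes on the given genotypes.

    Returns ``(phenotypes, truth)`` where ``phenotypes`` is an animals x
    taxa DataFrame of proportions in gaussian mode or an :class:`OTUTable`
    in counts mode.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cg = center_genotypes(genotypes)
    n = genotypes.n_animals
    u_unit, qtl_windows = _true_breeding_values(cg.M, genotypes.snp_map, config, rng)
    cohort_of, eff_df = _cohort_design(config, n)
    subpop = pd.Series(_subpop_assignment(n, max(config.n_subpop, 1)),
                       index=u_unit.index, name="subpop")

    sd = config.phenotype_sd
    u_scaled, liabilities = {}, {}
    for trait in config.traits():
        h2 = config.h2[trait]
        u_t = u_unit[trait].to_numpy() * np.sqrt(h2) * sd
        e_t = rng.normal(0.0, np.sqrt(max(1 - h2, 0.0)) * sd, size=n)
        xb = eff_df.loc[cohort_of.values, trait].to_numpy()
        u_scaled[trait] = u_t
        liabilities[trait] = xb + u_t + e_t
    u_df = pd.DataFrame(u_scaled, index=u_unit.index)
    truth = TruthRecord(h2=dict(config.h2), u=u_df, qtl_windows=qtl_windows,
                        cohort_effects=eff_df, cohort_of=cohort_of, subpop_of=subpop)

    if config.mode == "gaussian":
        phen = pd.DataFrame(liabilities, index=u_unit.index)
        phen = (config.phenotype_mean + phen).clip(0.0, 1.0)
        return phen, truth

    # counts mode: inject the trait signal into latent OTU log-abundances of
    # the trait's family, close to proportions, draw multinomial reads
    tax = build_taxonomy(config.taxonomy_spec)
    base = rng.normal(0.0, 1.5, size=len(tax))
    latent = np.tile(base, (n, 1))
    scale = config.latent_signal_sd / sd  # liability is on the sd-proportion scale
    for trait in config.traits():
        cols = np.flatnonzero(tax["family"].to_numpy() == trait)
        if cols.size:
            latent[:, cols] += (liabilities[trait] * scale)[:, None]
    expo = np.exp(latent - latent.max(axis=1, keepdims=True))
    probs = expo / expo.sum(axis=1, keepdims=True)
    libraries = np.maximum(rng.poisson(config.library_size, size=n), 1)
    counts = np.vstack([
        rng.multinomial(libraries[i], probs[i]) for i in range(n)
    ])
    table = OTUTable(
        pd.DataFrame(counts, index=u_unit.index, columns=tax.index), tax
    )
    return table, truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Genotypes + phenotypes + metadata + truth in one call."""
    genotypes = simulate_genotypes(config)
    result, truth = simulate_phenotypes(genotypes, config)
    metadata = pd.DataFrame({
        "contemporary_group": truth.cohort_of,
        "subpop": truth.subpop_of,
    })
    if config.mode == "gaussian":
        return SimulatedDataset(genotypes, result, None, metadata, truth)
    return SimulatedDataset(genotypes, None, result, metadata, truth)


def hudson_fst(dosages: np.ndarray, subpop: np.ndarray) -> np.ndarray:
    """Per-SNP Hudson Fst estimator between two subpopulations.

    Uses allele counts (2 per diploid individual); returns the ratio of the
    unbiased numerator to the denominator per SNP.
    """
    subpop = np.asarray(subpop)
    groups = np.unique(subpop)
    if len(groups) != 2:
        raise ValueError("Hudson Fst is defined for exactly two subpopulations")
    out = []
    d1 = dosages[subpop == groups[0]]
    d2 = dosages[subpop == groups[1]]
    n1, n2 = 2 * d1.shape[0], 2 * d2.shape[0]
    p1, p2 = d1.mean(axis=0) / 2, d2.mean(axis=0) / 2
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = num / den
    return fst
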