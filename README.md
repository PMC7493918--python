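# microherit

Host-genetic control of rumen microbial community composition: per-taxon
genomic heritability by Bayesian GBLUP, decomposition of breeding values
into SNP effects, and ranking of 1-Mb genomic windows by the variance of
window breeding values, with positional candidate-gene annotation.

The package is aimed at quantitative geneticists and microbial ecologists
who have, for a cohort of animals, (a) a SNP dosage matrix with a physical
map, (b) a 16S OTU count table with taxonomy, and (c) per-animal metadata
(contemporary groups), and who want to ask: *how much of the variation in
the relative abundance of a rumen taxon is explained by host genetics, and
where in the genome does that signal sit?*

## The model

For each taxon (OTU, family or phylum), the phenotype is the untransformed
relative abundance **y**, modelled as

    y = Xb + Zu + e,    u ~ N(0, G σ²_u),    e ~ N(0, I σ²_e)

where **X** carries the intercept, the first two principal components of
**G**, and contemporary-group indicators; **G** is the VanRaden genomic
relationship matrix

    G = M M' / (2 Σⱼ pⱼ(1 − pⱼ))

built from allele-frequency-centered dosages **M**. Variance components get
scaled inverse-χ² priors (df = 5, scales chosen so the prior mode splits
var(y) as R² : 1 − R² with R² = 0.20), b gets a flat prior, and the model
is sampled by a Gibbs sampler in the eigenbasis of **G** (default chain:
102,000 iterations, 2,000 burn-in, thinning 10). Heritability is reported
as the posterior mean ± SD of h² = σ²_u / (σ²_u + σ²_e) over the retained
samples, with an autocorrelation-adjusted effective sample size.

For association, posterior-mean breeding values û are backsolved into
per-SNP effects

    â = M' G⁻¹ û / (2 Σⱼ pⱼ(1 − pⱼ))

SNPs are grouped into non-overlapping 1-Mb windows, each animal's window
breeding value (WGEBV) is Σ within-window (centered dosage × effect), and
windows are ranked by the across-animal variance of WGEBV, expressed also
as a percentage of the phenotypic variance. Top windows are intersected
with a BED gene annotation to propose positional candidate genes.

A synthetic-data module (`microherit.simdata`) generates matched
genotype/microbiome datasets with known heritability, known QTL windows,
Balding–Nichols subpopulation structure and cohort effects — in a
model-matched "gaussian" mode and a compositional "counts" mode — so every
stage is testable by parameter recovery without external data.

## Worked example

```python
import numpy as np
from microherit import (
    SimulationConfig, simulate_dataset, GBLUPRegressor,
    center_genotypes, vanraden_grm, window_analysis, window_label,
)

cfg = SimulationConfig(
    n_animals=300, n_snp=1500, n_chrom=10, chrom_length_bp=15_000_000,
    h2={"Fibrobacteraceae": 0.5},
    qtl_spec={"Fibrobacteraceae": [(7, 3, 1.0)]},  # chr7, 3-4 Mb window
    seed=3,
)
ds = simulate_dataset(cfg)

model = GBLUPRegressor(n_iter=12_000, burn_in=2_000, thin=10, seed=1)
model.fit(ds.genotypes, ds.phenotypes["Fibrobacteraceae"],
          groups=ds.metadata["contemporary_group"])
print(f"h2 = {model.h2_mean_:.2f} +/- {model.h2_sd_:.2f}  "
      f"(ESS {model.ess_h2_:.0f})")

cg = center_genotypes(ds.genotypes)
table = window_analysis(cg, model.grm_, model.u_,
                        ds.phenotypes["Fibrobacteraceae"])
print(table.head(2)[["window_label", "pct_phenotypic_variance", "rank"]])
```

prints

```
h2 = 0.35 +/- 0.12  (ESS 175)
  window_label  pct_phenotypic_variance  rank
0  7:3.0-4.0Mb                 0.244120     1
1  9:1.0-2.0Mb                 0.057154     2
```

The simulated QTL window (chromosome 7, 3.0–4.0 Mb) ranks first by WGEBV
variance. The heritability estimate sits below the simulated 0.5 because at
this panel size the likelihood is weakly informative about the σ²_u/σ²_e
split and the R² = 0.20 prior shrinks the posterior toward 0.2 — see
`docs/methods.md` for when this matters.

The same pipeline is scriptable from the shell (`microherit simulate`,
`microherit community`, `microherit grm`, `microherit fit`,
`microherit windows`, `microherit annotate`, `microherit correlate`).

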