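# Methods

## Scope and data flow

The pipeline starts from an OTU count table (animals × OTUs, with a
taxonomy assigning each OTU a genus/family/phylum), a SNP dosage matrix
(animals × SNPs, 0/1/2 with missing allowed, plus a chromosome/bp map) and
per-animal metadata carrying a contemporary-group factor (management type ×
year). Upstream read processing (contig assembly, OTU clustering, chimera
removal, taxonomy assignment) is out of scope; the count table is the
entry point.

Stages: community processing (filters, relative abundance, aggregation,
rarefaction, Bray–Curtis/PCoA/PERMANOVA) → genomic relationship matrix →
per-taxon Bayesian GBLUP → marker-effect backsolve and 1-Mb window
variances → candidate-gene annotation.

## Community statistics

* **Taxon removal**: OTUs classified to a given rank label (typically the
  phylum Cyanobacteria, a chloroplast-16S artifact in plant-rich digesta)
  are dropped before analysis.
* **Core measurable microbiome (CMM)**: operationalized as a prevalence
  filter — an OTU is retained if it is detected in at least
  `ceil(threshold × n_animals)` animals, threshold 1% by default and
  exposed as a parameter (the boundary is inclusive). Whether an abundance
  floor should accompany the prevalence rule is left to the user; none is
  imposed by default.
* **Relative abundance** divides each animal's counts by its total; an
  all-zero animal is an error naming the animal.
* **Aggregation** to family/phylum sums member-OTU counts; unclassified
  labels pool into `unclassified_<level>`. Reads are conserved exactly.
* **Rarefaction** subsamples each animal to a fixed depth (default 7,000
  reads) without replacement via the multivariate hypergeometric
  distribution; animals below depth are dropped with a log message rather
  than erroring — standard practice when a handful of shallow libraries
  should not abort a cohort analysis.
* **Good's coverage** is 1 − singletons/reads per animal.
* **Bray–Curtis / PCoA / PERMANOVA** delegate to scipy and scikit-bio.
  PCoA axes with non-positive eigenvalues are dropped and explained-variance
  fractions renormalized over the positive spectrum. PERMANOVA permutes
  labels freely (no strata) and reports p = (1 + #{F* ≥ F}) / (1 + B).
* **Taxon selection for association**: OTUs need ≥ 40,000 total reads and
  ≥ 95% prevalence (inclusive boundaries); families need strictly more than
  1.8% of total reads, ranked by reads and capped at 12; phyla are ranked
  by their largest window variance and capped at 10. All thresholds are
  parameters with these defaults.

## Genomic relationship matrix

Missing dosages are imputed with the per-SNP mean of observed calls. Allele
frequencies are computed in-sample after imputation (an external frequency
vector can be supplied instead); "the counted allele" is whichever allele
the dosage encodes — with in-sample centering the choice does not affect G.
Centering is M = dosage − 2p per SNP and G = MM′ / (2Σp(1−p)). Monomorphic
SNPs are retained as zero columns (keeping SNP indices aligned with the map
for windowing) and contribute nothing to the denominator. With in-sample
frequencies G is singular by construction (its rows sum to ~0); no PSD
repair is applied — downstream consumers use an eigenvalue floor of
1e-8 × λ_max, below which components are treated as null. Population
structure is summarized by the eigendecomposition of G (scores =
eigenvector × √eigenvalue; negative eigenvalues clamped to zero for the
variance fractions); the first two PCs feed the fixed-effects design.

## Bayesian GBLUP

Model: y = Xb + Zu + e with u ~ N(0, Gσ²_u), one record per animal
(Z = I). y is the untransformed relative abundance. X = intercept + PC1 +
PC2 + contemporary group, reference-coded (first level dropped) so X is
full column rank under the flat prior on b; a rank check reports collinear
columns.

Priors: σ²_u and σ²_e get scaled inverse-χ² priors with df = 5 and scale
factors S_u = var(y)·R²·(df+2)/mean(diag G), S_e = var(y)·(1−R²)·(df+2),
R² = 0.20 — i.e., the prior mode splits var(y) as R² : (1−R²). Under this
χ⁻²(df, S) parameterization the full-conditional draw is
(sum-of-squares + S)/χ²_{df+n}: the prior scale enters the posterior
sum of squares once.

Sampling: G = UDU′ is eigendecomposed once; rotating the model by U′ makes
the genetic effects conditionally independent, so each sweep draws b from
its Gaussian conditional, the rotated effects elementwise, and the two
variances from scaled inverse-χ² conditionals. Components with eigenvalue
below the floor carry no genetic variance and are excluded from u′G⁻u and
its degrees of freedom (n₊ counts the kept components). Default chain:
102,000 iterations, 2,000 burn-in, thinning 10 → exactly 10,000 retained
samples; tests use shortened chains and say so. Chains are reproducible
from a seed. Initial values are the prior modes.

Heritability is the posterior mean ± SD of σ²_u/(σ²_u+σ²_e) over retained
samples; û is the posterior mean of u over retained samples. Effective
sample size uses n/(1 + 2Σρ_k) with Geyer's initial-positive-sequence
truncation, clipped to (0, n].

`blup_solve` provides the deterministic mixed-model-equation solution at
fixed variance components (GLS via the same eigendecomposition); with
variances clamped, the Gibbs chain's mean of (b, u) converges to it, which
the tests exploit as an oracle. A second, stronger oracle integrates the
closed-form marginal likelihood of (σ²_u, σ²_e) against the priors on a
2-D grid and checks the chain against the exact posterior mean of h².

### When is h² well identified?

The information about the σ²_u : σ²_e split scales with the variance of the
off-diagonal genomic relationships, roughly var(G_ij) ≈ 1/m_eff for
m_eff independent SNPs: the sampling SD of any h² estimator is about
√(2·m_eff)/n. With n = 400 animals and m = 2,000 independent simulated
SNPs that SD is ≈ 0.16 per dataset, the likelihood is nearly flat along
the h² direction, and the R² = 0.20 prior dominates: posterior means land
near 0.22/0.38/0.53 when the simulated truth is 0.1/0.5/0.8 (the exact
grid posterior gives the same numbers — this is a property of the model at
those conditions, not of the sampler). With m comparable to n (var(G_ij)
larger) the posterior tracks truth to within ±0.10. Real SNP panels sit in
between: linkage disequilibrium makes m_eff far smaller than the SNP count
(a few thousand in cattle), so cohort-scale analyses are moderately
informative and estimates remain visibly shrunk toward the prior's R².
Reported h² posterior means should therefore be read jointly with their
posterior SDs and the prior assumption.

## Marker effects and 1-Mb windows

â = M′G⁻û / (2Σp(1−p)) with G⁻ the eigen-floored pseudoinverse sharing the
GBLUP floor, which guarantees Mâ = û exactly for û in the row space of G.
Windows are half-open [k Mb, (k+1) Mb) anchored at bp 0; every SNP belongs
to exactly one window and empty windows are not materialized. WGEBV per
animal and window is Σ centered dosage × effect over the window's SNPs, so
window WGEBVs sum to the reconstructed total GEBV exactly. Window variance
is the across-animal sample variance (n−1 divisor); the percentage of
phenotypic variance divides by the raw sample variance of y (an option
switches the denominator to fixed-effect-adjusted y). Ranking is by
variance, descending, ties broken by window label. Pairwise taxon
correlations use Pearson r on log(1+x)-transformed relative abundances;
zero-variance taxa yield missing entries with a warning.

## Candidate genes

BED4 input (0-based, half-open) is the internal coordinate standard, and
windows are also half-open bp intervals, so overlap needs no coordinate
shift: gene ∩ window ⇔ gene.start < window.end and gene.end > window.start
(≥ 1 bp). "chr" prefixes are stripped for cross-annotation compatibility.
A GFF3 reader maps `gene` features to the same records. Windows without
genes are reported with an empty gene field. The package is genome-build
agnostic — the annotation is supplied by the user.

## Synthetic data

The generator emulates a two-location beef-cattle cohort: defaults are 586
animals, 61,974 SNPs on 29 autosomes (uniform positions on 100-Mb
chromosomes), allele frequencies uniform on [0.05, 0.5], two
subpopulations with Balding–Nichols divergence F = 0.03, five contemporary
groups with small additive shifts, and a rumen-like taxonomy in which the
phylum Fibrobacteres deliberately contains a single family
(Fibrobacteraceae) so that phylum- and family-level abundances coincide —
the analytic ground for the r = 1.0 correlation check. Under
Balding–Nichols the expected within/between-subpopulation relationship
entries are ±F, so PC1 of G explains ≈ F of the variance when structure
dominates noise; F = 0.03 therefore reproduces a first PC at ~3%.

Genetic architecture: each taxon's QTL windows get standard-normal SNP
effects rescaled so each window contributes its configured fraction of a
unit genetic variance (one window per taxon by default — a modeling choice,
as real architectures are unknown). In **gaussian** mode the phenotype is
exactly y = baseline + Xb + u + e with u scaled to the target h² of a
0.03²-variance proportion around 0.20 (clipping to [0, 1] is then
negligible, keeping the data model-matched for recovery tests). In
**counts** mode the same per-taxon signal is added to the latent
log-abundances of the taxon's member OTUs (lognormal baselines, σ = 1.5),
closed per animal by softmax and sampled multinomially at a
Poisson-distributed library size (mean 32,000 reads). Compositional closure
attenuates realized heritability in counts mode, as in real data, which is
why estimator-calibration tests use gaussian mode: passing them shows the
estimator is correct under its own model, not that compositional 16S data
meet that model.

Not simulated: linkage disequilibrium (SNPs are independent given
subpopulation frequencies), pedigree/family relatedness, read-level 16S
error. Consequently the synthetic panels are *less* informative about h²
per SNP than real livestock panels with LD and relatedness (see the
identifiability note above), and detection-power results transfer to real
data only qualitatively.

## Test problem sizes

Simulation-backed tests run at a few hundred animals and a few hundred to
a few thousand SNPs with 6k–12k-iteration chains — sizes at which every
check completes in seconds to a couple of minutes while keeping the Monte
Carlo error well inside the asserted bounds; the chain-bookkeeping check
runs the full 102,000-iteration default on a small panel. The acceptance
script states the size used alongside every reported value.
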