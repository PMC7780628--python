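# Methods

`hololink` implements an integrated analysis of a host–microbiome
("holobiont") exposure experiment: clonal host genotypes split into
wild-type and antibiotic-depleted (germ-free) lines, exposed to a control
condition and two herbicide treatments (glyphosate and its commercial
formulation), with gene expression, gut sOTU communities and life-history
traits measured per replicate. This note records the models, the
numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Synthetic holobiont generator

The generator (`hololink.simulate`) produces datasets with planted,
exactly recorded ground truth.

**Expression.** Gene counts are negative binomial. Baseline expected
proportions are log-normal across genes; genotype and treatment act
multiplicatively on the mean via log-normal draws with standard
deviations `genotype_effect_sd` and `treatment_effect_sd` (log scale,
defaults 0.4). The NB dispersion (`dispersion`, default 0.2) follows the
usual Var = μ + φμ² parameterization. Expected library size
`depth_mean_expr` (default 100,000 reads at desk scale).

**Community.** sOTU counts are Dirichlet-multinomial. A configurable
core (default 8 of 80 taxa) holds a fixed total relative abundance
(`core_abundance`, default 0.7) and is stable across genotypes and
treatments, emulating the empirical pattern that core taxa resist
perturbation. Non-core taxa get genotype-specific log-normal multipliers,
and each herbicide treatment multiplies a random half of the non-core
taxa by log-normal factors. Germ-free arms remove a fixed random subset
of non-core taxa (default 50%) and scale depth (default 0.6) — richness
and depth reduction without modeling antibiotic kinetics. The latent
composition is converted to counts by a Dirichlet draw (precision
`dm_concentration`, default 300) followed by a multinomial at fixed
depth, so sample depths are exact and compositionality holds.

**Planted links.** For each linked sOTU the latent log relative
abundance is shifted by `link_strength` times the mean z-scored
(log1p CPM) expression of its assigned driver gene(s) *before* any count
sampling. Three deliberate choices:

- `genes_per_link` defaults to 1. The downstream selection rule keeps
  genes holding ≥ 20% of total importance — by construction a detector of
  single genes of major effect. A link spread over several genes splits
  impurity credit between them and is not the regime the selection rule
  targets.
- Linked sOTUs are drawn from the more abundant half of surviving
  non-core taxa: a link planted on a taxon at 10⁻⁴ relative abundance is
  unidentifiable under multinomial counting noise at realistic depths.
- `link_recovery_config` freezes the recovery benchmark: a single
  genotype, 12 control + 12 glyphosate replicates, 60 genes, 10 sOTUs
  (2 linked), treatment effect SD 0.1, link strength 2. Within one
  genetic background the link signal is carried by replicate-level
  covariation; with several genotypes, genotype-structured expression
  confounds every gene with the community and gene-level attribution is
  not identifiable by any importance measure.

**Traits.** Continuous traits are log-normal around a genotype +
treatment + interaction linear predictor (herbicides reduce size and
fecundity, delay maturity); failed-development counts are binomial per
clutch with a treatment-shifted logit failure probability; comet tail
intensity is Beta-distributed around a treatment-shifted mean.

**What the generator does not emulate:** raw reads, chimeras, amplicon or
extraction bias, phylogenetic correlation between taxa, taxon–taxon
interactions, and temporal dynamics. Passing recovery tests therefore
shows the estimator chain is correct under the stated stochastic model,
not that real gut data meet those assumptions.

## Preprocessing rules

Fixed order: sample depth → feature total reads → feature
prevalence-in-samples → replicate correlation → rank collapse → prevalence
fraction. Sample-level rules run first so feature rules see the final
sample set. Defaults: samples with < 500 reads dropped; sOTUs with < 10
total reads dropped (the "low abundance" rule is read as a feature-total
rule because sample coverage is already handled by the 500-read rule);
sOTUs observed in < 2 samples dropped (strict `<`, presence = count > 0);
replicates with mean within-cell Pearson r < 0.4 dropped, computed on
relative abundances so library size does not dominate r; collapse at
genus with `unclassified:<ancestor>` fallback; genus-level prevalence
≥ 60% of samples (inclusive). Core taxa: mean relative abundance
strictly > 1% within a treatment. Rarefaction uses exact multivariate
hypergeometric draws to the minimum sample depth, seed-deterministic.

## Community statistics

Shannon entropy is reported in nats, so Pielou evenness H/ln S lands in
[0, 1]; the base is configurable in principle but natural log is the
package convention. Bray-Curtis is computed on counts, Jaccard on
presence/absence (SciPy `pdist`). The PERMANOVA partitions the
Gower-centered inner-product matrix G = C(−½ D∘D)C sequentially (Type I)
over an ordered term list with treatment-coded dummy blocks; term df is
the rank increment of the cumulative design (SVD with a relative
tolerance), so structurally missing cells reduce an interaction's df as
in vegan's `adonis2` (verified against it in the test suite). A term
adding no rank at all raises an error naming it. Significance permutes
raw sample labels (rows/columns of D jointly):
p = (1 + #{F* ≥ F})/(1 + n_perm), default 9999 permutations, giving the
conventional 10⁻⁴ floor.

## Random-forest linkage

Per treatment the design pools control + treatment samples (exposed as
`include_control`); predictors are z-scored log1p CPM expression,
responses log1p relative abundance per sOTU. Hyperparameters are tuned by
randomized search (default 100 draws; the full grid when smaller) over
trees {100..500}, depth {2..16, ∞}, features-per-split
{√p, 0.1..0.5, 1.0} and leaf size {1..5}, scored by k-fold (default 3)
mean held-out MSE; ties break toward fewer trees, then shallower depth.
The winner is refitted 80 times (independent seeds) on the full subset
and normalized impurity importances are averaged. A gene is selected at
≥ 20% importance share (hence at most ⌊1/0.2⌋ = 5 genes per sOTU); a model
is kept only if its mean CV MSE beats Var(y) (population variance), the
package's operational criterion for "significantly correlated". The
`scaled_down` configuration (10 runs, 10 draws, trees {50, 100}) is the
desk-scale setting used by the bundled benchmark and acceptance script.

## Weighted pathway enrichment

Annotation runs through orthologs of a related reference species, so one
host gene can map to several pathways. Each annotated gene distributes
total mass 1: 1/m(g) to each of its m(g) pathways, the remainder to the
off-pathway cell of each 2×2 table — multiplicity then cannot inflate
enrichment (an all-weight-1 alternative is available via
`build_weighted_table`'s caller). Fisher's exact test needs integers:
w11, w12, w21 are rounded nearest-ties-to-even and the last cell absorbs
the difference to preserve the rounded grand total; with unit weights the
procedure is exactly the classical one-sided Fisher test. The chi-square
statistic is computed on the raw fractional cells (1 df, no continuity
correction; it scales linearly with the cells). BH FDR is applied per
test family; the significance flag uses the Fisher q at α = 0.05.

## Fitness statistics

Failed development = (AE + DO)/(AE + DO + LO); tail intensity % =
100·tail/(tail + head). Trait ANOVAs are sequential (Type I) in the order
genotype → treatment → interaction, F against the residual mean square;
continuous traits are natural-log transformed first, the
failed-development fraction is tested untransformed. Mixed models with a
replicate random effect are out of scope — the fixed-effects `aov`-style
table is the reported analysis.

## Pipeline and reproducibility

One master seed spawns per-stage child seeds (`numpy.random.SeedSequence`)
so each stage is independently reproducible; the manifest records the
config echo, stage seeds and SHA-256 of every output. Identical config +
seed reproduces identical hashes (tested). Problem sizes in the bundled
tests and acceptance script (500 null PERMANOVA simulations at 199
permutations, 200 enrichment null datasets, 5 recovery seeds at the
`link_recovery_config` scale) are the package's desk-scale defaults; all
thresholds and sizes are config-exposed for larger studies.

## Known limitations

- The quality rule (CV MSE < Var y) is a pragmatic filter, not a
  calibrated test; permutation-based model significance would be the
  rigorous alternative.
- The weighted Fisher rounding step discards sub-integer information;
  the chi-square path keeps it, which is why both are reported.
- PERMANOVA uses raw-label permutation; under strongly unbalanced
  designs residual permutation (Freedman–Lane) would be preferable.
- Genus-level collapse assumes the taxonomy is consistent; conflicting
  lineages are not reconciled.
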