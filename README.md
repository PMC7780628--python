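# hololink

Integrated analysis of host–microbiome ("holobiont") exposure
experiments: microbiome preprocessing, community diversity and
multi-factor PERMANOVA, a replicated random-forest procedure linking host
gene expression to gut sOTU abundances, ortholog-multiplicity-weighted
pathway enrichment, and life-history/genotoxicity statistics — plus a
synthetic data generator with planted ground truth so the whole chain is
testable without any sequencing data.

The package is aimed at ecotoxicology and microbiome researchers who run
clonal-host exposure designs (e.g. *Daphnia* genotypes split into
wild-type and antibiotic-treated germ-free lines, exposed to control and
herbicide conditions) and want the downstream statistics in one tested,
scriptable toolbox.

## The core methods

**Community statistics.** Shannon H = −Σ pᵢ ln pᵢ (nats), Pielou
evenness H/ln S, observed sOTUs; Bray-Curtis Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) and
Jaccard 1 − |A∩B|/|A∪B|. PERMANOVA partitions the Gower-centered matrix
G = C(−½ D∘D)C sequentially over genotype (G), treatment (T), antibiotic
(A) and their interactions; pseudo-F = (SSₜ/dfₜ)/(SSᵣ/dfᵣ) with p from
raw-label permutation, p = (1 + #{F* ≥ F})/(1 + n_perm). For Euclidean
distances the partition equals classical linear-model ANOVA (and is
cross-checked against vegan's `adonis2` in the test suite).

**Transcriptome → microbiome linkage.** Per treatment (pooled with
controls), per sOTU: a random-forest regression of log1p relative
abundance on z-scored log1p-CPM expression, tuned by randomized CV search
(100 draws) and refitted 80 times; impurity importances are averaged and
a gene is selected when it holds ≥ 20% of total importance (at most
⌊1/0.2⌋ = 5 genes per sOTU). Models must beat the mean predictor in CV
MSE to enter the pooled linked sets.

**Weighted enrichment.** Host genes annotated through orthologs may map
to several pathways; each annotated gene spreads total weight 1 as 1/m(g)
per mapped pathway in the 2×2 contingency tables, so non-unique mappings
cannot inflate enrichment. One-sided Fisher (on rounded cells) and
chi-square (on fractional cells) p-values get Benjamini-Hochberg FDR.

**Fitness.** Failed development = (AE+DO)/(AE+DO+LO), comet tail
intensity % = 100·tail/(tail+head), and sequential two-way ANOVAs
(genotype, treatment, interaction) on optionally log-transformed traits.

Full model and parameter documentation: [docs/methods.md](docs/methods.md).

## Worked example

```python
from hololink.simulate import link_recovery_config, generate_dataset, truth_recovery_report
from hololink import preprocess, community, rflink

ds = generate_dataset(link_recovery_config(seed=1))   # 60 genes x 36 samples, 10 sOTUs, 2 planted links
dm = community.beta_diversity(ds.sotus, "bray_curtis")
print(community.permanova(dm, ds.samples, terms=("treatment",), n_perm=999, seed=1).round(4))

expr, _ = preprocess.filter_genes(ds.expression)
cfg = rflink.LinkConfig.scaled_down(seed=1, treatments=("glyphosate",))
res = rflink.link_analysis(expr, ds.sotus, ds.samples, cfg)
print(res.pair_table().round(3))
print(truth_recovery_report(res, ds.truth))
```

prints

```
     term  df     SS     R2      F     p
treatment   2 0.0367 0.0223 0.3767 0.864
 Residual  33 1.6075 0.9777    NaN   NaN
    Total  35 1.6442 1.0000    NaN   NaN

 treatment   sotu_id    gene_id  mean_importance
glyphosate sOTU_0000 gene_00033            0.386
glyphosate sOTU_0003 gene_00033            0.703
glyphosate sOTU_0009 gene_00045            0.631
...
{'pair_recall': 1.0, 'pair_precision': 0.286, 'gene_recall': 1.0, ...}
```

The PERMANOVA treatment term is small here because this scenario plants
links within a single genotype with a mild treatment effect (R² = 0.02,
p = 0.86). Both planted driver genes (`gene_00033` → `sOTU_0003`,
`gene_00045` → `sOTU_0009`) are recovered with the largest importance
shares (0.70 and 0.63), giving recall 1.0; the extra selections on
unlinked sOTUs are the price of the permissive model-quality rule and
show up as precision < 1.

A full pipeline run (simulate → preprocess → diversity → PERMANOVA →
linkage → enrichment → fitness) is one command:

```sh
hololink run-all --config demo.yaml --out out/
```

where `demo.yaml` declares either a `simulate:` block or paths to your
own TSV tables (counts are features × samples; see `hololink.io` for the
exact dialect). Every stage writes TSV outputs and a `manifest.json`
with stage seeds and SHA-256 hashes; identical config + seed reproduces
identical hashes.

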