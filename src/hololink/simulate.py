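"""Synthetic holobiont datasets with planted ground truth.

Emulates the statistical structure of a clonal host exposure experiment:
isogenic genotype lines, a control and two herbicide treatments, and a
split antibiotic design (wild-type vs germ-free arms), each cell
replicated.  The generator produces

* a gene-expression count matrix: negative-binomial counts whose means
  carry multiplicative (log-normal scale) genotype and treatment effects;
* an sOTU community matrix: Dirichlet-multinomial counts around a
  genotype-specific base composition, with treatment multipliers on a
  subset of non-core taxa, a stable core at a configurable total relative
  abundance, and germ-free arms with depleted richness and depth;
* planted transcriptome->microbiome links: for each linked sOTU, the
  latent log relative abundance is shifted by ``link_strength`` times the
  mean z-scored (log1p CPM) expression of its assigned genes, before any
  count sampling, so compositionality is preserved;
* a many-to-many gene->ortholog->pathway map, a seven-rank taxonomy, and
  a life-history trait table.

Everything planted is recorded in a :class:`GroundTruth` object so that
downstream recovery can be scored exactly.  A fixed seed yields
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    CountMatrix,
    OrthologPathwayMap,
    SampleTable,
    TaxonomyTable,
    TraitTable,
    ValidationError,
    parse_lineage,
    write_table,
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic holobiont experiment (desk scale)."""

    n_genotypes: int = 4
    treatments: tuple[str, ...] = ("control", "glyphosate", "roundup")
    antibiotic_arms: bool = True
    n_replicates_per_cell: int = 3
    n_genes: int = 300
    n_sotus: int = 80
    n_core_taxa: int = 8
    core_abundance: float = 0.7  # total relative abundance held by core taxa
    depth_mean_expr: int = 100_000
    depth_mean_sotu: int = 20_000
    genotype_effect_sd: float = 0.4  # log-scale
    treatment_effect_sd: float = 0.4  # log-scale
    n_linked_sotus: int = 3
    genes_per_link: int = 1
    link_strength: float = 2.0
    dispersion: float = 0.2  # negative-binomial overdispersion of expression
    dm_concentration: float = 300.0  # Dirichlet precision of the community
    antibiotic_removal_fraction: float = 0.5  # of non-core taxa in germ-free arms
    antibiotic_depth_factor: float = 0.6
    n_pathways: int = 12
    multiplicity_dist: dict = field(
        default_factory=lambda: {0: 0.2, 1: 0.5, 2: 0.2, 3: 0.1}
    )
    traits_per_cell: int = 10
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genotypes": self.n_genotypes,
            "n_replicates_per_cell": self.n_replicates_per_cell,
            "n_genes": self.n_genes,
            "n_sotus": self.n_sotus,
            "n_core_taxa": self.n_core_taxa,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValidationError(f"{name} must be >= 1, got {v}")
        if self.n_core_taxa > self.n_sotus:
            raise ValidationError("n_core_taxa exceeds n_sotus")
        if self.link_strength < 0:
            raise ValidationError("link_strength must be >= 0")
        if self.n_linked_sotus > self.n_sotus - self.n_core_taxa:
            raise ValidationError(
                "n_linked_sotus exceeds the number of non-core taxa "
                f"({self.n_sotus - self.n_core_taxa})"
            )
        if not 0 < self.core_abundance < 1:
            raise ValidationError("core_abundance must be in (0, 1)")


def link_recovery_config(seed: int, link_strength: float = 2.0) -> "SimulationConfig":
    """Desk-scale scenario for scoring planted-link recovery.

    Links are planted within a single genetic background with a moderate
    treatment effect, so the transcriptome->microbiome signal is carried
    by replicate-level covariation rather than confounded with genotype
    structure: 24 samples (12 control + 12 glyphosate), 60 genes, 10
    sOTUs of which 2 carry one planted driver gene each.
    """
    return SimulationConfig(
        n_genotypes=1,
        antibiotic_arms=False,
        n_replicates_per_cell=12,
        n_genes=60,
        n_sotus=10,
        n_core_taxa=3,
        n_linked_sotus=2,
        genes_per_link=1,
        link_strength=link_strength,
        treatment_effect_sd=0.1,
        depth_mean_expr=50_000,
        depth_mean_sotu=10_000,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact downstream scoring."""

    linked_pairs: set[tuple[str, str]]  # (sotu_id, gene_id)
    core_taxa: set[str]
    treatment_multipliers: dict[str, dict[str, float]]
    antibiotic_removed: set[str]
    genotype_effect_sd: float
    treatment_effect_sd: float

    @property
    def linked_sotus(self) -> set[str]:
        return {s for s, _ in self.linked_pairs}

    @property
    def linked_genes(self) -> set[str]:
        return {g for _, g in self.linked_pairs}


@dataclass
class HolobiontDataset:
    expression: CountMatrix
    sotus: CountMatrix
    samples: SampleTable
    taxonomy: TaxonomyTable
    ortholog_map: OrthologPathwayMap
    traits: TraitTable
    truth: GroundTruth
    config: SimulationConfig

    def __post_init__(self) -> None:
        ids = self.samples.sample_ids
        if self.expression.sample_ids != ids or self.sotus.sample_ids != ids:
            raise ValidationError("sample ids not aligned across component tables")


def _softmax_normalize(latent: np.ndarray) -> np.ndarray:
    total = latent.sum()
    if total <= 0:
        raise ValidationError("degenerate latent composition")
    return latent / total


def _make_taxonomy(sotu_ids: list[str], rng: np.random.Generator) -> TaxonomyTable:
    """Hierarchically consistent synthetic seven-rank lineages.

    Roughly one genus per three sOTUs so that rank collapsing merges
    features; ~10% of sOTUs get an empty genus to exercise the
    unclassified-grouping rule.
    """
    n = len(sotu_ids)
    n_gen = max(2, n // 3)
    n_fam = max(2, n_gen // 2)
    n_ord = max(2, n_fam // 2)
    n_cls = max(2, n_ord // 2)
    n_phy = max(2, n_cls // 2)
    genus_of = rng.integers(0, n_gen, size=n)
    fam_of_gen = rng.integers(0, n_fam, size=n_gen)
    ord_of_fam = rng.integers(0, n_ord, size=n_fam)
    cls_of_ord = rng.integers(0, n_cls, size=n_ord)
    phy_of_cls = rng.integers(0, n_phy, size=n_cls)
    drop_genus = rng.random(n) < 0.1
    rows = []
    for i, sid in enumerate(sotu_ids):
        g = genus_of[i]
        f = fam_of_gen[g]
        o = ord_of_fam[f]
        c = cls_of_ord[o]
        p = phy_of_cls[c]
        lineage = (
            f"d__Bacteria;p__Phylum{p:02d};c__Class{c:02d};o__Order{o:02d};"
            f"f__Family{f:02d};g__{'' if drop_genus[i] else f'Genus{g:02d}'};s__"
        )
        row = parse_lineage(lineage)
        row["sotu_id"] = sid
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sotu_id")
    return TaxonomyTable(df)


def generate_ortholog_map(
    n_genes: int,
    n_pathways: int,
    multiplicity_dist: dict[int, float],
    seed: int,
    gene_ids: list[str] | None = None,
) -> OrthologPathwayMap:
    """Draw a many-to-many gene->pathway map with random multiplicities.

    Each gene's multiplicity (number of distinct pathways reached through
    its ortholog) is drawn from ``multiplicity_dist``, a
    ``{multiplicity: probability}`` table; genes drawing 0 are left out of
    the map entirely (unannotated).
    """
    if n_pathways < 1:
        raise ValidationError("n_pathways must be >= 1")
    probs = np.array(list(multiplicity_dist.values()), dtype=float)
    if probs.sum() <= 0 or (probs < 0).any():
        raise ValidationError("multiplicity_dist must be a probability table")
    probs = probs / probs.sum()
    ks = np.array(list(multiplicity_dist.keys()), dtype=int)
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    pathways = [f"path_{i:03d}" for i in range(n_pathways)]
    rows = []
    for gid in gene_ids:
        k = int(rng.choice(ks, p=probs))
        k = min(k, n_pathways)
        if k == 0:
            continue
        chosen = rng.choice(n_pathways, size=k, replace=False)
        for p in sorted(chosen):
            rows.append(
                {"gene_id": gid, "ortholog_id": f"og_{gid}", "pathway_id": pathways[p]}
            )
    df = pd.DataFrame(rows, columns=["gene_id", "ortholog_id", "pathway_id"])
    return OrthologPathwayMap(df)


def _generate_expression(
    cfg: SimulationConfig, samples: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """NB counts and the z-scored log1p-CPM matrix used for planting links."""
    n_g, n_s = cfg.n_genes, len(samples)
    genotypes = sorted(set(samples["genotype"]))
    base_w = rng.lognormal(mean=0.0, sigma=1.0, size=n_g)
    geno_eff = {
        g: rng.normal(0.0, cfg.genotype_effect_sd, size=n_g) for g in genotypes
    }
    treat_eff = {t: rng.normal(0.0, cfg.treatment_effect_sd, size=n_g)
                 for t in cfg.treatments if t != "control"}
    treat_eff["control"] = np.zeros(n_g)

    counts = np.empty((n_g, n_s), dtype=np.int64)
    for j, (_, row) in enumerate(samples.iterrows()):
        w = base_w * np.exp(geno_eff[row["genotype"]] + treat_eff[row["treatment"]])
        mu = cfg.depth_mean_expr * w / w.sum()
        if cfg.dispersion > 0:
            r = 1.0 / cfg.dispersion
            p = r / (r + mu)
            counts[:, j] = rng.negative_binomial(r, p)
        else:
            counts[:, j] = rng.poisson(mu)
    gene_ids = [f"gene_{i:05d}" for i in range(n_g)]
    df = pd.DataFrame(counts, index=gene_ids, columns=list(samples.index))
    df.index.name = "feature_id"

    cpm = counts / counts.sum(axis=0, keepdims=True) * 1e6
    logc = np.log1p(cpm)
    sd = logc.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (logc - logc.mean(axis=1, keepdims=True)) / sd
    return df, z


def generate_dataset(config: SimulationConfig) -> HolobiontDataset:
    """Generate a complete holobiont dataset with recorded ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genotypes = [f"G{i+1}" for i in range(config.n_genotypes)]
    arms = ("wild_type", "germ_free") if config.antibiotic_arms else ("wild_type",)
    rows = []
    for g in genotypes:
        for t in config.treatments:
            for a in arms:
                for r in range(1, config.n_replicates_per_cell + 1):
                    arm_tag = "wt" if a == "wild_type" else "gf"
                    sid = f"{g}_{t}_{arm_tag}_r{r}"
                    rows.append(
                        {
                            "sample_id": sid,
                            "genotype": g,
                            "treatment": t,
                            "antibiotic": a,
                            "replicate": f"r{r}",
                        }
                    )
    meta = pd.DataFrame(rows).set_index("sample_id")
    samples = SampleTable(meta)

    expr_df, zscores = _generate_expression(config, meta, rng)
    gene_ids = list(expr_df.index)

    # --- community structure -------------------------------------------------
    sotu_ids = [f"sOTU_{i:04d}" for i in range(config.n_sotus)]
    core_idx = np.arange(config.n_core_taxa)
    noncore_idx = np.arange(config.n_core_taxa, config.n_sotus)

    base = np.zeros(config.n_sotus)
    base[core_idx] = config.core_abundance / config.n_core_taxa
    raw = rng.lognormal(0.0, 1.0, size=len(noncore_idx))
    base[noncore_idx] = (1.0 - config.core_abundance) * raw / raw.sum()

    geno_mult = {}
    for g in genotypes:
        m = np.ones(config.n_sotus)
        m[noncore_idx] = np.exp(
            rng.normal(0.0, config.genotype_effect_sd, size=len(noncore_idx))
        )
        geno_mult[g] = m

    treatment_multipliers: dict[str, dict[str, float]] = {}
    treat_mult = {}
    for t in config.treatments:
        m = np.ones(config.n_sotus)
        if t != "control":
            affected = rng.choice(
                noncore_idx, size=max(1, len(noncore_idx) // 2), replace=False
            )
            m[affected] = np.exp(
                rng.normal(0.0, config.treatment_effect_sd, size=len(affected))
            )
            treatment_multipliers[t] = {
                sotu_ids[i]: float(m[i]) for i in sorted(affected)
            }
        treat_mult[t] = m

    n_removed = int(round(config.antibiotic_removal_fraction * len(noncore_idx)))
    removed_idx = (
        rng.choice(noncore_idx, size=n_removed, replace=False)
        if (config.antibiotic_arms and n_removed > 0)
        else np.array([], dtype=int)
    )
    removed_set = {sotu_ids[i] for i in removed_idx}

    # planted links live on non-core taxa that survive the antibiotic arm;
    # favour the more abundant half so the link is not drowned by counting noise
    candidates = np.array(sorted(set(noncore_idx) - set(removed_idx)))
    if len(candidates) < config.n_linked_sotus:
        raise ValidationError(
            "not enough surviving non-core taxa to host the requested links"
        )
    by_mass = candidates[np.argsort(-base[candidates])]
    pool = by_mass[: max(config.n_linked_sotus, len(by_mass) // 2)]
    linked_idx = rng.choice(pool, size=config.n_linked_sotus, replace=False)
    linked_pairs: set[tuple[str, str]] = set()
    link_genes: dict[int, np.ndarray] = {}
    gene_pool = rng.permutation(config.n_genes)
    cursor = 0
    for s in sorted(linked_idx):
        gsel = gene_pool[cursor : cursor + config.genes_per_link]
        cursor += config.genes_per_link
        link_genes[s] = gsel
        for gi in gsel:
            linked_pairs.add((sotu_ids[s], gene_ids[gi]))

    sotu_counts = np.zeros((config.n_sotus, len(meta)), dtype=np.int64)
    for j, (sid, row) in enumerate(meta.iterrows()):
        latent = base * geno_mult[row["genotype"]] * treat_mult[row["treatment"]]
        for s, gsel in link_genes.items():
            latent[s] = latent[s] * np.exp(
                config.link_strength * float(zscores[gsel, j].mean())
            )
        depth = config.depth_mean_sotu
        if row["antibiotic"] == "germ_free":
            latent = latent.copy()
            latent[list(removed_idx)] = 0.0
            depth = int(round(depth * config.antibiotic_depth_factor))
        p = _softmax_normalize(latent)
        alpha = p * config.dm_concentration
        q = rng.dirichlet(alpha[alpha > 0])
        full_q = np.zeros_like(p)
        full_q[alpha > 0] = q
        sotu_counts[:, j] = rng.multinomial(depth, full_q)
    sotu_df = pd.DataFrame(sotu_counts, index=sotu_ids, columns=list(meta.index))
    sotu_df.index.name = "feature_id"

    taxonomy = _make_taxonomy(sotu_ids, rng)
    omap = generate_ortholog_map(
        config.n_genes,
        config.n_pathways,
        config.multiplicity_dist,
        seed=int(rng.integers(0, 2**31 - 1)),
        gene_ids=gene_ids,
    )
    traits = _generate_traits(config, genotypes, rng)

    truth = GroundTruth(
        linked_pairs=linked_pairs,
        core_taxa={sotu_ids[i] for i in core_idx},
        treatment_multipliers=treatment_multipliers,
        antibiotic_removed=removed_set,
        genotype_effect_sd=config.genotype_effect_sd,
        treatment_effect_sd=config.treatment_effect_sd,
    )
    return HolobiontDataset(
        expression=CountMatrix(expr_df, kind="expression"),
        sotus=CountMatrix(sotu_df, kind="sotu"),
        samples=samples,
        taxonomy=taxonomy,
        ortholog_map=omap,
        traits=traits,
        truth=truth,
        config=config,
    )


def _generate_traits(
    cfg: SimulationConfig, genotypes: list[str], rng: np.random.Generator
) -> TraitTable:
    """Life-history traits from a genotype + treatment + interaction model.

    Continuous traits are log-normal around genotype/treatment cell means;
    failed-development counts are binomial per clutch; comet tail
    intensity is Beta-distributed with a treatment shift.
    """
    base = {"size_at_maturity": 2.5, "age_at_maturity": 8.0, "fecundity": 25.0}
    # herbicide exposure: smaller, later, fewer offspring, more damage
    treat_shift = {"control": 0.0, "glyphosate": -0.15, "roundup": -0.20}
    rows = []
    geno_eff = {g: rng.normal(0.0, 0.08) for g in genotypes}
    inter_eff = {
        (g, t): rng.normal(0.0, 0.05) for g in genotypes for t in cfg.treatments
    }
    for g in genotypes:
        for t in cfg.treatments:
            shift = treat_shift.get(t, -0.15)
            for _ in range(cfg.traits_per_cell):
                eta = geno_eff[g] + shift + inter_eff[(g, t)]
                size = base["size_at_maturity"] * np.exp(eta + rng.normal(0, 0.05))
                age = base["age_at_maturity"] * np.exp(-eta + rng.normal(0, 0.05))
                fec = rng.poisson(base["fecundity"] * np.exp(2 * eta))
                clutch = 1 + rng.poisson(14)
                p_fail = 1.0 / (1.0 + np.exp(-(np.log(0.05 / 0.95) - 6 * shift
                                                + rng.normal(0, 0.3))))
                failures = rng.binomial(clutch, p_fail)
                ae = rng.binomial(failures, 0.5)
                do = failures - ae
                ti_mean = min(0.9, 0.10 - shift * 1.2)
                conc = 30.0
                ti = 100.0 * rng.beta(ti_mean * conc, (1 - ti_mean) * conc)
                rows.append(
                    {
                        "genotype": g,
                        "treatment": t,
                        "size_at_maturity": round(float(size), 4),
                        "age_at_maturity": round(float(age), 4),
                        "fecundity": int(fec),
                        "aborted_eggs": int(ae),
                        "dead_offspring": int(do),
                        "live_offspring": int(clutch - failures),
                        "tail_intensity_pct": round(float(ti), 4),
                    }
                )
    return TraitTable(pd.DataFrame(rows))


def truth_recovery_report(result, truth: GroundTruth) -> dict[str, float]:
    """Recall/precision of planted (sOTU, gene) links against a LinkResult.

    ``result`` must expose ``pooled_pairs`` (set of (sotu_id, gene_id)),
    ``pooled_genes``, ``pooled_sotus`` and the analysed universes
    ``all_genes`` / ``all_sotus`` (used to detect identifier mismatches).
    """
    planted = set(truth.linked_pairs)
    bad_genes = truth.linked_genes - set(result.all_genes)
    bad_sotus = truth.linked_sotus - set(result.all_sotus)
    if bad_genes or bad_sotus:
        raise ValidationError(
            f"truth identifiers absent from result universe: genes={sorted(bad_genes)}, "
            f"sotus={sorted(bad_sotus)}"
        )
    selected = set(result.pooled_pairs)

    def _pr(sel: set, pos: set) -> tuple[float, float]:
        recall = len(sel & pos) / len(pos) if pos else float("nan")
        precision = len(sel & pos) / len(sel) if sel else float("nan")
        return recall, precision

    pair_r, pair_p = _pr(selected, planted)
    gene_r, gene_p = _pr(set(result.pooled_genes), truth.linked_genes)
    sotu_r, sotu_p = _pr(set(result.pooled_sotus), truth.linked_sotus)
    return {
        "pair_recall": pair_r,
        "pair_precision": pair_p,
        "gene_recall": gene_r,
        "gene_precision": gene_p,
        "sotu_recall": sotu_r,
        "sotu_precision": sotu_p,
    }


def write_dataset(ds: HolobiontDataset, outdir) -> dict[str, str]:
    """Serialize every component table plus the ground truth and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "sotus": outdir / "sotus.tsv",
        "samples": outdir / "samples.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "ortholog_map": outdir / "ortholog_map.tsv",
        "traits": outdir / "traits.tsv",
    }
    for key, path in paths.items():
        write_table(getattr(ds, key), path)
    truth_df = pd.DataFrame(
        sorted(ds.truth.linked_pairs), columns=["sotu_id", "gene_id"]
    )
    write_table(truth_df, outdir / "truth_pairs.tsv")
    core_df = pd.DataFrame(sorted(ds.truth.core_taxa), columns=["sotu_id"])
    write_table(core_df, outdir / "truth_core_taxa.tsv")
    cfg = asdict(ds.config)
    cfg["treatments"] = list(cfg["treatments"])
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    paths.update(
        truth_pairs=outdir / "truth_pairs.tsv",
        truth_core_taxa=outdir / "truth_core_taxa.tsv",
        config=outdir / "config.yaml",
    )
    return {k: str(v) for k, v in paths.items()}
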