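"""End-to-end orchestration with a declarative config and full provenance.

A single YAML config (or an equivalent dict) declares either a
``simulate`` block (a :class:`~hololink.simulate.SimulationConfig`) or an
``inputs`` block of table paths, plus per-stage parameter blocks whose
defaults are the conventional thresholds of the analysis (sample depth
500, feature reads 10, feature samples 2, replicate correlation 0.4,
prevalence 0.6, core 1%, 80 replicated fits, 100 hyperparameter draws,
20% importance share, 9999 permutations).

``run_pipeline`` executes simulate? -> preprocess -> diversity ->
permanova -> link -> enrich -> fitness, writes every stage output as TSV,
and returns a manifest with the echoed config, per-stage child seeds and
SHA-256 hashes of every output file.  Identical config + seed reproduces
identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, enrichment, fitness, preprocess, rflink, simulate
from .io import (
    ValidationError,
    read_count_matrix,
    read_ortholog_map,
    read_sample_table,
    read_taxonomy,
    read_trait_table,
    write_table,
)

log = logging.getLogger("hololink")

STAGES = ("preprocess", "diversity", "permanova", "link", "enrich", "fitness")

DEFAULTS: dict = {
    "preprocess": {
        "min_sample_depth": 500,
        "min_feature_reads": 10,
        "min_feature_samples": 2,
        "replicate_r_min": 0.4,
        "rarefy": True,
        "rarefy_depth": None,  # None = minimum sample depth
        "collapse_rank": "genus",
        "prevalence_min_fraction": 0.6,
        "core_threshold": 0.01,
        "max_zero_fraction": 0.5,
    },
    "permanova": {"n_perm": 9999, "metric": "bray_curtis"},
    "link": {
        "n_runs": 80,
        "n_hyperparam_draws": 100,
        "cv_folds": 3,
        "selection_threshold": 0.20,
    },
    "enrich": {"alpha": 0.05},
    "fitness": {
        "traits": [
            "size_at_maturity",
            "age_at_maturity",
            "fecundity",
            "failed_development",
            "tail_intensity_pct",
        ]
    },
}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("pipeline config must be a YAML mapping")
    return cfg


def _merged(cfg: dict, stage: str) -> dict:
    merged = dict(DEFAULTS.get(stage, {}))
    merged.update(cfg.get(stage) or {})
    return merged


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_config(cfg: dict) -> None:
    """Fail fast, before any stage runs, naming every missing input path."""
    if "simulate" not in cfg:
        inputs = cfg.get("inputs") or {}
        required = ("expression", "sotus", "samples", "taxonomy")
        missing_keys = [k for k in required if k not in inputs]
        if missing_keys:
            raise ValidationError(
                f"config without a simulate block must declare inputs: {missing_keys}"
            )
        absent = [str(p) for p in inputs.values() if not Path(p).exists()]
        if absent:
            raise ValidationError(f"input file(s) not found: {absent}")
    unknown = [s for s in cfg.get("stages", []) if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stage(s): {unknown}; allowed: {STAGES}")


def _load_or_simulate(cfg: dict, outdir: Path, seed: int):
    if "simulate" in cfg:
        sim_kw = dict(cfg["simulate"] or {})
        sim_kw.setdefault("seed", seed)
        if "treatments" in sim_kw:
            sim_kw["treatments"] = tuple(sim_kw["treatments"])
        sconf = simulate.SimulationConfig(**sim_kw)
        ds = simulate.generate_dataset(sconf)
        simulate.write_dataset(ds, outdir / "simulated")
        return ds
    inputs = cfg["inputs"]
    expr = read_count_matrix(inputs["expression"], "expression")
    sotus = read_count_matrix(inputs["sotus"], "sotu")
    samples = read_sample_table(inputs["samples"])
    taxonomy = read_taxonomy(inputs["taxonomy"])
    omap = (
        read_ortholog_map(inputs["ortholog_map"]) if "ortholog_map" in inputs else None
    )
    traits = read_trait_table(inputs["traits"]) if "traits" in inputs else None

    class _Loaded:
        pass

    ds = _Loaded()
    ds.expression, ds.sotus, ds.samples = expr, sotus, samples
    ds.taxonomy, ds.ortholog_map, ds.traits, ds.truth = taxonomy, omap, traits, None
    return ds


def _available_terms(samples) -> tuple[str, ...]:
    factors = [
        f
        for f in ("genotype", "treatment", "antibiotic")
        if samples.data[f].nunique() > 1
    ]
    terms = list(factors)
    if len(factors) >= 2:
        from itertools import combinations

        for k in (2, 3):
            for combo in combinations(factors, k):
                terms.append(":".join(combo))
    return tuple(terms)


def run_pipeline(cfg: dict, output_dir, seed: int | None = None) -> dict:
    """Run every requested stage; returns the manifest (also written as JSON)."""
    t0 = time.time()
    validate_config(cfg)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    stages = tuple(cfg.get("stages") or STAGES)

    master = np.random.SeedSequence(seed)
    child = {name: s for name, s in zip(("simulate",) + STAGES, master.spawn(1 + len(STAGES)))}
    stage_seed = {k: int(v.generate_state(1)[0] % (2**31 - 1)) for k, v in child.items()}

    manifest: dict = {
        "config": cfg,
        "seed": seed,
        "stage_seeds": stage_seed,
        "outputs": {},
        "stages_run": [],
    }
    outputs: dict[str, str] = manifest["outputs"]

    def _emit(obj, name: str) -> None:
        path = outdir / name
        write_table(obj, path)
        outputs[name] = _sha256(path)

    log.info("loading inputs (simulate=%s)", "simulate" in cfg)
    ds = _load_or_simulate(cfg, outdir, stage_seed["simulate"])
    if getattr(ds, "truth", None) is not None:
        for name in ("expression.tsv", "sotus.tsv", "samples.tsv", "taxonomy.tsv",
                     "ortholog_map.tsv", "traits.tsv", "truth_pairs.tsv",
                     "truth_core_taxa.tsv"):
            p = outdir / "simulated" / name
            if p.exists():
                outputs[f"simulated/{name}"] = _sha256(p)

    filtered_sotus = ds.sotus
    filtered_expr = ds.expression
    core: dict | None = None

    if "preprocess" in stages:
        p = _merged(cfg, "preprocess")
        log.info("[preprocess] sOTU and gene filters")
        try:
            filtered_sotus, rep1 = preprocess.filter_sotu_matrix(
                ds.sotus,
                min_sample_depth=p["min_sample_depth"],
                min_feature_reads=p["min_feature_reads"],
                min_feature_samples=p["min_feature_samples"],
            )
            filtered_sotus, rep2 = preprocess.filter_replicate_correlation(
                filtered_sotus, ds.samples, r_min=p["replicate_r_min"]
            )
            if p["rarefy"]:
                filtered_sotus = preprocess.rarefy(
                    filtered_sotus, depth=p["rarefy_depth"], seed=stage_seed["preprocess"]
                )
            kept = ds.samples.subset(filtered_sotus.sample_ids)
            core = preprocess.core_taxa(filtered_sotus, kept, threshold=p["core_threshold"])
            collapsed = preprocess.collapse_to_rank(
                filtered_sotus, ds.taxonomy, rank=p["collapse_rank"]
            )
            collapsed, rep3 = preprocess.prevalence_filter(
                collapsed, min_fraction=p["prevalence_min_fraction"]
            )
            filtered_expr, rep4 = preprocess.filter_genes(
                ds.expression, max_zero_fraction=p["max_zero_fraction"]
            )
            frames = [
                f for f in (r.to_frame() for r in (rep1, rep2, rep3, rep4))
                if not f.empty
            ]
            report = (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(columns=["rule", "item_id", "threshold", "axis"])
            )
            _emit(report, "filter_report.tsv")
            _emit(filtered_sotus, "sotus_filtered.tsv")
            _emit(collapsed, "sotus_collapsed.tsv")
            _emit(filtered_expr, "expression_filtered.tsv")
            core_rows = [
                {"scope": scope, "taxon": taxon}
                for scope in sorted(core)
                for taxon in sorted(core[scope])
            ]
            _emit(pd.DataFrame(core_rows, columns=["scope", "taxon"]), "core_taxa.tsv")
            filtered_sotus_for_link = collapsed
        except ValidationError as exc:
            raise StageError("preprocess", str(exc)) from exc
        manifest["stages_run"].append("preprocess")
    else:
        filtered_sotus_for_link = filtered_sotus

    kept_samples = ds.samples.subset(
        [s for s in ds.samples.sample_ids if s in filtered_sotus.sample_ids]
    )

    if "diversity" in stages:
        log.info("[diversity] alpha and beta indices")
        try:
            alpha = community.alpha_diversity(filtered_sotus)
            _emit(alpha.reset_index(), "alpha_diversity.tsv")
            for metric in ("bray_curtis", "jaccard"):
                dm = community.beta_diversity(filtered_sotus, metric=metric)
                df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
                df.index.name = "sample_id"
                _emit(df.reset_index(), f"beta_{metric}.tsv")
        except ValidationError as exc:
            raise StageError("diversity", str(exc)) from exc
        manifest["stages_run"].append("diversity")

    if "permanova" in stages:
        p = _merged(cfg, "permanova")
        log.info("[permanova] %s, %d permutations", p["metric"], p["n_perm"])
        try:
            dm = community.beta_diversity(filtered_sotus, metric=p["metric"])
            terms = list(p.get("terms") or _available_terms(kept_samples))
            table = None
            while terms:
                try:
                    table = community.permanova(
                        dm, kept_samples, terms=tuple(terms),
                        n_perm=p["n_perm"], seed=stage_seed["permanova"],
                    )
                    break
                except ValidationError as exc:
                    msg = str(exc)
                    confounded = [t for t in terms if f"'{t}'" in msg and "confounded" in msg]
                    if not confounded:
                        raise
                    log.warning("[permanova] dropping confounded term %s", confounded[0])
                    terms.remove(confounded[0])
            if table is None:
                raise ValidationError("no testable permanova terms")
            _emit(table, "permanova.tsv")
        except ValidationError as exc:
            raise StageError("permanova", str(exc)) from exc
        manifest["stages_run"].append("permanova")

    link_result = None
    if "link" in stages:
        p = _merged(cfg, "link")
        log.info("[link] random-forest linkage (%d runs, %d draws)",
                 p["n_runs"], p["n_hyperparam_draws"])
        try:
            lconf_kw = {k: v for k, v in p.items() if k in (
                "n_runs", "n_hyperparam_draws", "cv_folds", "selection_threshold",
                "quality_rule", "include_control",
            )}
            if "search_space" in p and p["search_space"]:
                lconf_kw["search_space"] = {
                    k: tuple(v) for k, v in p["search_space"].items()
                }
            if "treatments" in p and p["treatments"]:
                lconf_kw["treatments"] = tuple(p["treatments"])
            lconf = rflink.LinkConfig(seed=stage_seed["link"], **lconf_kw)
            link_result = rflink.link_analysis(
                filtered_expr, filtered_sotus_for_link, kept_samples, lconf
            )
            _emit(link_result.model_table(), "link_models.tsv")
            _emit(link_result.pair_table(), "link_pairs.tsv")
            if getattr(ds, "truth", None) is not None:
                truth = ds.truth
                if "preprocess" in stages:
                    # linkage ran on rank-collapsed taxa: score the planted
                    # pairs at the same rank
                    labels = preprocess.rank_labels(
                        ds.sotus.feature_ids, ds.taxonomy,
                        _merged(cfg, "preprocess")["collapse_rank"],
                    )
                    truth = simulate.GroundTruth(
                        linked_pairs={(labels[s], g) for s, g in truth.linked_pairs},
                        core_taxa={labels[s] for s in truth.core_taxa},
                        treatment_multipliers=truth.treatment_multipliers,
                        antibiotic_removed=truth.antibiotic_removed,
                        genotype_effect_sd=truth.genotype_effect_sd,
                        treatment_effect_sd=truth.treatment_effect_sd,
                    )
                try:
                    report = simulate.truth_recovery_report(link_result, truth)
                except ValidationError as exc:
                    log.warning("[link] truth recovery skipped: %s", exc)
                else:
                    _emit(
                        pd.DataFrame([report]).melt(
                            var_name="metric", value_name="value"
                        ),
                        "truth_recovery.tsv",
                    )
        except ValidationError as exc:
            raise StageError("link", str(exc)) from exc
        manifest["stages_run"].append("link")

    if "enrich" in stages:
        p = _merged(cfg, "enrich")
        log.info("[enrich] weighted pathway enrichment")
        try:
            if getattr(ds, "ortholog_map", None) is None:
                raise ValidationError("enrich stage requires an ortholog_map input")
            background = set(filtered_expr.feature_ids)
            selected = (
                set(link_result.pooled_genes) & background if link_result else set()
            )
            table = enrichment.enrich_pathways(
                selected, background, ds.ortholog_map, alpha=p["alpha"]
            )
            _emit(table, "enrichment.tsv")
        except ValidationError as exc:
            raise StageError("enrich", str(exc)) from exc
        manifest["stages_run"].append("enrich")

    if "fitness" in stages:
        p = _merged(cfg, "fitness")
        log.info("[fitness] trait ANOVAs")
        try:
            if getattr(ds, "traits", None) is None:
                raise ValidationError("fitness stage requires a traits input")
            tables = []
            for trait in p["traits"]:
                t = fitness.trait_anova_table(ds.traits, trait)
                t.insert(0, "trait", trait)
                tables.append(t)
                norms = fitness.reaction_norms(ds.traits, trait)
                _emit(norms, f"reaction_norm_{trait}.tsv")
            _emit(pd.concat(tables, ignore_index=True), "fitness_anova.tsv")
        except ValidationError as exc:
            raise StageError("fitness", str(exc)) from exc
        manifest["stages_run"].append("fitness")

    manifest["wall_clock_s"] = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    log.info("pipeline complete in %.1fs; %d outputs", manifest["wall_clock_s"],
             len(outputs))
    return manifest
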