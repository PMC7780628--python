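"""Filtering, rarefaction and collapsing rules for community count tables.

The rules implemented here are the standard hygiene steps applied to
denoised 16S community tables before diversity or machine-learning
analysis: drop under-sequenced samples, drop rare features, drop
irreproducible replicates, rarefy to a common depth, collapse exact
sequence variants (sOTUs) to a taxonomic rank, and apply a prevalence
filter.  Each rule returns a :class:`FilterReport` entry so every removal
is auditable.

Fixed application order for the full pipeline: sample depth -> feature
total reads -> feature prevalence-in-samples -> replicate correlation ->
rank collapse -> prevalence fraction.  Sample-level rules run first so
that feature-level rules see the final sample set.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    SampleTable,
    TaxonomyTable,
    LINEAGE_RANKS,
    ValidationError,
)


@dataclass
class FilterRecord:
    rule: str
    threshold: float
    axis: str  # "samples" or "features"
    removed: list[str]
    n_before: int
    n_after: int

    def __post_init__(self) -> None:
        if self.n_before - len(self.removed) != self.n_after:
            raise ValueError(
                f"filter bookkeeping violated for {self.rule}: "
                f"{self.n_before} - {len(self.removed)} != {self.n_after}"
            )


@dataclass
class FilterReport:
    records: list[FilterRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, rule, threshold, axis, removed, n_before) -> FilterRecord:
        rec = FilterRecord(
            rule=rule,
            threshold=threshold,
            axis=axis,
            removed=sorted(removed),
            n_before=n_before,
            n_after=n_before - len(removed),
        )
        self.records.append(rec)
        return rec

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def removed_by(self, rule: str) -> list[str]:
        return [i for r in self.records if r.rule == rule for i in r.removed]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": r.rule, "item_id": item, "threshold": r.threshold, "axis": r.axis}
            for r in self.records
            for item in r.removed
        ]
        return pd.DataFrame(rows, columns=["rule", "item_id", "threshold", "axis"])


def filter_sotu_matrix(
    m: CountMatrix,
    min_sample_depth: int = 500,
    min_feature_reads: int = 10,
    min_feature_samples: int = 2,
) -> tuple[CountMatrix, FilterReport]:
    """Coverage and rarity filters for an sOTU table.

    Applied in order: (1) samples with total depth below
    ``min_sample_depth`` reads are removed; (2) sOTUs with fewer than
    ``min_feature_reads`` total reads are removed; (3) sOTUs observed
    (count > 0) in fewer than ``min_feature_samples`` of the remaining
    samples are removed.  All comparisons are strict ``<``, so a sample at
    exactly 500 reads or an sOTU seen in exactly 2 samples is retained.
    """
    report = FilterReport()
    df = m.data

    depth = df.sum(axis=0)
    low = list(depth.index[depth < min_sample_depth])
    report.add("sample_depth", min_sample_depth, "samples", low, df.shape[1])
    df = df.drop(columns=low)
    if df.shape[1] == 0:
        raise ValidationError(
            f"all samples removed by sample_depth < {min_sample_depth}"
        )

    totals = df.sum(axis=1)
    rare_reads = list(totals.index[totals < min_feature_reads])
    report.add("feature_reads", min_feature_reads, "features", rare_reads, df.shape[0])
    df = df.drop(index=rare_reads)

    prevalence = (df > 0).sum(axis=1)
    rare_prev = list(prevalence.index[prevalence < min_feature_samples])
    report.add(
        "feature_samples", min_feature_samples, "features", rare_prev, df.shape[0]
    )
    df = df.drop(index=rare_prev)
    if df.shape[0] == 0:
        raise ValidationError("all sOTUs removed by rarity filters")
    return CountMatrix(df, kind=m.kind), report


def filter_replicate_correlation(
    m: CountMatrix, samples: SampleTable, r_min: float = 0.4
) -> tuple[CountMatrix, FilterReport]:
    """Drop replicates poorly correlated with their sibling replicates.

    Within each genotype x treatment x antibiotic cell, every sample's
    relative-abundance profile is compared (Pearson r on proportions over
    the shared feature set) to each other replicate of the cell; samples
    whose mean pairwise r falls below ``r_min`` are removed.  Singleton
    cells have no siblings and pass through with a warning.
    """
    report = FilterReport()
    aligned = samples.subset([s for s in samples.sample_ids if s in m.data.columns])
    rel = m.subset_samples(aligned.sample_ids).relative_abundance()

    removed: list[str] = []
    cells = aligned.data.groupby(
        ["genotype", "treatment", "antibiotic"], observed=True, sort=True
    )
    for key, cell in cells:
        ids = list(cell.index)
        if len(ids) < 2:
            report.warn(f"singleton cell {key}: replicate filter not applied")
            continue
        sub = rel[ids].to_numpy()
        r = np.corrcoef(sub.T)
        for i, sid in enumerate(ids):
            others = [r[i, j] for j in range(len(ids)) if j != i]
            if float(np.mean(others)) < r_min:
                removed.append(sid)
    report.add("replicate_correlation", r_min, "samples", removed, m.data.shape[1])
    out = m.data.drop(columns=removed)
    if out.shape[1] == 0:
        raise ValidationError("all samples removed by replicate correlation filter")
    return CountMatrix(out, kind=m.kind), report


def rarefy(m: CountMatrix, depth: int | None = None, seed: int = 0) -> CountMatrix:
    """Subsample every sample without replacement to a common depth.

    Uses exact multivariate hypergeometric draws, so each rarefied column
    sums to exactly ``depth``.  ``depth=None`` uses the smallest sample
    depth in the matrix.  Samples below ``depth`` are dropped (cannot
    happen with the default).  Deterministic for a given seed.
    """
    sums = m.data.sum(axis=0)
    if depth is None:
        depth = int(sums.min())
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    keep = [s for s in m.sample_ids if sums[s] >= depth]
    if not keep:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    out = {}
    for sid in keep:
        col = m.data[sid].to_numpy()
        if col.sum() == depth:
            out[sid] = col
        else:
            out[sid] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=m.data.index, dtype=np.int64)
    df.index.name = m.data.index.name
    return CountMatrix(df, kind=m.kind)


def rank_labels(feature_ids, tax: TaxonomyTable, rank: str = "genus") -> dict[str, str]:
    """Collapse label of each sOTU at ``rank`` (with unclassified fallback)."""
    if rank not in LINEAGE_RANKS:
        raise ValidationError(f"unknown rank {rank!r}; allowed: {LINEAGE_RANKS}")
    missing = sorted(set(feature_ids) - set(tax.data.index))
    if missing:
        raise ValidationError(f"sOTUs without taxonomy entry: {missing}")
    upto = LINEAGE_RANKS[: LINEAGE_RANKS.index(rank) + 1]
    labels = {}
    for sid in feature_ids:
        name = tax.data.at[sid, rank]
        if name:
            labels[sid] = name
        else:
            ancestors = [tax.data.at[sid, r] for r in upto[:-1]]
            named = [a for a in ancestors if a]
            labels[sid] = "unclassified:" + (named[-1] if named else "unassigned")
    return labels


def collapse_to_rank(
    m: CountMatrix, tax: TaxonomyTable, rank: str = "genus"
) -> CountMatrix:
    """Sum sOTU counts over shared labels at a taxonomic rank.

    sOTUs whose label at ``rank`` is empty are grouped under their most
    specific named ancestor as ``unclassified:<ancestor>`` (or
    ``unclassified:unassigned`` when the whole lineage is empty), so
    per-sample totals are conserved exactly.
    """
    labels = rank_labels(m.feature_ids, tax, rank)
    grouped = m.data.groupby(pd.Series(labels), sort=True).sum()
    grouped.index.name = "feature_id"
    return CountMatrix(grouped.astype(np.int64), kind=m.kind)


def prevalence_filter(
    m: CountMatrix, min_fraction: float = 0.6
) -> tuple[CountMatrix, FilterReport]:
    """Keep features present (count > 0) in at least ``min_fraction`` of samples.

    The bound is inclusive: with 5 samples and the default 0.6, presence
    in exactly 3 samples retains the feature.
    """
    report = FilterReport()
    frac = (m.data > 0).sum(axis=1) / m.data.shape[1]
    removed = list(frac.index[frac < min_fraction])
    report.add("prevalence", min_fraction, "features", removed, m.data.shape[0])
    df = m.data.drop(index=removed)
    if df.shape[0] == 0:
        raise ValidationError("all features removed by prevalence filter")
    return CountMatrix(df, kind=m.kind), report


def filter_genes(
    expr: CountMatrix, max_zero_fraction: float = 0.5
) -> tuple[CountMatrix, FilterReport]:
    """Remove invariant genes and genes with too many zero counts.

    A gene with zero variance across samples carries no signal for the
    downstream regressions; a gene whose zero-count fraction exceeds
    ``max_zero_fraction`` is considered too sparse.
    """
    report = FilterReport()
    df = expr.data
    variances = df.var(axis=1, ddof=0)
    invariant = list(variances.index[variances == 0])
    report.add("invariant_genes", 0.0, "features", invariant, df.shape[0])
    df = df.drop(index=invariant)

    zero_frac = (df == 0).sum(axis=1) / df.shape[1]
    sparse = list(zero_frac.index[zero_frac > max_zero_fraction])
    report.add("sparse_genes", max_zero_fraction, "features", sparse, df.shape[0])
    df = df.drop(index=sparse)
    if df.shape[0] == 0:
        raise ValidationError("all genes removed by gene filters")
    return CountMatrix(df, kind=expr.kind), report


def core_taxa(
    m: CountMatrix, samples: SampleTable, threshold: float = 0.01
) -> dict[str, set[str]]:
    """Identify core taxa: mean relative abundance strictly above 1% within a treatment.

    Returns one set per treatment plus an ``"overall"`` set of taxa core in
    every treatment.
    """
    aligned = samples.align_counts(m)
    rel = aligned.relative_abundance()
    out: dict[str, set[str]] = {}
    treatments = sorted(set(samples.data["treatment"]))
    for t in treatments:
        ids = list(samples.data.index[samples.data["treatment"] == t])
        if not ids:
            raise ValidationError(f"empty treatment group {t!r}")
        means = rel[ids].mean(axis=1)
        out[t] = set(means.index[means > threshold])
    out["overall"] = set.intersection(*(out[t] for t in treatments)) if treatments else set()
    return out
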