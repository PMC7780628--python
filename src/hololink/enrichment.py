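"""Pathway enrichment weighted by ortholog-mapping multiplicity.

When host genes are annotated through orthologs of a related species, a
single gene can hit several pathways (non-unique mappings).  Giving every
mapping full weight would let promiscuous genes inflate enrichment, so
each annotated gene distributes a total mass of 1 over its pathways: a
gene with multiplicity ``m`` contributes ``1/m`` to each pathway it maps
to and the remainder to the off-pathway cell of each 2x2 table.  With all
multiplicities equal to 1 the procedure reduces exactly to classical
Fisher / chi-square enrichment.

Fisher's exact test needs integer counts, so weighted cells are rounded
(nearest, ties to even) with the fourth cell re-balanced to preserve the
rounded grand total; the chi-square statistic is computed directly on the
fractional cells.  Benjamini-Hochberg FDR is applied per test family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OrthologPathwayMap, ValidationError


@dataclass
class WeightedContingency:
    """Fractional 2x2 table for one pathway.

    w11: selected genes' weight on the pathway; w12: selected genes'
    off-pathway weight; w21/w22: the same for non-selected background.
    Each annotated gene contributes total weight 1 to its row.
    """

    pathway_id: str
    w11: float
    w12: float
    w21: float
    w22: float

    def __post_init__(self) -> None:
        for name in ("w11", "w12", "w21", "w22"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} negative in weighted table")

    @property
    def grand_total(self) -> float:
        return self.w11 + self.w12 + self.w21 + self.w22

    def as_array(self) -> np.ndarray:
        return np.array([[self.w11, self.w12], [self.w21, self.w22]], dtype=float)


def build_weighted_table(
    selected: set[str],
    background: set[str],
    pmap: OrthologPathwayMap,
    pathway: str,
) -> WeightedContingency:
    """Multiplicity-weighted 2x2 table for one pathway.

    Only annotated genes (present in the map) enter the table; a gene
    with multiplicity m contributes 1/m to the pathway cell if it maps to
    the pathway and the remaining mass to the off-pathway cell.
    """
    if not selected <= background:
        raise ValidationError("selected gene set must be a subset of background")
    gene_paths = pmap.gene_pathways()
    if pathway not in pmap.pathways:
        warnings.warn(f"pathway {pathway!r} absent from map: zero column", stacklevel=2)
    w = np.zeros(4)  # w11, w12, w21, w22
    for gene in background:
        paths = gene_paths.get(gene)
        if not paths:
            continue  # unannotated: excluded from the table
        m = len(paths)
        hit = 1.0 / m if pathway in paths else 0.0
        miss = 1.0 - hit
        if gene in selected:
            w[0] += hit
            w[1] += miss
        else:
            w[2] += hit
            w[3] += miss
    return WeightedContingency(pathway, *w)


def _rounded_integer_table(t: WeightedContingency) -> np.ndarray:
    """Round weighted cells to integers, preserving the rounded grand total.

    w11, w12, w21 are rounded nearest-ties-to-even; w22 absorbs the
    difference so the integer grand total equals the rounded fractional
    grand total (clipped at zero).
    """
    total = int(np.rint(t.grand_total))
    a = int(np.rint(t.w11))
    b = int(np.rint(t.w12))
    c = int(np.rint(t.w21))
    d = max(0, total - a - b - c)
    return np.array([[a, b], [c, d]], dtype=int)


def weighted_fisher(t: WeightedContingency) -> float:
    """One-sided (enrichment) Fisher exact p on the integerized table.

    With all-unit weights this is exactly the classical Fisher test.
    """
    if t.grand_total <= 0:
        warnings.warn("zero grand total: Fisher p set to 1", stacklevel=2)
        return 1.0
    table = _rounded_integer_table(t)
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)


def chisq_statistic(t: WeightedContingency) -> float:
    """Pearson X^2 on the fractional weighted cells (no rounding)."""
    obs = t.as_array()
    n = obs.sum()
    if n <= 0:
        raise ValidationError("chi-square needs a positive grand total")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValidationError("zero margin: chi-square statistic undefined")
    expected = np.outer(rows, cols) / n
    return float(((obs - expected) ** 2 / expected).sum())


def weighted_chisq(t: WeightedContingency) -> float:
    """Pearson chi-square (1 df, no continuity correction) on fractional cells.

    The statistic scales linearly when every cell is multiplied by a
    constant; a zero margin makes expected counts degenerate and returns
    p = 1 with a warning.
    """
    try:
        x2 = chisq_statistic(t)
    except ValidationError as exc:
        if "zero margin" not in str(exc):
            raise
        warnings.warn("zero margin in weighted table: chi-square p set to 1",
                      stacklevel=2)
        return 1.0
    return float(stats.chi2.sf(x2, df=1))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich_pathways(
    selected: set[str],
    background: set[str],
    pmap: OrthologPathwayMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Weighted Fisher + chi-square enrichment over every annotated pathway.

    Pathways are tested when they carry nonzero annotated weight in the
    background; BH FDR is applied separately to the Fisher and chi-square
    p-value families, and the ``significant`` flag reflects the Fisher
    q-value at ``alpha``.
    """
    if not selected <= background:
        raise ValidationError("selected gene set must be a subset of background")
    annotated = background & pmap.genes
    columns = [
        "pathway_id", "w11", "w12", "w21", "w22", "odds_ratio",
        "p_fisher", "p_chisq", "q_fisher", "q_chisq", "significant",
    ]
    if not annotated:
        warnings.warn("no annotated genes in background: empty enrichment table",
                      stacklevel=2)
        return pd.DataFrame(columns=columns)
    gene_paths = pmap.gene_pathways()
    pathways = sorted({p for g in annotated for p in gene_paths[g]})
    rows = []
    for pw in pathways:
        t = build_weighted_table(selected, background, pmap, pw)
        if t.w11 + t.w21 == 0:
            continue  # no annotated weight on this pathway
        num = t.w11 * t.w22
        den = t.w12 * t.w21
        odds = num / den if den > 0 else (np.inf if num > 0 else 0.0)
        rows.append(
            {
                "pathway_id": pw,
                "w11": t.w11,
                "w12": t.w12,
                "w21": t.w21,
                "w22": t.w22,
                "odds_ratio": odds,
                "p_fisher": weighted_fisher(t),
                "p_chisq": weighted_chisq(t),
            }
        )
    if not rows:
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows)
    table["q_fisher"] = bh_fdr(table["p_fisher"])
    table["q_chisq"] = bh_fdr(table["p_chisq"])
    table["significant"] = table["q_fisher"] < alpha
    return table[columns]
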