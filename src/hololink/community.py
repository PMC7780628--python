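"""Community diversity and permutational multivariate ANOVA.

Alpha diversity (Shannon entropy in nats, Pielou evenness, observed
feature count), Bray-Curtis and Jaccard dissimilarity matrices, and a
multi-factor PERMANOVA with sequential (Type I) sums of squares in the
style of vegan's ``adonis``.

The PERMANOVA partitions the Gower-centered inner-product matrix
``G = C (-1/2 D*D) C`` (``C`` the centering operator) over an ordered list
of model terms by projecting onto cumulative design spaces.  For
Euclidean distances this reproduces classical linear-model ANOVA exactly.
Significance is assessed by permuting sample labels, i.e. permuting the
rows and columns of ``D`` jointly, with ``p = (1 + #{F* >= F}) / (1 + n_perm)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .io import CountMatrix, SampleTable, ValidationError


def alpha_diversity(m: CountMatrix) -> pd.DataFrame:
    """Per-sample Shannon H (nats), Pielou evenness and observed features.

    ``H = -sum p_i ln p_i`` over nonzero proportions; evenness ``H/ln(S)``
    is defined only when the sample holds more than one feature (NaN for
    single-feature samples).
    """
    counts = m.data.to_numpy(dtype=float)
    sums = counts.sum(axis=0)
    if (sums == 0).any():
        empty = [s for s, tot in zip(m.sample_ids, sums) if tot == 0]
        raise ValidationError(f"empty samples: {empty}")
    rows = []
    for j, sid in enumerate(m.sample_ids):
        p = counts[:, j] / sums[j]
        p = p[p > 0]
        h = float(-(p * np.log(p)).sum())
        s = int(len(p))
        evenness = h / np.log(s) if s > 1 else np.nan
        rows.append(
            {"sample_id": sid, "shannon": h, "evenness": evenness, "observed_features": s}
        )
    return pd.DataFrame(rows).set_index("sample_id")


def beta_diversity(m: CountMatrix, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise Bray-Curtis or Jaccard dissimilarities between samples.

    Bray-Curtis is computed on counts, Jaccard on presence/absence.  A
    pair of all-zero samples has no defined dissimilarity; it is reported
    as 0 with a warning.
    """
    x = m.data.to_numpy(dtype=float).T  # samples x features
    if x.shape[0] < 2:
        raise ValidationError("beta diversity needs at least 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if metric == "bray_curtis":
            d = pdist(x, metric="braycurtis")
        elif metric == "jaccard":
            d = pdist(x > 0, metric="jaccard")
        else:
            raise ValidationError(f"unknown metric {metric!r}")
    if np.isnan(d).any():
        warnings.warn(
            "all-zero sample pair(s): dissimilarity undefined, reported as 0",
            stacklevel=2,
        )
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(squareform(d), ids=m.sample_ids)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

DEFAULT_TERMS = (
    "genotype",
    "treatment",
    "antibiotic",
    "genotype:treatment",
    "genotype:antibiotic",
    "treatment:antibiotic",
    "genotype:treatment:antibiotic",
)


def _dummy(series: pd.Series) -> np.ndarray:
    """Treatment (drop-first) dummy coding of a categorical factor."""
    levels = sorted(set(series))
    return np.column_stack([(series == lv).to_numpy(float) for lv in levels[1:]]) if len(
        levels
    ) > 1 else np.empty((len(series), 0))


def _term_columns(samples: pd.DataFrame, term: str) -> np.ndarray:
    factors = term.split(":")
    for f in factors:
        if f not in samples.columns:
            raise ValidationError(f"unknown factor {f!r} in term {term!r}")
    blocks = [_dummy(samples[f]) for f in factors]
    cols = blocks[0]
    for b in blocks[1:]:
        if cols.shape[1] == 0 or b.shape[1] == 0:
            return np.empty((len(samples), 0))
        cols = np.einsum("ni,nj->nij", cols, b).reshape(len(samples), -1)
    return cols


def _orth_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing, SVD-based)."""
    if x.size == 0:
        return np.empty((x.shape[0], 0))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    return u[:, s > tol]


def gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d * d
    c = np.eye(n) - np.ones((n, n)) / n
    return c @ a @ c


def permanova(
    d: DistanceMatrix,
    samples: SampleTable,
    terms: tuple[str, ...] = DEFAULT_TERMS,
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequential multi-factor PERMANOVA on a dissimilarity matrix.

    Terms are fitted in the order given (``"a:b"`` denotes an
    interaction); each term's sum of squares is the increment in explained
    trace when its design columns are added to the cumulative model, so a
    partially aliased interaction (structurally missing cells) simply
    carries a reduced df, as in adonis.  A term adding no rank at all is
    fully confounded and raises an error naming it.  Returns the
    conventional table with Residual and Total rows; R² values plus the
    residual sum to 1.
    """
    ids = samples.sample_ids
    if set(ids) != set(d.ids):
        raise ValidationError("distance matrix and sample table ids differ")
    dm = d.filter(ids).data
    n = len(ids)
    g = gower_center(dm)
    ss_total = float(np.trace(g))

    # Cumulative orthonormal bases: intercept, then one per term.
    meta = samples.data
    ones = np.ones((n, 1)) / np.sqrt(n)
    bases = [ones]
    dfs: list[int] = []
    cum = ones
    for term in terms:
        cols = _term_columns(meta, term)
        combined = _orth_basis(np.hstack([cum, cols]))
        df_t = combined.shape[1] - cum.shape[1]
        if df_t == 0:
            raise ValidationError(
                f"term {term!r} is fully confounded with preceding terms"
            )
        dfs.append(df_t)
        cum = combined
        bases.append(cum)
    rank_full = cum.shape[1]
    df_res = n - rank_full
    if df_res <= 0:
        raise ValidationError("model saturates the samples: no residual df")

    # hat-matrix diagonal products: tr(H G) with H = Q Q^T
    def explained(qs, gmat):
        # tr(Q Q^T G) = sum((Q^T G Q) diagonal) computed cheaply
        return np.array([float(np.sum((q.T @ gmat) * q.T)) for q in qs])

    tr = explained(bases, g)  # cumulative explained trace, intercept first
    ss_terms = np.diff(tr)
    ss_res = ss_total - (tr[-1] - tr[0])

    fstats = np.full(len(terms), np.nan)
    for i, df_t in enumerate(dfs):
        if df_t > 0:
            fstats[i] = (ss_terms[i] / df_t) / (ss_res / df_res)

    pvals = np.full(len(terms), np.nan)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(terms))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            gp = g[np.ix_(perm, perm)]
            trp = explained(bases, gp)
            ssp = np.diff(trp)
            ssrp = ss_total - (trp[-1] - trp[0])
            for i, df_t in enumerate(dfs):
                if df_t > 0:
                    fp = (ssp[i] / df_t) / (ssrp / df_res)
                    if fp >= fstats[i]:
                        exceed[i] += 1
        for i, df_t in enumerate(dfs):
            if df_t > 0:
                pvals[i] = (1.0 + exceed[i]) / (1.0 + n_perm)

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": dfs[i],
                "SS": float(ss_terms[i]),
                "R2": float(ss_terms[i] / ss_total),
                "F": fstats[i],
                "p": pvals[i],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "SS": float(ss_res),
            "R2": float(ss_res / ss_total),
            "F": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "SS": ss_total,
            "R2": 1.0,
            "F": np.nan,
            "p": np.nan,
        }
    )
    return pd.DataFrame(rows, columns=["term", "df", "SS", "R2", "F", "p"])
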