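"""Life-history and genotoxicity statistics.

Embryonic failure is summarized per brood as
``(AE + DO) / (AE + DO + LO)`` — aborted eggs plus dead offspring over
all embryos.  Comet-assay DNA damage is the tail intensity percentage,
``100 * tail / (tail + head)``.  Trait responses are tested with a
two-way ANOVA (genotype, treatment, interaction) using sequential
(Type I) sums of squares, optionally after a natural-log transform of the
response.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import TraitTable, ValidationError


def failed_development(ae: float, do: float, lo: float) -> float:
    """Fraction of failed embryos: (AE + DO) / (AE + DO + LO).

    Scale-free: multiplying all three counts by a constant leaves the
    fraction unchanged.
    """
    if ae < 0 or do < 0 or lo < 0:
        raise ValidationError("embryo counts must be non-negative")
    total = ae + do + lo
    if total == 0:
        raise ValidationError("failed development undefined for an empty brood")
    return (ae + do) / total


def tail_intensity(tail: float, head: float) -> float:
    """Comet tail intensity percentage: 100 * tail / (tail + head)."""
    if tail < 0 or head < 0:
        raise ValidationError("intensities must be non-negative")
    total = tail + head
    if total == 0:
        raise ValidationError("tail intensity undefined for zero comet intensity")
    return 100.0 * tail / total


def two_way_anova(
    values,
    factor_a,
    factor_b,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Sequential (Type I) two-way ANOVA: A, then B, then A x B.

    F statistics are tested against the residual mean square; with
    ``log_transform`` the response is natural-log transformed first
    (values must then be strictly positive).  Returns a table with rows
    A, B, A:B, Residual and columns term, df, SS, MS, F, p.
    """
    y = np.asarray(values, dtype=float)
    a = pd.Series(factor_a, dtype="object")
    b = pd.Series(factor_b, dtype="object")
    if not (len(y) == len(a) == len(b)):
        raise ValidationError("values and factors must have equal length")
    if log_transform:
        if (y <= 0).any():
            raise ValidationError("log transform requires strictly positive values")
        y = np.log(y)
    df = pd.DataFrame({"y": y, "A": a.values, "B": b.values})
    model = smf.ols("y ~ C(A) + C(B) + C(A):C(B)", data=df).fit()
    if model.df_resid <= 0:
        raise ValidationError("no residual degrees of freedom: F undefined")
    table = sm.stats.anova_lm(model, typ=1)
    out = table.rename(
        index={"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"}
    ).reset_index(names="term")
    out = out.rename(
        columns={"df": "df", "sum_sq": "SS", "F": "F", "PR(>F)": "p"}
    )
    out["MS"] = out["SS"] / out["df"]
    out["df"] = out["df"].astype(int)
    return out[["term", "df", "SS", "MS", "F", "p"]]


def trait_anova_table(
    traits: TraitTable,
    trait: str,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Genotype x treatment ANOVA for one trait column of a TraitTable.

    Continuous traits (size, age, fecundity, tail intensity) are
    conventionally log transformed; the failed-development fraction is
    tested untransformed.
    """
    df = traits.data
    if trait == "failed_development":
        y = [
            failed_development(r.aborted_eggs, r.dead_offspring, r.live_offspring)
            for r in df.itertuples()
        ]
        log_transform = False
    elif trait in df.columns:
        y = df[trait]
    else:
        raise ValidationError(f"unknown trait {trait!r}")
    return two_way_anova(y, df["genotype"], df["treatment"], log_transform=log_transform)


def reaction_norms(traits: TraitTable, trait: str) -> pd.DataFrame:
    """Per genotype x treatment mean and standard error for plotting."""
    df = traits.data
    if trait == "failed_development":
        values = pd.Series(
            [
                failed_development(r.aborted_eggs, r.dead_offspring, r.live_offspring)
                for r in df.itertuples()
            ],
            index=df.index,
        )
    elif trait in df.columns:
        values = df[trait]
    else:
        raise ValidationError(f"unknown trait {trait!r}")
    g = values.groupby([df["genotype"], df["treatment"]])
    out = g.agg(["mean", "sem", "count"]).reset_index()
    out.columns = ["genotype", "treatment", "mean", "se", "n"]
    return out
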