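"""Replicated random-forest regression linking host genes to gut sOTUs.

For each treatment (contrasted against control) and each retained sOTU, a
random-forest regression is fitted with the sOTU's transformed relative
abundance as the response and the variance-stabilized host transcriptome
as predictors.  Hyperparameters are tuned by randomized cross-validated
search (default 100 draws); the winning configuration is then refitted in
a highly replicated manner (default 80 independent fits) and the
impurity-reduction importances are averaged across fits.  A gene is
selected for an sOTU when its averaged importance holds at least a
``selection_threshold`` share (default 20%) of the total importance, so
at most ``floor(1/threshold)`` genes can be selected per sOTU and only
genes of major effect survive.

A model is kept only if its mean cross-validated MSE beats the response
variance (i.e. it outperforms the mean predictor); sOTUs failing this
quality rule are excluded from the pooled linked sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .io import CountMatrix, SampleTable, ValidationError

DEFAULT_SEARCH_SPACE: dict[str, tuple] = {
    "n_estimators": (100, 200, 300, 400, 500),
    "max_depth": (2, 4, 8, 16, None),
    "max_features": ("sqrt", 0.1, 0.2, 0.3, 0.4, 0.5, 1.0),
    "min_samples_leaf": (1, 2, 3, 4, 5),
}


@dataclass
class LinkConfig:
    n_runs: int = 80
    n_hyperparam_draws: int = 100
    cv_folds: int = 3
    selection_threshold: float = 0.20
    search_space: dict = field(default_factory=lambda: dict(DEFAULT_SEARCH_SPACE))
    quality_rule: bool = True
    include_control: bool = True  # pool control samples with each treatment
    treatments: tuple[str, ...] = ("glyphosate", "roundup")
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.selection_threshold <= 1:
            raise ValidationError("selection_threshold must be in (0, 1]")
        if self.n_runs < 1:
            raise ValidationError("n_runs must be >= 1")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")

    @classmethod
    def scaled_down(cls, seed: int = 0, **kw) -> "LinkConfig":
        """Light configuration for desk-scale runs: 10 runs, 10 draws."""
        space = {
            "n_estimators": (50, 100),
            "max_depth": (4, 8, None),
            "max_features": ("sqrt", 1.0),
            "min_samples_leaf": (1, 2),
        }
        return cls(n_runs=10, n_hyperparam_draws=10, search_space=space, seed=seed, **kw)


@dataclass
class SotuLinkModel:
    sotu_id: str
    best_params: dict
    cv_mse_per_run: list[float]
    mean_cv_mse: float
    var_y: float
    importances: pd.Series  # averaged over runs, sums to 1
    selected_genes: list[str]
    passes_quality: bool


@dataclass
class LinkResult:
    models: dict[str, list[SotuLinkModel]]  # per treatment
    all_genes: list[str]
    all_sotus: list[str]

    @property
    def pooled_pairs(self) -> set[tuple[str, str]]:
        return {
            (m.sotu_id, g)
            for ms in self.models.values()
            for m in ms
            if m.passes_quality
            for g in m.selected_genes
        }

    @property
    def pooled_genes(self) -> set[str]:
        return {g for _, g in self.pooled_pairs}

    @property
    def pooled_sotus(self) -> set[str]:
        return {
            m.sotu_id
            for ms in self.models.values()
            for m in ms
            if m.passes_quality and m.selected_genes
        }

    def model_table(self) -> pd.DataFrame:
        rows = []
        for treatment, ms in self.models.items():
            for m in ms:
                rows.append(
                    {
                        "treatment": treatment,
                        "sotu_id": m.sotu_id,
                        "params": ";".join(
                            f"{k}={v}" for k, v in sorted(m.best_params.items())
                        ),
                        "mean_cv_mse": m.mean_cv_mse,
                        "var_y": m.var_y,
                        "passes_quality": m.passes_quality,
                        "n_selected": len(m.selected_genes),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "treatment", "sotu_id", "params", "mean_cv_mse",
                "var_y", "passes_quality", "n_selected",
            ],
        )

    def pair_table(self) -> pd.DataFrame:
        rows = []
        for treatment, ms in self.models.items():
            for m in ms:
                if not m.passes_quality:
                    continue
                for g in m.selected_genes:
                    rows.append(
                        {
                            "treatment": treatment,
                            "sotu_id": m.sotu_id,
                            "gene_id": g,
                            "mean_importance": float(m.importances[g]),
                        }
                    )
        return pd.DataFrame(
            rows, columns=["treatment", "sotu_id", "gene_id", "mean_importance"]
        )


def prepare_design(
    expr: CountMatrix,
    sotus: CountMatrix,
    samples: SampleTable,
    treatment: str,
    include_control: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predictor and response tables for one treatment contrast.

    Samples: the named treatment plus (by default) controls.  X is
    variance-stabilized expression — log1p of CPM-normalized counts,
    z-scored per gene; a zero-variance gene cannot be z-scored and is
    rejected (it should have been removed by the gene filter).  Y is the
    per-sample relative abundance of each sOTU, log1p-transformed.  Rows
    of X and Y share identical order.
    """
    if treatment not in set(samples.data["treatment"]):
        raise ValidationError(f"treatment {treatment!r} absent from sample table")
    wanted = {treatment} | ({"control"} if include_control else set())
    ids = [s for s in samples.sample_ids if samples.data.at[s, "treatment"] in wanted]

    e = expr.subset_samples(ids).data.to_numpy(dtype=float)
    depth = e.sum(axis=0)
    if (depth == 0).any():
        raise ValidationError("expression sample with zero depth")
    logc = np.log1p(e / depth * 1e6)
    sd = logc.std(axis=1)
    raw_sd = e.std(axis=1)
    dead = [expr.feature_ids[i] for i in np.where((sd == 0) | (raw_sd == 0))[0]]
    if dead:
        raise ValidationError(f"zero-variance genes cannot be z-scored: {dead}")
    x = (logc - logc.mean(axis=1, keepdims=True)) / sd[:, None]
    xdf = pd.DataFrame(x.T, index=ids, columns=expr.feature_ids)

    rel = sotus.subset_samples(ids).relative_abundance()
    ydf = pd.DataFrame(np.log1p(rel.to_numpy().T), index=ids, columns=sotus.feature_ids)
    return xdf, ydf


def _grid(space: dict) -> list[dict]:
    keys = list(space)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(space[k] for k in keys))]


def _param_sort_key(params: dict):
    depth = params.get("max_depth")
    return (
        params.get("n_estimators", 0),
        np.inf if depth is None else depth,
    )


def tune_hyperparameters(
    X: pd.DataFrame, y: pd.Series, cfg: LinkConfig, seed: int
) -> tuple[dict, float] | None:
    """Randomized CV search over the declared space; returns (params, mean CV MSE).

    Evaluates ``n_hyperparam_draws`` distinct combinations (the full grid
    when it is smaller), scoring each by k-fold mean held-out MSE.  Ties
    are broken toward fewer trees, then shallower depth.  Returns None for
    a degenerate (zero-variance) response.
    """
    yv = y.to_numpy(dtype=float)
    if np.var(yv) == 0:
        return None
    if len(yv) < cfg.cv_folds:
        raise ValidationError(
            f"fewer samples ({len(yv)}) than cv_folds ({cfg.cv_folds})"
        )
    rng = np.random.default_rng(seed)
    grid = _grid(cfg.search_space)
    if len(grid) > cfg.n_hyperparam_draws:
        idx = rng.choice(len(grid), size=cfg.n_hyperparam_draws, replace=False)
        candidates = [grid[i] for i in sorted(idx)]
    else:
        candidates = grid
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True,
               random_state=int(rng.integers(0, 2**31 - 1)))
    splits = list(kf.split(X))
    xv = X.to_numpy(dtype=float)

    best: tuple[float, tuple, dict] | None = None
    for params in candidates:
        fold_mse = []
        for tr, te in splits:
            model = RandomForestRegressor(
                **params, random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1
            )
            model.fit(xv[tr], yv[tr])
            resid = yv[te] - model.predict(xv[te])
            fold_mse.append(float(np.mean(resid**2)))
        score = float(np.mean(fold_mse))
        key = (score, _param_sort_key(params))
        if best is None or key < (best[0], best[1]):
            best = (score, _param_sort_key(params), params)
    assert best is not None
    return best[2], best[0]


def fit_replicated(
    X: pd.DataFrame, y: pd.Series, best_params: dict, cfg: LinkConfig, seed: int,
    mean_cv_mse: float = float("nan"),
) -> SotuLinkModel:
    """Refit the tuned model ``n_runs`` times and average the importances.

    Each run is an independent forest (distinct derived seed) on the full
    sample subset; per-run impurity-reduction importances (normalized by
    sklearn to sum to 1) are averaged and renormalized.  Deterministic for
    a given seed.
    """
    rng = np.random.default_rng(seed)
    xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    acc = np.zeros(X.shape[1])
    for _ in range(cfg.n_runs):
        model = RandomForestRegressor(
            **best_params, random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1
        )
        model.fit(xv, yv)
        acc += model.feature_importances_
    mean_imp = acc / cfg.n_runs
    total = mean_imp.sum()
    if total > 0:
        mean_imp = mean_imp / total
    importances = pd.Series(mean_imp, index=X.columns)
    var_y = float(np.var(yv))
    passes = (not cfg.quality_rule) or (mean_cv_mse < var_y)
    selected = select_features_from_importances(importances, cfg.selection_threshold)
    return SotuLinkModel(
        sotu_id=str(y.name),
        best_params=dict(best_params),
        cv_mse_per_run=[mean_cv_mse],
        mean_cv_mse=mean_cv_mse,
        var_y=var_y,
        importances=importances,
        selected_genes=selected,
        passes_quality=passes,
    )


def select_features_from_importances(
    importances: pd.Series, threshold: float = 0.20
) -> list[str]:
    """Genes holding at least ``threshold`` of the total importance mass."""
    total = float(importances.sum())
    if total <= 0:
        return []
    return list(importances.index[importances / total >= threshold])


def select_features(model: SotuLinkModel, threshold: float = 0.20) -> list[str]:
    return select_features_from_importances(model.importances, threshold)


def link_analysis(
    expr: CountMatrix,
    sotus: CountMatrix,
    samples: SampleTable,
    cfg: LinkConfig | None = None,
) -> LinkResult:
    """Full linkage analysis: per treatment, per sOTU, tune -> refit -> select.

    Expects preprocessed matrices (filtered genes, collapsed/prevalence-
    filtered sOTUs).  Individual sOTU failures are isolated: a degenerate
    response is skipped without aborting the run.  The whole result is
    deterministic under a fixed master seed.
    """
    cfg = cfg or LinkConfig()
    cfg.validate()
    models: dict[str, list[SotuLinkModel]] = {}
    master = np.random.SeedSequence(cfg.seed)
    treatment_seeds = master.spawn(len(cfg.treatments))
    for treatment, tseed in zip(cfg.treatments, treatment_seeds):
        X, Y = prepare_design(expr, sotus, samples, treatment, cfg.include_control)
        sotu_seeds = tseed.spawn(2 * max(1, Y.shape[1]))
        fitted: list[SotuLinkModel] = []
        for k, sotu_id in enumerate(Y.columns):
            y = Y[sotu_id]
            tune_seed = int(sotu_seeds[2 * k].generate_state(1)[0] % (2**31 - 1))
            fit_seed = int(sotu_seeds[2 * k + 1].generate_state(1)[0] % (2**31 - 1))
            tuned = tune_hyperparameters(X, y, cfg, seed=tune_seed)
            if tuned is None:
                continue  # degenerate response, flagged by omission
            params, cv_mse = tuned
            fitted.append(
                fit_replicated(X, y, params, cfg, seed=fit_seed, mean_cv_mse=cv_mse)
            )
        models[treatment] = fitted
    return LinkResult(
        models=models, all_genes=expr.feature_ids, all_sotus=sotus.feature_ids
    )
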