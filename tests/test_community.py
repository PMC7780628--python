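"""Alpha/beta diversity closed forms and PERMANOVA oracle equivalences."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from skbio.stats.distance import DistanceMatrix

from hololink import community
from hololink.io import CountMatrix, SampleTable, ValidationError


def cm(array, samples=None):
    a = np.asarray(array, dtype=np.int64)
    samples = samples or [f"s{j}" for j in range(a.shape[1])]
    return CountMatrix(
        pd.DataFrame(a, index=[f"f{i}" for i in range(a.shape[0])], columns=samples)
    )


def sample_table(assignments: dict[str, dict]) -> SampleTable:
    df = pd.DataFrame.from_dict(assignments, orient="index")
    df.index.name = "sample_id"
    for col, default in (
        ("treatment", "control"),
        ("antibiotic", "wild_type"),
        ("replicate", "r1"),
        ("genotype", "G1"),
    ):
        if col not in df.columns:
            df[col] = default
    return SampleTable(df)


class TestAlpha:
    @pytest.mark.parametrize(
        "counts, shannon, evenness, observed",
        [
            ([25, 25, 25, 25], np.log(4), 1.0, 4),
            ([100, 0, 0], 0.0, np.nan, 1),
            ([50, 50, 0, 0], np.log(2), 1.0, 2),
        ],
    )
    def test_closed_forms(self, counts, shannon, evenness, observed):
        m = cm(np.array(counts)[:, None])
        row = community.alpha_diversity(m).iloc[0]
        assert row["shannon"] == pytest.approx(shannon, abs=1e-12)
        assert row["observed_features"] == observed
        if np.isnan(evenness):
            assert np.isnan(row["evenness"])
        else:
            assert row["evenness"] == pytest.approx(evenness, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            community.alpha_diversity(cm([[1, 0], [1, 0]]))


class TestBeta:
    def test_disjoint_supports(self):
        m = cm([[1, 0], [0, 1]])
        assert community.beta_diversity(m, "bray_curtis")["s0", "s1"] == 1.0
        assert community.beta_diversity(m, "jaccard")["s0", "s1"] == 1.0

    def test_identical_samples(self):
        m = cm([[3, 3], [5, 5]])
        assert community.beta_diversity(m, "bray_curtis")["s0", "s1"] == 0.0
        assert community.beta_diversity(m, "jaccard")["s0", "s1"] == 0.0

    def test_bray_curtis_formula(self):
        m = cm([[2, 1], [2, 3]])
        assert community.beta_diversity(m, "bray_curtis")["s0", "s1"] == pytest.approx(
            0.25
        )

    @pytest.mark.parametrize("metric", ["bray_curtis", "jaccard"])
    def test_bounds_symmetry_identity(self, metric):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = cm(rng.integers(0, 30, size=(6, 5)))
            d = community.beta_diversity(m, metric).data
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            assert (d >= 0).all() and (d <= 1).all()


def euclidean_dm(values: np.ndarray, ids) -> DistanceMatrix:
    diff = np.linalg.norm(values[:, None, :] - values[None, :, :], axis=-1)
    return DistanceMatrix(diff, ids=ids)


def sequential_anova_oracle(values: np.ndarray, design_blocks: list[np.ndarray]):
    """Sequential SS by explicit least-squares projection on raw coordinates."""
    n = values.shape[0]
    y = values - values.mean(axis=0)
    ss_total = float((y**2).sum())
    x = np.ones((n, 1))
    prev_rss = ss_total
    out = []
    for block in design_blocks:
        x = np.hstack([x, block])
        beta, *_ = np.linalg.lstsq(x, values, rcond=None)
        rss = float(((values - x @ beta) ** 2).sum())
        out.append(prev_rss - rss)
        prev_rss = rss
    return out, prev_rss, ss_total


class TestPermanova:
    def test_toy_groups_pseudo_f_equals_anova_f(self):
        vals = np.array([[0.0], [1.0], [10.0], [11.0]])
        ids = ["a", "b", "c", "d"]
        dm = euclidean_dm(vals, ids)
        st = sample_table({i: {"genotype": g} for i, g in zip(ids, "AABB")})
        table = community.permanova(dm, st, terms=("genotype",), n_perm=0)
        row = table.set_index("term").loc["genotype"]
        assert row["F"] == pytest.approx(200.0, rel=1e-10)
        assert row["df"] == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_euclidean_sequential_ss_matches_linear_model(self, seed):
        rng = np.random.default_rng(seed)
        genotypes = np.repeat(["G1", "G2", "G3"], 6)
        treatments = np.tile(np.repeat(["control", "glyphosate"], 3), 3)
        vals = rng.normal(size=(18, 2)) + (genotypes == "G2")[:, None] * 1.5
        ids = [f"s{i}" for i in range(18)]
        st = sample_table(
            {
                i: {"genotype": g, "treatment": t, "replicate": f"r{k}"}
                for k, (i, g, t) in enumerate(zip(ids, genotypes, treatments))
            }
        )
        dm = euclidean_dm(vals, ids)
        table = community.permanova(
            dm, st, terms=("genotype", "treatment", "genotype:treatment"), n_perm=0
        ).set_index("term")

        gdum = pd.get_dummies(pd.Series(genotypes), drop_first=True).to_numpy(float)
        tdum = pd.get_dummies(pd.Series(treatments), drop_first=True).to_numpy(float)
        inter = np.einsum("ni,nj->nij", gdum, tdum).reshape(18, -1)
        ss, ss_res, ss_total = sequential_anova_oracle(vals, [gdum, tdum, inter])
        for term, expected in zip(
            ("genotype", "treatment", "genotype:treatment"), ss
        ):
            assert table.loc[term, "SS"] == pytest.approx(expected, rel=1e-8)
        assert table.loc["Residual", "SS"] == pytest.approx(ss_res, rel=1e-8)
        assert table.loc["Total", "SS"] == pytest.approx(ss_total, rel=1e-8)

    def test_r2_sums_to_one_and_df_partition(self, small_dataset):
        dm = community.beta_diversity(small_dataset.sotus, "bray_curtis")
        table = community.permanova(
            dm,
            small_dataset.samples,
            terms=("genotype", "treatment", "antibiotic", "genotype:treatment"),
            n_perm=49,
            seed=5,
        )
        body = table[~table["term"].isin(["Total"])]
        assert body["R2"].sum() == pytest.approx(1.0, abs=1e-9)
        assert body["df"].sum() == len(small_dataset.samples.sample_ids) - 1

    def test_permutation_p_floor(self):
        rng = np.random.default_rng(0)
        vals = np.vstack([rng.normal(0, 0.1, (6, 1)), rng.normal(50, 0.1, (6, 1))])
        ids = [f"s{i}" for i in range(12)]
        st = sample_table({i: {"genotype": "A" if k < 6 else "B"}
                           for k, i in enumerate(ids)})
        dm = euclidean_dm(vals, ids)
        table = community.permanova(dm, st, terms=("genotype",), n_perm=99, seed=1)
        assert table.set_index("term").loc["genotype", "p"] == pytest.approx(0.01)

    def test_seed_reproducible(self, small_dataset):
        dm = community.beta_diversity(small_dataset.sotus, "bray_curtis")
        kw = dict(terms=("genotype", "treatment"), n_perm=99, seed=9)
        a = community.permanova(dm, small_dataset.samples, **kw)
        b = community.permanova(dm, small_dataset.samples, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_confounded_term_named(self):
        ids = ["a", "b", "c", "d"]
        st = sample_table(
            {i: {"genotype": g, "treatment": t, "replicate": f"r{k}"}
             for k, (i, g, t) in enumerate(
                 zip(ids, "AABB", ["control", "control", "glyphosate", "glyphosate"])
             )}
        )
        dm = euclidean_dm(np.arange(4.0)[:, None], ids)
        with pytest.raises(ValidationError, match="treatment"):
            community.permanova(dm, st, terms=("genotype", "treatment"), n_perm=0)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_permanova_matches_vegan_adonis2(tmp_path):
    """Cross-check sequential SS/R2/F against vegan's adonis2 on one design."""
    rng = np.random.default_rng(4)
    genotypes = np.repeat(["G1", "G2"], 9)
    treatments = np.tile(np.repeat(["control", "glyphosate", "roundup"], 3), 2)
    counts = cm(rng.integers(0, 60, size=(12, 18)))
    ids = counts.sample_ids
    st = sample_table(
        {i: {"genotype": g, "treatment": t, "replicate": f"r{k}"}
         for k, (i, g, t) in enumerate(zip(ids, genotypes, treatments))}
    )
    dm = community.beta_diversity(counts, "bray_curtis")
    mine = community.permanova(
        dm, st, terms=("genotype", "treatment", "genotype:treatment"), n_perm=0
    ).set_index("term")

    dist_path = tmp_path / "d.tsv"
    pd.DataFrame(dm.data, index=ids, columns=ids).to_csv(dist_path, sep="\t")
    meta_path = tmp_path / "meta.tsv"
    st.data.to_csv(meta_path, sep="\t")
    out_path = tmp_path / "vegan.tsv"
    script = tmp_path / "adonis.R"
    script.write_text(
        f"""
        suppressMessages(library(vegan))
        d <- as.dist(as.matrix(read.table("{dist_path}", sep="\\t", header=TRUE, row.names=1, check.names=FALSE)))
        meta <- read.table("{meta_path}", sep="\\t", header=TRUE, row.names=1)
        res <- adonis2(d ~ genotype * treatment, data=meta, permutations=99, by="terms")
        write.table(as.data.frame(res), "{out_path}", sep="\\t", quote=FALSE)
        """
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    vegan = pd.read_csv(out_path, sep="\t")
    vegan.index = ["genotype", "treatment", "genotype:treatment", "Residual", "Total"]
    for term in ("genotype", "treatment", "genotype:treatment", "Residual"):
        assert mine.loc[term, "SS"] == pytest.approx(
            vegan.loc[term, "SumOfSqs"], rel=1e-6
        ), term
        assert mine.loc[term, "df"] == vegan.loc[term, "Df"], term
    for term in ("genotype", "treatment", "genotype:treatment"):
        assert mine.loc[term, "F"] == pytest.approx(vegan.loc[term, "F"], rel=1e-6)
        assert mine.loc[term, "R2"] == pytest.approx(vegan.loc[term, "R2"], rel=1e-6)
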