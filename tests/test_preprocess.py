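"""Filtering, rarefaction, collapsing and core-taxon rules."""

import numpy as np
import pandas as pd
import pytest

from hololink import preprocess
from hololink.io import CountMatrix, SampleTable, TaxonomyTable, ValidationError
from hololink.io import parse_lineage


def cm(array, features=None, samples=None):
    a = np.asarray(array, dtype=np.int64)
    features = features or [f"f{i}" for i in range(a.shape[0])]
    samples = samples or [f"s{j}" for j in range(a.shape[1])]
    return CountMatrix(pd.DataFrame(a, index=features, columns=samples))


def taxonomy(lineages: dict) -> TaxonomyTable:
    rows = {sid: parse_lineage(ln) for sid, ln in lineages.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sotu_id"
    return TaxonomyTable(df)


class TestSotuFilters:
    def test_low_coverage_sample_removed_at_500(self):
        m = cm([[499, 500, 600], [0, 0, 0]])
        out, report = preprocess.filter_sotu_matrix(m, min_feature_reads=0,
                                                    min_feature_samples=0)
        assert out.sample_ids == ["s1", "s2"]
        assert report.removed_by("sample_depth") == ["s0"]

    def test_feature_below_10_reads_removed(self):
        m = cm([[9, 0, 0], [600, 600, 600]])
        out, report = preprocess.filter_sotu_matrix(m)
        assert out.feature_ids == ["f1"]
        assert report.removed_by("feature_reads") == ["f0"]

    def test_feature_in_exactly_two_samples_retained(self):
        m = cm([[30, 30, 0], [600, 600, 600]])
        out, _ = preprocess.filter_sotu_matrix(m)
        assert "f0" in out.feature_ids

    def test_all_samples_removed_is_hard_error(self):
        m = cm([[1, 2], [3, 4]])
        with pytest.raises(ValidationError, match="all samples"):
            preprocess.filter_sotu_matrix(m)

    def test_report_bookkeeping_identity(self):
        m = cm([[499, 600, 600], [9, 0, 0], [600, 600, 600]])
        _, report = preprocess.filter_sotu_matrix(m)
        for rec in report.records:
            assert rec.n_before - len(rec.removed) == rec.n_after


class TestReplicateCorrelation:
    @staticmethod
    def _samples(n, genotype="G1"):
        rows = [
            {
                "sample_id": f"s{i}",
                "genotype": genotype,
                "treatment": "control",
                "antibiotic": "wild_type",
                "replicate": f"r{i}",
            }
            for i in range(n)
        ]
        return SampleTable(pd.DataFrame(rows).set_index("sample_id"))

    def test_identical_replicates_kept(self):
        m = cm(np.tile([[10], [20], [30]], (1, 3)))
        out, _ = preprocess.filter_replicate_correlation(m, self._samples(3))
        assert out.sample_ids == ["s0", "s1", "s2"]

    def test_discordant_replicate_removed(self):
        # s2 orthogonal (r = 0) to two identical siblings: its mean r = 0
        # < 0.4 while the siblings keep mean r = (1 + 0)/2 >= 0.4
        m = cm([[10, 10, 5], [20, 20, 1], [30, 30, 5]])
        rel = m.relative_abundance()
        r = np.corrcoef(rel.to_numpy().T)
        assert abs(r[2, 0]) < 1e-9  # construction check
        out, report = preprocess.filter_replicate_correlation(m, self._samples(3))
        assert report.removed_by("replicate_correlation") == ["s2"]
        assert out.sample_ids == ["s0", "s1"]

    def test_r_min_zero_removes_nothing(self):
        rng = np.random.default_rng(0)
        m = cm(rng.integers(0, 50, size=(5, 3)))
        out, _ = preprocess.filter_replicate_correlation(m, self._samples(3), r_min=0.0)
        assert out.sample_ids == ["s0", "s1", "s2"]

    def test_singleton_cell_warns(self):
        m = cm([[5], [5]])
        _, report = preprocess.filter_replicate_correlation(m, self._samples(1))
        assert any("singleton" in w for w in report.warnings)


class TestRarefy:
    def test_depth_conserved_exactly(self):
        m = cm([[60], [40]])
        out = preprocess.rarefy(m, depth=50, seed=1)
        assert out.sample_sums()["s0"] == 50

    def test_identity_at_own_depth(self):
        m = cm([[60], [40]])
        out = preprocess.rarefy(m, depth=100, seed=1)
        assert out == m

    def test_seed_deterministic(self):
        m = cm([[900, 800], [100, 200]])
        a = preprocess.rarefy(m, depth=500, seed=7)
        b = preprocess.rarefy(m, depth=500, seed=7)
        assert a == b

    def test_hypergeometric_expectation(self):
        # taxon 1 holds 0.9 of a 10000-read sample; rarefied proportion is
        # unbiased, so the 200-seed mean sits within 3 SE of 0.9
        m = cm([[9000], [1000]])
        draws = np.array(
            [
                preprocess.rarefy(m, depth=1000, seed=s).data.iloc[0, 0]
                for s in range(200)
            ],
            dtype=float,
        ) / 1000.0
        se = draws.std(ddof=1) / np.sqrt(200)
        assert abs(draws.mean() - 0.9) < 3 * max(se, 1e-4)

    def test_depth_exceeding_all_samples_errors(self):
        m = cm([[10], [10]])
        with pytest.raises(ValidationError, match="depth"):
            preprocess.rarefy(m, depth=100, seed=1)


class TestCollapse:
    def test_same_genus_counts_add(self):
        tax = taxonomy(
            {
                "a": "d__B;p__P;c__C;o__O;f__F;g__Gx;s__",
                "b": "d__B;p__P;c__C;o__O;f__F;g__Gx;s__",
            }
        )
        m = cm([[3], [4]], features=["a", "b"])
        out = preprocess.collapse_to_rank(m, tax, rank="genus")
        assert out.data.loc["Gx", "s0"] == 7

    def test_per_sample_totals_invariant(self, small_dataset):
        m, tax = small_dataset.sotus, small_dataset.taxonomy
        out = preprocess.collapse_to_rank(m, tax, rank="genus")
        assert (out.sample_sums() == m.sample_sums()).all()

    def test_empty_genus_grouped_under_family(self):
        tax = taxonomy({"a": "d__B;p__P;c__C;o__O;f__Burkholderiaceae;g__;s__"})
        m = cm([[5]], features=["a"])
        out = preprocess.collapse_to_rank(m, tax, rank="genus")
        assert out.feature_ids == ["unclassified:Burkholderiaceae"]

    def test_unknown_rank_rejected(self, small_dataset):
        with pytest.raises(ValidationError, match="rank"):
            preprocess.collapse_to_rank(
                small_dataset.sotus, small_dataset.taxonomy, rank="serovar"
            )


class TestPrevalence:
    def test_three_of_five_retained_at_60pct(self):
        m = cm([[1, 1, 1, 0, 0], [1, 1, 0, 0, 0]])
        out, _ = preprocess.prevalence_filter(m, min_fraction=0.6)
        assert out.feature_ids == ["f0"]

    def test_zero_fraction_is_identity(self):
        m = cm([[1, 0], [0, 1]])
        out, report = preprocess.prevalence_filter(m, min_fraction=0.0)
        assert out == m and report.records[0].removed == []


class TestGeneFilters:
    def test_rules(self):
        m = cm(
            [[5, 5, 5, 5], [0, 0, 0, 7], [1, 2, 3, 4]],
            features=["const", "sparse", "ok"],
        )
        out, report = preprocess.filter_genes(m, max_zero_fraction=0.5)
        assert out.feature_ids == ["ok"]
        assert report.removed_by("invariant_genes") == ["const"]
        assert report.removed_by("sparse_genes") == ["sparse"]


class TestCoreTaxa:
    @staticmethod
    def _samples():
        rows = []
        for t in ("control", "glyphosate", "roundup"):
            for r in ("r1", "r2"):
                rows.append(
                    {
                        "sample_id": f"{t}_{r}",
                        "genotype": "G1",
                        "treatment": t,
                        "antibiotic": "wild_type",
                        "replicate": r,
                    }
                )
        return SampleTable(pd.DataFrame(rows).set_index("sample_id"))

    def test_core_rules(self):
        samples = self._samples()
        # f0: 2% everywhere -> overall core. f1: exactly 1.0% -> never core.
        # f2: 5% in glyphosate only -> core only there.
        data = np.zeros((4, 6), dtype=np.int64)
        data[0] = 20
        data[1] = 10
        data[2, 2:4] = 50
        data[3] = 1000 - data[:3].sum(axis=0)
        m = cm(data, samples=list(samples.sample_ids))
        core = preprocess.core_taxa(m, samples, threshold=0.01)
        assert "f0" in core["overall"]
        assert all("f1" not in core[t] for t in ("control", "glyphosate", "roundup"))
        assert "f2" in core["glyphosate"] and "f2" not in core["overall"]


@pytest.mark.parametrize(
    "apply_filter",
    [
        lambda m: preprocess.filter_sotu_matrix(m, 5, 3, 1)[0],
        lambda m: preprocess.prevalence_filter(m, 0.5)[0],
        lambda m: preprocess.filter_genes(m, 0.5)[0],
    ],
    ids=["sotu", "prevalence", "genes"],
)
def test_filters_idempotent(apply_filter):
    rng = np.random.default_rng(3)
    m = cm(rng.integers(0, 20, size=(12, 8)))
    once = apply_filter(m)
    assert apply_filter(once) == once
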