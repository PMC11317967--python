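"""TPM, differential expression, cis-correlation, Venn overlap, rescue."""

import numpy as np
import pandas as pd
import pytest

from aied.exceptions import ConfigurationError
from aied.integrate import (
    cis_correlation,
    cis_correlation_table,
    de_gene_test,
    overlap_dre_sets,
    rescue_call,
    tpm_normalize,
)
from aied.quantify import build_editing_matrix
from aied.simulate import generate_rescue_study

from oracles import membership_venn


class TestTpm:
    def test_single_gene_gets_the_whole_million(self):
        counts = pd.DataFrame({"s1": [50]}, index=["g1"])
        tpm = tpm_normalize(counts, pd.Series({"g1": 1000}))
        assert tpm.loc["g1", "s1"] == pytest.approx(1e6)

    def test_equal_counts_unequal_lengths(self):
        counts = pd.DataFrame({"s1": [100, 100]}, index=["g1", "g2"])
        tpm = tpm_normalize(counts, pd.Series({"g1": 1000, "g2": 2000}))
        assert tpm["s1"].tolist() == pytest.approx([666666.7, 333333.3], abs=0.1)

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, (20, 6)),
                              index=[f"g{i}" for i in range(20)])
        lengths = pd.Series(rng.integers(200, 5000, 20), index=counts.index)
        tpm = tpm_normalize(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-3)

    def test_invariant_to_global_length_rescaling(self, rng):
        counts = pd.DataFrame(rng.integers(1, 500, (10, 3)),
                              index=[f"g{i}" for i in range(10)])
        lengths = pd.Series(rng.integers(200, 5000, 10), index=counts.index)
        a = tpm_normalize(counts, lengths)
        b = tpm_normalize(counts, lengths * 7.5)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_zero_library_warns_and_zeroes(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [5, 5]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="zero library"):
            tpm = tpm_normalize(counts, pd.Series({"g1": 100, "g2": 100}))
        assert (tpm["s1"] == 0).all()


class TestDifferentialExpression:
    def _meta(self, n_per=4, groups=("a", "b")):
        rows = [
            {"sample_id": f"{g}{i}", "group": g}
            for g in groups for i in range(n_per)
        ]
        return pd.DataFrame(rows)

    def test_identical_columns_are_null(self):
        meta = self._meta()
        counts = pd.DataFrame(
            {m: [100, 50, 20] for m in meta["sample_id"]},
            index=["g1", "g2", "g3"],
        )
        res = de_gene_test(counts, meta)
        assert (res["p"] > 0.9).all()

    def test_single_sample_group_is_an_error(self):
        meta = self._meta(n_per=1)
        counts = pd.DataFrame({m: [10] for m in meta["sample_id"]}, index=["g1"])
        with pytest.raises(ConfigurationError, match="dispersion"):
            de_gene_test(counts, meta)

    def test_all_zero_gene_skipped_with_flag(self):
        meta = self._meta()
        counts = pd.DataFrame({m: [0, 30] for m in meta["sample_id"]}, index=["g0", "g1"])
        res = de_gene_test(counts, meta).set_index("gene")
        assert res.loc["g0", "flag"] == "all_zero"
        assert np.isnan(res.loc["g0", "p"])

    def test_shifted_genes_detected(self, rng):
        meta = self._meta(n_per=8)
        n_genes = 40
        base = rng.integers(50, 400, n_genes).astype(float)
        data = {}
        for _, row in meta.iterrows():
            mu = base * (2.0 if row["group"] == "b" else 1.0) ** (np.arange(n_genes) < 8)
            data[row["sample_id"]] = rng.poisson(mu)
        counts = pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)])
        res = de_gene_test(counts, meta).set_index("gene")
        hits = res["fdr"] < 0.05
        sens = hits[[f"g{i}" for i in range(8)]].mean()
        assert sens >= 0.8


class TestCisCorrelation:
    def test_strictly_increasing_pairs(self):
        r, p = cis_correlation([0.1, 0.2, 0.3, 0.4, 0.5], [1, 2, 3, 4, 5])
        assert r == pytest.approx(1.0)

    def test_anticorrelated_pairs(self):
        r, _ = cis_correlation([0.1, 0.2, 0.3, 0.35, 0.4], [50, 40, 30, 20, 10])
        assert r == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self, rng):
        x = rng.uniform(0, 1, 30)
        y = rng.uniform(1, 100, 30)
        r1, _ = cis_correlation(x, y)
        r2, _ = cis_correlation(np.exp(3 * x), np.log(y))
        assert r1 == pytest.approx(r2)

    def test_too_few_or_constant_is_undefined(self):
        assert np.isnan(cis_correlation([0.1, 0.2], [1, 2])[0])
        assert np.isnan(cis_correlation([0.2] * 6, [1, 2, 3, 4, 5, 6])[0])

    def test_generator_coupling_recovered(self, small_study):
        """Sites simulated with expression coupling show positive rank correlation."""
        from aied import io as aio
        from aied.integrate import tpm_normalize

        oriented, _ = aio.orient_to_sense(small_study.allele_counts)
        matrix = build_editing_matrix(oriented, min_coverage=1)
        tpm = tpm_normalize(small_study.expression, small_study.gene_lengths)
        genes = small_study.annotation.set_index("site_id")["gene"]
        coupled = small_study.truth.loc[small_study.truth["coupling"] > 0, "site_id"]
        table = cis_correlation_table(matrix, tpm, genes, sites=coupled)
        assert len(table) > 0
        assert table["spearman_r"].mean() > 0.2
        assert table["significant"].mean() > 0.5


class TestOverlap:
    def test_set_algebra_example(self):
        rep = overlap_dre_sets({"A": ["a", "b"], "B": ["b", "c"], "C": ["b"]})
        assert rep.shared_by_all == {"b"}
        assert rep.in_and_any_other("A") == {"b"}

    def test_disjoint_sets_share_nothing(self):
        rep = overlap_dre_sets({"A": ["a"], "B": ["b"], "C": ["c"]})
        assert rep.shared_by_all == set()
        assert all(len(k) == 1 for k in rep.cells)

    def test_cells_partition_the_union(self, rng):
        ids = [f"x{i}" for i in range(60)]
        sets = {n: list(rng.choice(ids, size=rng.integers(5, 40), replace=False))
                for n in "ABC"}
        rep = overlap_dre_sets(sets)
        union = set().union(*rep.sets.values())
        assert sum(len(v) for v in rep.cells.values()) == len(union)
        assert rep.cell_counts() == membership_venn(rep.sets)

    def test_duplicates_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            rep = overlap_dre_sets({"A": ["a", "a"], "B": ["a"]})
        assert rep.sets["A"] == {"a"}


class TestRescue:
    def _counts(self, means, n_per=4, cov=200, seed=0):
        rng = np.random.default_rng(seed)
        rows, meta_rows = [], []
        for g, mu in means.items():
            for i in range(n_per):
                sid = f"{g}{i}"
                meta_rows.append({"sample_id": sid, "group": g})
                alt = rng.binomial(cov, mu)
                rows.append({"site_id": "s:chr1:1", "sample_id": sid,
                             "ref_count": cov - alt, "alt_count": alt,
                             "chrom": "chr1", "pos": 1, "strand": "+",
                             "ref": "A", "alt": "G"})
        return pd.DataFrame(rows), pd.DataFrame(meta_rows)

    def test_restored_site_is_rescued(self):
        counts, meta = self._counts({"CON": 0.10, "LPS": 0.30, "FUL": 0.12})
        res = rescue_call(counts, meta)
        assert res["rescued"].iloc[0]

    def test_persistently_shifted_site_is_not_rescued(self):
        counts, meta = self._counts({"CON": 0.10, "LPS": 0.30, "FUL": 0.35})
        res = rescue_call(counts, meta)
        assert not res["rescued"].iloc[0]

    def test_requires_two_samples_per_arm(self):
        counts, meta = self._counts({"CON": 0.1, "LPS": 0.3, "FUL": 0.1}, n_per=1)
        with pytest.raises(ConfigurationError, match="fewer than 2"):
            rescue_call(counts, meta)

    def test_simulated_rescue_pattern_recovered(self):
        study = generate_rescue_study(
            n_rescued=15, n_unrescued=10, n_null=40,
            effect_size=0.15, coverage_mean=100, seed=4,
        )
        from aied import io as aio

        oriented, _ = aio.orient_to_sense(study.allele_counts)
        res = rescue_call(oriented, study.metadata).set_index("site_id")
        truth = study.truth.set_index("site_id").loc[res.index]
        sens = res.loc[truth["is_rescued"], "rescued"].mean()
        spec = (~res.loc[~truth["is_rescued"], "rescued"]).mean()
        assert sens >= 0.8
        assert spec >= 0.8
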