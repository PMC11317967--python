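"""GLM+LRT, pooled exact test, BH adjustment, trends, and the DRE caller."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from aied.catalog import SubgroupScheme
from aied.differential import (
    bh_adjust,
    call_dre,
    covariate_effects,
    dre_inclusion_mask,
    fisher_pooled,
    glm_lrt_site,
    trend_cluster,
)

from oracles import brute_fisher, design_matrices, irls_lrt


class TestGlmLrt:
    def test_identical_counts_in_all_groups_give_p_one(self):
        alt = np.full(12, 10)
        ref = np.full(12, 90)
        g = np.repeat(["a", "b", "c"], 4)
        res = glm_lrt_site(alt, ref, g)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_fixture_matches_irls_oracle(self):
        alt = np.array([10] * 4 + [30] * 4)
        ref = np.array([90] * 4 + [70] * 4)
        g = np.repeat(["a", "b"], 4)
        res = glm_lrt_site(alt, ref, g)
        X_full, X_null, df = design_matrices(g)
        p_oracle, dev_full, dev_null = irls_lrt(alt, ref, X_full, X_null, df)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-8)
        assert res.statistic == pytest.approx(dev_null - dev_full, abs=1e-8)

    def test_all_zero_alt_counts_flagged_degenerate(self):
        res = glm_lrt_site(np.zeros(8), np.full(8, 50), np.repeat(["a", "b"], 4))
        assert res.p_value == 1.0
        assert res.flag == "degenerate"

    def test_insufficient_replication_gives_missing_p(self):
        res = glm_lrt_site([5, 6], [45, 44], ["a", "b"])
        assert np.isnan(res.p_value)
        assert res.flag == "insufficient"

    def test_quasi_mode_is_more_conservative_under_overdispersion(self, rng):
        n = np.full(24, 60)
        q = rng.beta(4, 16, size=24)  # overdispersed around 0.2
        alt = rng.binomial(n, q)
        g = np.repeat(["a", "b", "c"], 8)
        plain = glm_lrt_site(alt, n - alt, g)
        quasi = glm_lrt_site(alt, n - alt, g, dispersion="quasi")
        assert quasi.p_value >= plain.p_value

    def test_group_coefficients_returned(self):
        alt = np.array([10] * 4 + [30] * 4)
        ref = np.array([90] * 4 + [70] * 4)
        res = glm_lrt_site(alt, ref, np.repeat(["a", "b"], 4))
        # logit(0.3) - logit(0.1)
        expected = np.log(30 / 70) - np.log(10 / 90)
        assert res.group_coefs["group[b]"] == pytest.approx(expected, abs=1e-6)


class TestCovariateEffects:
    def test_constant_covariate_is_inestimable(self):
        alt = np.array([10, 12, 30, 28])
        ref = np.array([90, 88, 70, 72])
        g = np.array(["a", "a", "b", "b"])
        out = covariate_effects(alt, ref, g, age=np.array(["y", "o", "y", "o"]),
                                sex=np.array(["f", "f", "f", "f"]))
        assert np.isnan(out["p_sex"])
        assert not np.isnan(out["p_age"])

    def test_matches_irls_oracle_with_covariates(self):
        rng = np.random.default_rng(3)
        g = np.repeat(["a", "b"], 8)
        age = np.tile(np.repeat(["y", "o"], 4), 2)
        sex = np.tile(["m", "f"], 8)
        n = np.full(16, 80)
        p = np.where(g == "b", 0.25, 0.15) + np.where(age == "o", 0.05, 0.0)
        alt = rng.binomial(n, p)
        out = covariate_effects(alt, n - alt, g, age, sex)
        X_full, _, _ = design_matrices(g, age=age, sex=sex)
        X_noage, _, _ = design_matrices(g, age=None, sex=sex)
        p_oracle, _, _ = irls_lrt(alt, n - alt, X_full, X_noage, 1)
        assert out["p_age"] == pytest.approx(p_oracle, abs=1e-8)


class TestFisherPooled:
    def test_identical_groups_give_p_one(self):
        assert fisher_pooled([[90, 10], [90, 10]]) == pytest.approx(1.0)

    def test_two_group_table_matches_enumeration(self):
        t = [[90, 10], [50, 50]]
        assert fisher_pooled(t) == pytest.approx(brute_fisher(t), rel=1e-9)

    def test_three_group_table_matches_enumeration(self):
        t = [[90, 10], [80, 20], [50, 50]]
        assert fisher_pooled(t) == pytest.approx(brute_fisher(t), rel=1e-9)

    def test_zero_read_group_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero total reads"):
            p = fisher_pooled([[90, 10], [0, 0], [50, 50]])
        assert p == pytest.approx(fisher_pooled([[90, 10], [50, 50]]))

    def test_all_groups_empty_is_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(fisher_pooled([[0, 0], [0, 0]]))

    def test_monte_carlo_fallback_close_to_exact(self):
        t = [[300, 60], [280, 80], [260, 100]]
        exact = fisher_pooled(t)
        mc = fisher_pooled(t, rng=np.random.default_rng(7), max_tables=10)
        assert mc == pytest.approx(exact, abs=0.02)


class TestBhAdjust:
    def test_hand_computed_staircase(self):
        # p(i) * m / i = 0.05 for every i, cummin leaves all at 0.05
        out = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
        assert out == pytest.approx([0.05] * 5)

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_nan_excluded_then_reinserted(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(0.02)

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=50)
    )
    @settings(max_examples=50, deadline=None, derandomize=True, database=None)
    def test_matches_statsmodels_and_preserves_ranking(self, ps):
        ours = bh_adjust(ps)
        ref = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(ours, ref)
        order = np.argsort(ps)
        assert (np.diff(ours[order]) >= -1e-12).all()
        assert (ours <= 1).all() and (ours >= np.asarray(ps) - 1e-12).all()


class TestTrendRules:
    @pytest.mark.parametrize(
        "means,label",
        [
            ((0.10, 0.20, 0.12), "early_up_then_down"),
            ((0.10, 0.11, 0.25), "late_up"),
            ((0.20, 0.10, 0.08), "down"),
            ((0.10, 0.10, 0.10), "unclassified"),   # exact ties
            ((0.10, 0.20, 0.20), "late_up"),        # late >= early, above baseline
            ((0.10, 0.05, 0.15), "late_up"),
            ((0.20, 0.25, 0.30), "late_up"),
            ((0.20, 0.15, 0.25), "late_up"),
            ((0.20, 0.25, 0.22), "early_up_then_down"),
            ((0.20, 0.10, 0.20), "unclassified"),
            ((np.nan, 0.1, 0.2), "unclassified"),
        ],
    )
    def test_rule_table(self, means, label):
        assert trend_cluster(*means) == label


class TestInclusionAndCaller:
    def _study(self, rng, n_sites=8, level=0.2):
        samples = [f"s{i}" for i in range(12)]
        groups = np.repeat(["control", "D1", "D4"], 4)
        meta = pd.DataFrame({"sample_id": samples, "group": groups})
        rows = []
        for i in range(n_sites):
            for s in samples:
                cov = 50
                alt = rng.binomial(cov, level)
                rows.append({"site_id": f"g{i}:chr1:{i+1}", "sample_id": s,
                             "ref_count": cov - alt, "alt_count": alt,
                             "chrom": "chr1", "pos": i + 1, "strand": "+",
                             "ref": "A", "alt": "G"})
        return pd.DataFrame(rows), meta

    def test_inclusion_boundary_at_5_percent(self):
        m = pd.DataFrame({"s1": [0.05, 0.02], "s2": [0.049, 0.02]}, index=["a", "b"])
        scheme = SubgroupScheme(pd.Series({"s1": "g1", "s2": "g2"}))
        mask = dre_inclusion_mask(m, scheme, threshold=0.05)
        assert mask.tolist() == [True, False]

    def test_identical_data_site_never_called(self, rng):
        counts, meta = self._study(rng, n_sites=1)
        counts["alt_count"] = 10
        counts["ref_count"] = 40
        res = call_dre(counts, meta, groups=("control", "D1", "D4"))
        assert not res["is_dre"].any()
        assert res["p_glm"].iloc[0] == pytest.approx(1.0)

    def test_fdr_off_mode_calls_at_raw_p(self, rng):
        counts, meta = self._study(rng, n_sites=6)
        # inject one strongly shifted site
        shifted = counts["site_id"] == "g0:chr1:1"
        d1 = counts["sample_id"].isin([f"s{i}" for i in range(4, 8)])
        counts.loc[shifted & d1, "alt_count"] = 35
        counts.loc[shifted & d1, "ref_count"] = 15
        res = call_dre(counts, meta, groups=("control", "D1", "D4"), fdr_mode="off")
        assert res.set_index("site_id").loc["g0:chr1:1", "is_dre"]
        on = call_dre(counts, meta, groups=("control", "D1", "D4"))
        assert (on["fdr"] >= on["p_glm"] - 1e-12).all()

    def test_delta_flag_consistent_with_group_means(self, rng):
        counts, meta = self._study(rng, n_sites=4)
        res = call_dre(counts, meta, groups=("control", "D1", "D4"))
        gm = res[["mean_control", "mean_D1", "mean_D4"]].to_numpy()
        max_delta = np.max(gm, axis=1) - np.min(gm, axis=1)
        assert np.allclose(res["max_delta"], max_delta)
        assert (res["delta5_flag"] == (res["max_delta"] >= 0.05)).all()
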