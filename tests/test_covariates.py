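import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from hoodspot.covariates import (
    DEFAULT_HOUSEKEEPING,
    correlate_genes,
    heatmap_order,
    remove_housekeeping,
    sample_means,
)
from hoodspot.synthetic import StudyDesign, default_covariate_table, simulate_study

from .oracles import brute_average_linkage


def _cov_table(values):
    return pd.DataFrame(
        {"violent_crime_rate": values},
        index=[f"S{i}" for i in range(len(values))],
    )


class TestSampleMeans:
    def test_single_spot_sample_mean_is_that_spot(self, rng):
        m1 = pd.DataFrame(rng.random((5, 1)), index=list("abcde"))
        m2 = pd.DataFrame(rng.random((5, 8)), index=list("abcde"))
        means = sample_means({"s1": m1, "s2": m2})
        assert np.allclose(means["s1"], m1.iloc[:, 0])

    def test_disjoint_gene_universes_rejected(self, rng):
        m1 = pd.DataFrame(rng.random((2, 3)), index=["a", "b"])
        m2 = pd.DataFrame(rng.random((2, 3)), index=["c", "d"])
        with pytest.raises(ValueError, match="shared"):
            sample_means({"s1": m1, "s2": m2})

    def test_partial_overlap_drops_with_warning(self, rng):
        m1 = pd.DataFrame(rng.random((3, 4)), index=["a", "b", "c"])
        m2 = pd.DataFrame(rng.random((2, 4)), index=["b", "c"])
        with pytest.warns(UserWarning, match="dropping"):
            means = sample_means({"s1": m1, "s2": m2})
        assert sorted(means.index) == ["b", "c"]

    def test_matches_direct_recomputation(self, rng):
        mats = {
            f"s{i}": pd.DataFrame(rng.random((10, 7)),
                                  index=[f"g{j}" for j in range(10)])
            for i in range(3)
        }
        means = sample_means(mats)
        for sid, df in mats.items():
            assert np.allclose(means[sid], df.to_numpy().mean(axis=1))


class TestCorrelateGenes:
    def test_exactly_linear_gene_gives_r_one_up(self, rng):
        cov = _cov_table(np.linspace(2.0, 30.0, 15))
        means = pd.DataFrame(
            [2.0 + 0.5 * cov["violent_crime_rate"].to_numpy()], index=["lin"],
            columns=cov.index,
        )
        res = correlate_genes(means, cov)
        assert res.iloc[0]["r"] == pytest.approx(1.0)
        assert res.iloc[0]["p"] == pytest.approx(0.0, abs=1e-30)
        assert res.iloc[0]["direction"] == "up"

    def test_matches_scipy_pearsonr(self, rng):
        cov = _cov_table(rng.uniform(1, 40, size=12))
        means = pd.DataFrame(rng.normal(size=(20, 12)),
                             index=[f"g{i}" for i in range(20)],
                             columns=cov.index)
        res = correlate_genes(means, cov, all_results=True).set_index("gene_id")
        for g in means.index:
            r, p = stats.pearsonr(means.loc[g], cov["violent_crime_rate"])
            assert res.loc[g, "r"] == pytest.approx(r, abs=1e-12)
            assert res.loc[g, "p"] == pytest.approx(p, abs=1e-12)

    def test_constant_gene_skipped_not_fatal(self, rng):
        cov = _cov_table(rng.uniform(1, 40, size=10))
        means = pd.DataFrame(
            [np.full(10, 3.0), rng.normal(size=10)], index=["const", "ok"],
            columns=cov.index,
        )
        with pytest.warns(UserWarning, match="constant gene"):
            res = correlate_genes(means, cov, all_results=True)
        assert list(res["gene_id"]) == ["ok"]

    def test_constant_covariate_rejected(self, rng):
        cov = _cov_table(np.full(10, 5.0))
        means = pd.DataFrame(rng.normal(size=(2, 10)), index=["a", "b"],
                             columns=cov.index)
        with pytest.raises(ValueError, match="constant"):
            correlate_genes(means, cov)

    def test_too_few_samples_rejected(self, rng):
        cov = _cov_table([1.0, 2.0])
        means = pd.DataFrame(rng.normal(size=(2, 2)), columns=cov.index)
        with pytest.raises(ValueError, match=">= 3"):
            correlate_genes(means, cov)

    def test_invariant_to_positive_affine_transforms(self, rng):
        cov = _cov_table(rng.uniform(1, 40, size=10))
        means = pd.DataFrame(rng.normal(size=(5, 10)),
                             index=[f"g{i}" for i in range(5)], columns=cov.index)
        base = correlate_genes(means, cov, all_results=True)
        shifted = correlate_genes(3.0 + 2.0 * means, cov, all_results=True)
        assert np.allclose(base["r"], shifted["r"])
        cov2 = cov * 7.0 + 1.0
        scaled = correlate_genes(means, cov2, all_results=True)
        assert np.allclose(base["r"], scaled["r"])

    def test_null_type_one_error_calibrated(self, rng):
        """1,000 independent genes, n = 15: positive rate within 3 binomial
        SEs of 0.05."""
        cov = _cov_table(rng.uniform(1, 40, size=15))
        means = pd.DataFrame(rng.normal(size=(1000, 15)),
                             index=[f"g{i}" for i in range(1000)],
                             columns=cov.index)
        res = correlate_genes(means, cov, all_results=True)
        rate = float((res["p"] < 0.05).mean())
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_noiseless_study_recovery_exact(self):
        """On simulate_study output with noise_sd = 0 every planted gene has
        |r| = 1; sensitivity is 1 and the direction matches the slope sign."""
        design = StudyDesign(n_samples=15, n_genes=50, n_covariate_genes=10,
                             effect_slope=0.2, noise_sd=0.0, seed=7)
        means, cov, truth = simulate_study(design)
        res = correlate_genes(means, cov)
        got = set(res["gene_id"])
        assert set(truth["covariate_genes"]) <= got
        planted = res[res["gene_id"].isin(truth["covariate_genes"])]
        assert np.allclose(planted["r"], 1.0)
        assert (planted["direction"] == "up").all()


class TestRemoveHousekeeping:
    def test_empty_list_is_identity(self):
        assert remove_housekeeping(["TP53", "EGFR"], hk_list=[]) == ["TP53", "EGFR"]

    def test_all_housekeeping_warns_and_empties(self):
        with pytest.warns(UserWarning, match="empty"):
            assert remove_housekeeping(["ACTB", "GAPDH"]) == []

    def test_case_insensitive_matching(self):
        assert remove_housekeeping(["actb", "Gapdh", "EGFR"]) == ["EGFR"]

    def test_default_list_applied(self):
        kept = remove_housekeeping(["TP53"] + list(DEFAULT_HOUSEKEEPING))
        assert kept == ["TP53"]


class TestHeatmapOrder:
    def test_identical_rows_adjacent(self, rng):
        base = rng.random(6)
        mat = pd.DataFrame(
            [base, rng.random(6), base + 0.0, rng.random(6) + 5],
            index=["a", "x", "a2", "y"],
            columns=[f"S{i}" for i in range(6)],
        )
        rates = pd.Series(np.arange(6.0), index=mat.columns)
        order = heatmap_order(mat, rates)
        rows = list(mat.index[order.row_order])
        assert abs(rows.index("a") - rows.index("a2")) == 1

    def test_columns_sorted_by_crime_rate(self, rng):
        mat = pd.DataFrame(rng.random((3, 3)), columns=["S0", "S1", "S2"])
        rates = pd.Series([9.0, 2.0, 5.0], index=mat.columns)
        order = heatmap_order(mat, rates)
        assert list(order.col_order) == [1, 2, 0]

    def test_single_row_trivial_order(self, rng):
        mat = pd.DataFrame(rng.random((1, 4)))
        rates = pd.Series(np.arange(4.0), index=mat.columns)
        order = heatmap_order(mat, rates)
        assert list(order.row_order) == [0]

    def test_cophenetic_matches_brute_force_average_linkage(self, rng):
        """scipy average-linkage cophenetic distances equal an O(n^3) naive
        agglomeration on the log-transformed rows (random 20 x 15)."""
        mat = pd.DataFrame(rng.random((20, 15)) * 10,
                           columns=[f"S{i}" for i in range(15)])
        rates = pd.Series(rng.random(15), index=mat.columns)
        order = heatmap_order(mat, rates)
        log_m = np.log2(mat.to_numpy() + 1.0)
        coph = hierarchy.cophenet(order.linkage_matrix)
        from scipy.spatial.distance import squareform

        assert np.allclose(squareform(coph), brute_average_linkage(log_m), atol=1e-8)


class TestDefaultCovariateTable:
    def test_invariants(self, rng):
        tab = default_covariate_table(15, rng)
        assert len(tab) == 15
        assert (tab["violent_crime_rate"] >= 0).all()
        pct = tab[["pct_black", "pct_white", "pct_hispanic", "pct_poverty"]]
        assert ((pct >= 0) & (pct <= 100)).all().all()
        assert set(tab["crime_tier"]) == {"low", "medium", "high"}
        # tiers are ordered in violent crime rate
        assert (
            tab[tab["crime_tier"] == "low"]["violent_crime_rate"].max()
            < tab[tab["crime_tier"] == "high"]["violent_crime_rate"].min()
        )
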