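"""Cohort statistics: enrichment, rate correlations, ANOVA, age, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mthet import (
    DegenerateStatisticError,
    ParameterError,
    age_correlations,
    build_maf_matrix,
    cluster_samples,
    mean_rate_comparison,
    mr_correlation,
    occurrence_counts,
    per_site_anova,
    region_enrichment,
)
from mthet.cohort import _woolf_ci


@pytest.fixture
def small_cohort(make_profile):
    profiles = [
        make_profile("CENT01", "CENT", "F01", {146: 0.02, 204: 0.01}),
        make_profile("CENT02", "CENT", "F02", {146: 0.015}),
        make_profile("CO01", "CO", "F01", {146: 0.018, 120: 0.003}),
        make_profile("CO02", "CO", "F02", {146: 0.012, 204: 0.005}),
        make_profile("ONLL01", "ONLL", None, {16129: 0.004}),
        make_profile("ONLL02", "ONLL", None, {}),
    ]
    return build_maf_matrix(profiles)


class TestMafMatrix:
    def test_shape_and_entries(self, small_cohort):
        matrix, meta = small_cohort
        assert matrix.shape == (6, 853)
        assert matrix.loc["CENT01", 146] == 0.02
        assert matrix.loc["ONLL02"].sum() == 0.0
        assert list(meta["group"]) == ["CENT", "CENT", "CO", "CO", "ONLL", "ONLL"]

    def test_entries_within_maf_bounds(self, small_cohort):
        matrix, _ = small_cohort
        values = matrix.to_numpy()
        assert values.min() >= 0.0 and values.max() <= 0.5


class TestOccurrenceCounts:
    def test_planted_counts(self, small_cohort):
        matrix, meta = small_cohort
        occ = occurrence_counts(matrix, meta["group"], "CENT")
        assert occ.loc[146, "count"] == 2
        assert occ.loc[204, "count"] == 1
        assert occ.loc[146, "mean_maf"] == pytest.approx((0.02 + 0.015) / 2)
        assert np.isnan(occ.loc[120, "mean_maf"])  # zero occurrences -> absent

    def test_unknown_group_rejected(self, small_cohort):
        matrix, meta = small_cohort
        with pytest.raises(ParameterError):
            occurrence_counts(matrix, meta["group"], "NOPE")


class TestRegionEnrichment:
    def test_cells_sum_to_fragment_and_or_direction(self, region_map):
        hv2_sites = set(range(80, 120))  # all inside HV2
        results = {e.region: e for e in region_enrichment(hv2_sites, region_map)}
        for e in results.values():
            assert e.het_in + e.non_het_in + e.het_out + e.non_het_out == 853
        assert results["HV2"].odds_ratio > 1
        assert results["HV1"].odds_ratio < 1
        assert results["INTERMEDIATE"].odds_ratio < 1
        assert results["HV2"].p_value < 1e-6

    def test_uniform_coverage_is_degenerate_or_one(self, region_map, coords):
        all_sites = set(int(p) for p in coords.positions)
        results = region_enrichment(all_sites, region_map)
        for e in results:
            assert e.degenerate
            assert e.odds_ratio == 1.0
            assert e.p_value == 1.0

    def test_woolf_ci_cross_product(self):
        orr, lo, hi = _woolf_ci(10, 90, 5, 95)
        assert orr == pytest.approx((10 * 95) / (90 * 5))
        assert lo < orr < hi
        se = np.sqrt(1 / 10 + 1 / 90 + 1 / 5 + 1 / 95)
        assert np.log(hi) - np.log(orr) == pytest.approx(stats.norm.ppf(0.975) * se)

    def test_haldane_anscombe_on_zero_cell(self):
        orr, lo, hi = _woolf_ci(0, 100, 10, 90)
        expected = (0.5 * 90.5) / (100.5 * 10.5)
        assert orr == pytest.approx(expected)
        assert 0 < lo < hi


class TestMrCorrelation:
    def test_proportional_rates(self, coords):
        rates = pd.Series(
            np.linspace(1, 10, 853), index=[int(p) for p in coords.positions]
        )
        occ = pd.Series(3.0 * rates.to_numpy(), index=rates.index)
        r, p = mr_correlation(occ, rates)
        assert r == pytest.approx(1.0)

    def test_anti_proportional(self, coords):
        rates = pd.Series(
            np.linspace(1, 10, 853), index=[int(p) for p in coords.positions]
        )
        occ = pd.Series(-rates.to_numpy() + 20, index=rates.index)
        r, _ = mr_correlation(occ, rates)
        assert r == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self, coords):
        rng = np.random.default_rng(5)
        idx = [int(p) for p in coords.positions]
        rates = pd.Series(rng.gamma(0.5, 2, 853), index=idx)
        occ = pd.Series(rng.poisson(1.0, 853).astype(float), index=idx)
        r, p = mr_correlation(occ, rates)
        assert abs(r) < 0.1

    def test_zero_variance_flagged(self, coords):
        idx = [int(p) for p in coords.positions]
        rates = pd.Series(np.ones(853), index=idx)
        occ = pd.Series(np.arange(853, dtype=float), index=idx)
        with pytest.raises(DegenerateStatisticError):
            mr_correlation(occ, rates)


class TestMeanRateComparison:
    def test_equal_rates_give_p_one(self, region_map, coords):
        rates = pd.Series(2.0, index=[int(p) for p in coords.positions])
        out = mean_rate_comparison({146, 204}, rates, region_map)
        assert out.loc["ALL", "mean_rate_all"] == out.loc["ALL", "mean_rate_het"] == 2.0
        assert out.loc["ALL", "mannwhitney_p"] == 1.0

    def test_hotspot_het_sites_detected(self, region_map, coords):
        idx = [int(p) for p in coords.positions]
        rng = np.random.default_rng(8)
        rates = pd.Series(rng.gamma(1.0, 2.0, 853), index=idx)
        top = rates.nlargest(40).index  # het sites planted at top-decile rates
        out = mean_rate_comparison(set(int(s) for s in top), rates, region_map)
        assert out.loc["ALL", "mean_rate_het"] > out.loc["ALL", "mean_rate_all"]
        assert out.loc["ALL", "mannwhitney_p"] < 1e-6

    def test_stratum_without_het_flagged(self, region_map, coords):
        rates = pd.Series(
            np.linspace(1, 3, 853), index=[int(p) for p in coords.positions]
        )
        out = mean_rate_comparison({16100}, rates, region_map)  # HV1 only
        assert np.isnan(out.loc["HV2", "mean_rate_het"])
        assert out.loc["HV1", "n_het_sites"] == 1

    def test_empty_het_sites_rejected(self, region_map, coords):
        rates = pd.Series(1.0, index=[int(p) for p in coords.positions])
        with pytest.raises(ParameterError):
            mean_rate_comparison(set(), rates, region_map)


class TestPerSiteAnova:
    def _matrix(self, data: np.ndarray, groups: list[str], coords):
        cols = [int(p) for p in coords.positions]
        matrix = pd.DataFrame(data, columns=cols,
                              index=[f"S{i}" for i in range(len(groups))])
        return matrix, pd.Series(groups, index=matrix.index)

    def test_identical_groups_give_zero_f(self, coords):
        data = np.zeros((6, 853))
        matrix, groups = self._matrix(data, ["A"] * 3 + ["B"] * 3, coords)
        out = per_site_anova(matrix, groups, contrasts=False)
        assert (out["F"] == 0).all()
        assert (out["p"] == 1).all()

    def test_planted_shift_is_top_hit(self, coords):
        rng = np.random.default_rng(12)
        data = rng.normal(0.002, 0.001, size=(90, 853)).clip(0)
        site_idx = coords.require(146)
        data[:30, site_idx] += 0.01  # group A shifted at position 146
        matrix, groups = self._matrix(data, ["A"] * 30 + ["B"] * 30 + ["C"] * 30, coords)
        out = per_site_anova(matrix, groups)
        assert out["p_adj"].idxmin() == 146
        assert out.loc[146, "p_adj"] < 1e-6
        assert "A-B" in out.loc[146, "significant_contrasts"]

    def test_two_group_f_equals_t_squared(self, coords):
        rng = np.random.default_rng(13)
        data = rng.normal(size=(20, 853))
        matrix, groups = self._matrix(data, ["A"] * 10 + ["B"] * 10, coords)
        out = per_site_anova(matrix, groups, contrasts=False)
        t = stats.ttest_ind(data[:10], data[10:], axis=0)
        assert np.allclose(out["F"].to_numpy(), t.statistic**2, atol=1e-8)
        assert np.allclose(out["p"].to_numpy(), t.pvalue, atol=1e-10)

    def test_bonferroni_never_below_nominal(self, coords):
        rng = np.random.default_rng(14)
        data = rng.normal(size=(12, 853))
        matrix, groups = self._matrix(data, ["A"] * 6 + ["B"] * 6, coords)
        out = per_site_anova(matrix, groups, contrasts=False)
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert (out["p_adj"] <= 1.0).all()

    def test_group_size_preconditions(self, coords):
        data = np.zeros((3, 853))
        matrix, groups = self._matrix(data, ["A", "A", "B"], coords)
        with pytest.raises(ParameterError):
            per_site_anova(matrix, groups)


class TestAgeCorrelations:
    def test_linear_column_has_unit_correlation(self, coords):
        ages = pd.Series([60.0, 70, 80, 90, 100], index=[f"S{i}" for i in range(5)])
        data = np.zeros((5, 853))
        data[:, coords.require(204)] = 0.0001 * ages.to_numpy()
        matrix = pd.DataFrame(data, index=ages.index,
                              columns=[int(p) for p in coords.positions])
        per_site, _ = age_correlations(matrix, ages)
        assert per_site.loc[204, "r"] == pytest.approx(1.0)
        assert per_site.loc[204, "p"] < 0.01

    def test_constant_column_flagged(self, coords):
        ages = pd.Series([60.0, 70, 80], index=["S0", "S1", "S2"])
        matrix = pd.DataFrame(
            np.zeros((3, 853)), index=ages.index, columns=[int(p) for p in coords.positions]
        )
        per_site, count_rp = age_correlations(matrix, ages)
        assert not per_site["defined"].any()
        assert np.isnan(per_site["r"]).all()

    def test_permuted_ages_near_null(self, coords):
        rng = np.random.default_rng(15)
        n = 60
        ages = pd.Series(rng.uniform(60, 100, n), index=[f"S{i}" for i in range(n)])
        data = rng.exponential(0.004, size=(n, 853)) * (rng.random((n, 853)) < 0.05)
        matrix = pd.DataFrame(data, index=ages.index,
                              columns=[int(p) for p in coords.positions])
        per_site, _ = age_correlations(matrix, ages)
        defined_p = per_site.loc[per_site["defined"], "p"]
        # under independence roughly 5% of nominal p-values fall below 0.05
        assert abs((defined_p < 0.05).mean() - 0.05) < 0.04


class TestClustering:
    def test_identical_samples_merge_at_zero(self, coords, make_profile):
        profiles = [
            make_profile("A", "CENT", None, {146: 0.01}),
            make_profile("B", "CENT", None, {146: 0.01}),
        ]
        matrix, _ = build_maf_matrix(profiles)
        res = cluster_samples(matrix)
        assert res.linkage[0, 2] == 0.0

    def test_complete_linkage_uses_max_distance(self):
        # three points with pairwise distances 1, 1, 10 -> final merge at 10
        matrix = pd.DataFrame(
            [[0.0], [1.0], [10.0]], index=["a", "b", "c"], columns=[146]
        )
        res = cluster_samples(matrix)
        heights = res.linkage[:, 2]
        assert heights[-1] == pytest.approx(10.0)
        assert (np.diff(heights) >= 0).all()

    def test_planted_partition_recovered(self, coords):
        rng = np.random.default_rng(16)
        a = rng.normal(0.0, 0.0005, size=(5, 853)).clip(0)
        b = rng.normal(0.0, 0.0005, size=(5, 853)).clip(0)
        b[:, :50] += 0.05
        matrix = pd.DataFrame(
            np.vstack([a, b]),
            index=[f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)],
            columns=[int(p) for p in coords.positions],
        )
        res = cluster_samples(matrix)
        clusters = res.cut(2)
        groups = {}
        for label, c in clusters.items():
            groups.setdefault(c, set()).add(label[0])
        assert sorted(map(sorted, groups.values())) == [["A"], ["B"]]

    def test_newick_contains_all_leaves(self, coords, make_profile):
        profiles = [
            make_profile(f"S{i}", "CENT", None, {146: 0.001 * (i + 1)}) for i in range(4)
        ]
        matrix, _ = build_maf_matrix(profiles)
        nwk = cluster_samples(matrix).to_newick()
        assert nwk.endswith(";")
        for i in range(4):
            assert f"S{i}:" in nwk

    def test_duplicate_ids_rejected(self):
        matrix = pd.DataFrame([[0.0], [1.0]], index=["a", "a"], columns=[146])
        with pytest.raises(ParameterError):
            cluster_samples(matrix)
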