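"""Mother-offspring transmission statistics and reshuffling nulls."""

import itertools

import numpy as np
import pytest

from mthet import (
    DegenerateStatisticError,
    ParameterError,
    PairSet,
    classify_sites,
    cross_group_null,
    pair_correlation,
    pair_site_distances,
    reshuffle_null,
    site_distance,
    tncs,
    total_heteroplasmy,
)


def make_pairs(make_profile, mother_mafs, offspring_mafs, onll_mafs=()):
    pairs = []
    profiles = []
    for i, (m, o) in enumerate(zip(mother_mafs, offspring_mafs), start=1):
        fam = f"F{i:02d}"
        profiles.append(make_profile(f"CENT{i}", "CENT", fam, m))
        profiles.append(make_profile(f"CO{i}", "CO", fam, o))
    for i, m in enumerate(onll_mafs, start=1):
        profiles.append(make_profile(f"ONLL{i}", "ONLL", None, m))
    return PairSet.from_profiles(profiles)


class TestTotalHeteroplasmy:
    def test_sum_in_percent(self, make_profile):
        p = make_profile("S", "CENT", None, {1: 0.005, 2: 0.003, 3: 0.002})
        assert total_heteroplasmy(p) == pytest.approx(1.0)

    def test_no_calls_is_zero(self, make_profile):
        assert total_heteroplasmy(make_profile("S", "CENT", None, {})) == 0.0

    def test_matches_generator_bookkeeping(self):
        from mthet import GeneratorConfig, generate_truth_cohort

        cohort = generate_truth_cohort(GeneratorConfig(), seed=4)
        for profile in cohort.profiles[:5]:
            assert profile.total_heteroplasmy == pytest.approx(
                100 * sum(profile.maf.values())
            )


class TestPairCorrelation:
    def test_perfect_concordance(self, make_profile):
        mafs = [{146: 0.01 * (i + 1)} for i in range(5)]
        pairs = make_pairs(make_profile, mafs, mafs)
        th_m = pairs.mother_values(total_heteroplasmy)
        th_o = pairs.offspring_values(total_heteroplasmy)
        r, p = pair_correlation(th_m, th_o)
        assert r == pytest.approx(1.0)

    def test_independent_values_near_zero(self):
        rng = np.random.default_rng(21)
        rs = [
            pair_correlation(rng.normal(size=29), rng.normal(size=29))[0]
            for _ in range(50)
        ]
        assert abs(np.mean(rs)) < 0.1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ParameterError):
            pair_correlation([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            pair_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestReshuffleNull:
    def test_exhaustive_permutation_mean_is_zero(self):
        """Mean Pearson r over all n! permutations is exactly 0.

        Brute-force enumeration at n = 5: permuting one side leaves both
        marginal means and variances unchanged, and the centered values of
        the permuted side sum to zero, so the permutation average of the
        correlation vanishes identically (for any fixed vectors).
        """
        rng = np.random.default_rng(22)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        rs = []
        for perm in itertools.permutations(range(5)):
            yp = y[list(perm)]
            rs.append(np.corrcoef(x, yp)[0, 1])
        assert np.mean(rs) == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_mean_matches_exhaustive(self):
        """The 2000-reshuffle Monte-Carlo mean agrees with the exhaustive
        permutation mean (zero) to within 4 standard errors at n = 29."""
        rng = np.random.default_rng(23)
        x = rng.normal(size=29)
        y = rng.normal(size=29)
        null = reshuffle_null(x, y, "pearson_r", n_reshuffles=2000, seed=1)
        se = null.sd / np.sqrt(2000)
        assert abs(null.mean - 0.0) < 4 * se

    def test_constant_site_sets_give_p_one(self, make_profile):
        sites = {146: 0.01, 204: 0.02}
        pairs = make_pairs(make_profile, [sites] * 5, [sites] * 5)
        null = reshuffle_null(
            [m.sites for m, _ in pairs.pairs],
            [o.sites for _, o in pairs.pairs],
            "tncs", n_reshuffles=200, seed=2,
        )
        assert null.p == 1.0
        assert null.sd == 0.0

    def test_empirical_p_add_one_convention(self):
        rng = np.random.default_rng(24)
        x = np.arange(10.0)
        y = x + rng.normal(0, 0.1, 10)  # observed r near 1 beats all reshuffles
        null = reshuffle_null(x, y, "pearson_r", n_reshuffles=999, seed=3)
        assert null.p >= 1 / 1000  # never exactly zero
        assert null.p == (1 + np.sum(null.replicates >= null.observed)) / 1000

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ParameterError):
            reshuffle_null([1.0, 2.0], [1.0], "pearson_r", 10, seed=0)

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ParameterError):
            reshuffle_null([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "median", 10, seed=0)


class TestCrossGroupNull:
    def test_centered_near_zero_with_truncation(self):
        rng = np.random.default_rng(25)
        a = rng.normal(size=29)
        b = rng.normal(size=28)  # smaller group; pairs truncate to 28
        null = cross_group_null(a, b, n_reshuffles=500, seed=4)
        assert null.observed is None and null.p is None
        assert abs(null.mean) < 3 * null.sd / np.sqrt(500) + 0.05


class TestTncs:
    def test_small_example(self, make_profile):
        pairs = make_pairs(
            make_profile,
            [{146: 0.01, 204: 0.01}, {100: 0.01}],
            [{146: 0.02, 204: 0.005}, {120: 0.01}],
        )
        assert tncs(pairs) == 2

    def test_identical_triplet_shared_by_all(self, make_profile):
        sites = {146: 0.01, 204: 0.01, 16129: 0.01}
        pairs = make_pairs(make_profile, [sites] * 29, [sites] * 29)
        assert tncs(pairs) == 87

    def test_symmetric_and_bounded(self, make_profile):
        m = [{146: 0.01, 100: 0.02}, {204: 0.01}]
        o = [{146: 0.03}, {204: 0.02, 150: 0.01}]
        assert tncs(make_pairs(make_profile, m, o)) == tncs(make_pairs(make_profile, o, m))
        assert tncs(make_pairs(make_profile, m, o)) <= 853 * 2

    def test_matches_generator_bookkeeping(self):
        from mthet import GeneratorConfig, generate_truth_cohort

        cohort = generate_truth_cohort(GeneratorConfig(), seed=6)
        by_hand = sum(len(m.sites & o.sites) for m, o in cohort.pairs)
        assert cohort.planted_tncs == by_hand


class TestSiteDistance:
    @pytest.mark.parametrize(
        "m1,m2,expected",
        [(0.005, 0.0025, 50.0), (0.004, 0.004, 0.0), (0.002, 0.02, 90.0)],
    )
    def test_examples(self, m1, m2, expected):
        assert site_distance(m1, m2) == pytest.approx(expected)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(26)
        for _ in range(50):
            a, b = rng.uniform(0.002, 0.5, size=2)
            d = site_distance(a, b)
            assert 0.0 <= d <= 100.0
            assert d == pytest.approx(site_distance(b, a))
            if a == b:
                assert d == 0.0

    def test_below_threshold_rejected(self):
        with pytest.raises(ParameterError):
            site_distance(0.001, 0.01)

    def test_distance_matrix_nan_outside_joint_sites(self, make_profile):
        pairs = make_pairs(
            make_profile,
            [{146: 0.01, 204: 0.02}],
            [{146: 0.005, 120: 0.01}],
        )
        dist = pair_site_distances(pairs)
        assert dist.loc["F01", 146] == pytest.approx(50.0)
        assert np.isnan(dist.loc["F01", 204])  # mother-only site
        assert np.isnan(dist.loc["F01", 120])  # offspring-only site


class TestClassifySites:
    def test_shared_by_all_is_public(self, make_profile):
        sites = {146: 0.01}
        pairs = make_pairs(make_profile, [sites] * 4, [sites] * 4)
        assert classify_sites(pairs)[146] == "public"

    def test_shared_by_one_pair_is_private(self, make_profile):
        pairs = make_pairs(
            make_profile,
            [{146: 0.01}, {100: 0.01}, {}, {}],
            [{146: 0.02}, {100: 0.02}, {}, {}],
        )
        classes = classify_sites(pairs, public_fraction=0.5)
        assert classes[146] == "private"
        assert classes[100] == "private"
        assert classes[204] == "absent"

    def test_generator_public_sites_recovered(self):
        from mthet import GeneratorConfig, generate_truth_cohort
        from mthet.calling import HeteroplasmyCall, SampleProfile

        cohort = generate_truth_cohort(GeneratorConfig(), seed=7)
        profiles = []
        for t in cohort.profiles:
            calls = tuple(
                HeteroplasmyCall(site=s, major_allele="A", minor_allele="G",
                                 maf=min(m, 0.5), depth=50_000, ds_validated=True)
                for s, m in sorted(t.maf.items())
            )
            profiles.append(
                SampleProfile(t.sample_id, t.group, t.family_id, t.age,
                              50_000.0, True, calls)
            )
        pairs = PairSet.from_profiles(profiles)
        classes = classify_sites(pairs)
        for site in (146, 204, 16129):
            assert classes[site] == "public"


class TestPairSet:
    def test_duplicate_family_rejected(self, make_profile):
        a = make_profile("CENT1", "CENT", "F01", {})
        b = make_profile("CO1", "CO", "F01", {})
        with pytest.raises(ParameterError):
            PairSet(pairs=((a, b), (a, b)))

    def test_qc_failed_members_drop_the_pair(self, make_profile):
        from mthet.calling import SampleProfile

        good_m = make_profile("CENT1", "CENT", "F01", {146: 0.01})
        good_o = make_profile("CO1", "CO", "F01", {146: 0.01})
        bad = SampleProfile("CENT2", "CENT", "F02", 70.0, 500.0, False, ())
        orphan = make_profile("CO2", "CO", "F02", {})
        pairs = PairSet.from_profiles([good_m, good_o, bad, orphan])
        assert pairs.n_pairs == 1
        assert pairs.pairs[0][0].sample_id == "CENT1"
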