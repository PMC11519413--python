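"""Ranking, chi-squared, Anderson-Darling, BH control, and the battery."""

import itertools

import numpy as np
import pytest
import scipy.stats

from nephrometry import (
    DataError,
    ad_ksample,
    bh_adjust,
    chi2_independence,
    default_pairs,
    derive_variables,
    fdr_bound,
    rank_within_kidney,
    run_dependence_battery,
    simulate_cohort,
)
from nephrometry.dependence import _ADWorkspace, _ad_null_sd, _groups_to_codes
from nephrometry.simulate import null_config


class TestRanking:
    def test_simple_ranks(self):
        out = rank_within_kidney([10.0, 20.0, 30.0], ["k1"] * 3)
        np.testing.assert_allclose(out, [1 / 3, 2 / 3, 1.0])

    def test_midranks_for_ties(self):
        out = rank_within_kidney([5.0, 5.0, 7.0], ["k1"] * 3)
        np.testing.assert_allclose(out, [0.5, 0.5, 1.0])

    def test_per_kidney_normalization(self):
        values = [1.0, 2.0, 100.0, 200.0, 300.0]
        kidneys = ["a", "a", "b", "b", "b"]
        out = rank_within_kidney(values, kidneys)
        np.testing.assert_allclose(out, [0.5, 1.0, 1 / 3, 2 / 3, 1.0])

    def test_strictly_increasing_input_increasing_output(self):
        rng = np.random.default_rng(0)
        values = np.sort(rng.normal(size=20))
        out = rank_within_kidney(values, ["k"] * 20)
        assert (np.diff(out) > 0).all()
        assert out.min() > 0 and out.max() == 1.0

    def test_missing_values_stay_missing(self):
        out = rank_within_kidney([1.0, np.nan, 3.0], ["k"] * 3)
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.5, 1.0])


class TestChi2:
    def test_perfect_independence(self):
        stat, p = chi2_independence([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # 60 * (20*20 - 10*10)^2 / (30*30*30*30) = 20/3
        stat, _ = chi2_independence([[20, 10], [10, 20]])
        assert stat == pytest.approx(20 / 3, abs=1e-12)

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            table = rng.integers(1, 30, size=(3, 4)).astype(float)
            stat, _ = chi2_independence(table)
            expected = table.sum() * 0.0
            E = np.outer(table.sum(1), table.sum(0)) / table.sum()
            expected = ((table - E) ** 2 / E).sum()
            assert stat == pytest.approx(expected, abs=1e-10)
            assert stat >= 0

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            stat, _ = chi2_independence([[5, 5], [0, 0], [5, 5]])
        ref, _ = chi2_independence([[5, 5], [5, 5]])
        assert stat == pytest.approx(ref)

    def test_degenerate_table_is_error(self):
        with pytest.raises(DataError):
            chi2_independence([[5, 5]])


class TestAndersonDarling:
    def test_statistic_matches_reference_implementation(self):
        """Tie-adjusted A2akN agrees with scipy's midrank version."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            sizes = rng.integers(8, 30, size=3)
            values = np.round(rng.normal(size=sizes.sum()), 1)  # heavy ties
            labels = np.repeat(np.arange(3), sizes)
            codes, sz = _groups_to_codes(labels)
            ws = _ADWorkspace(values, sz)
            mine = (ws.a2akn(codes) - 2) / _ad_null_sd(sz)
            ref = scipy.stats.anderson_ksamp(
                [values[labels == i] for i in range(3)], midrank=True
            ).statistic
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_identical_group_multisets_not_significant(self):
        stat, p = ad_ksample(
            [1, 2, 3, 1, 2, 3], [0, 0, 0, 1, 1, 1], method="permutation",
            n_perm=999, seed=0,
        )
        assert p >= 0.5

    def test_all_values_identical(self):
        stat, p = ad_ksample([4, 4, 4, 4], [0, 0, 1, 1])
        assert stat == 0.0 and p == 1.0

    def test_exact_enumeration_well_separated_groups(self):
        """{1,2,3,4} vs {10,11,12,13}: the observed split and its mirror are
        the two most extreme of C(8,4)=70 relabellings."""
        _, p = ad_ksample(
            [1, 2, 3, 4, 10, 11, 12, 13], [0, 0, 0, 0, 1, 1, 1, 1], method="exact"
        )
        assert p == pytest.approx(2 / 70, abs=1e-12)

    def test_permutation_approximates_exact(self):
        values = [1.0, 4.0, 2.0, 8.0, 3.0, 9.0, 7.0]
        labels = [0, 0, 0, 1, 1, 1, 1]
        _, p_exact = ad_ksample(values, labels, method="exact")
        _, p_perm = ad_ksample(values, labels, method="permutation",
                               n_perm=9999, seed=5)
        assert p_perm == pytest.approx(p_exact, abs=0.03)

    def test_exact_matches_independent_enumeration(self):
        """Exhaustive oracle written from scratch with scipy's statistic."""
        values = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        _, p_exact = ad_ksample(values, labels, method="exact")
        obs = scipy.stats.anderson_ksamp(
            [values[labels == 0], values[labels == 1]], midrank=True
        ).statistic
        n_ge = 0
        combos = list(itertools.combinations(range(8), 4))
        for combo in combos:
            mask = np.zeros(8, dtype=bool)
            mask[list(combo)] = True
            stat = scipy.stats.anderson_ksamp(
                [values[mask], values[~mask]], midrank=True
            ).statistic
            if stat >= obs - 1e-9:
                n_ge += 1
        assert p_exact == pytest.approx(n_ge / len(combos), abs=1e-12)

    def test_asymptotic_and_permutation_agree_under_null(self):
        rng = np.random.default_rng(42)
        for i in range(5):
            values = rng.normal(size=120)
            labels = np.repeat([0, 1], 60)
            _, p_asym = ad_ksample(values, labels, method="asymptotic")
            _, p_perm = ad_ksample(values, labels, method="permutation",
                                   n_perm=2999, seed=i)
            if 0.001 < p_asym < 0.25:  # outside, the asymptotic p is clipped
                assert p_perm == pytest.approx(p_asym, abs=0.02)

    def test_rank_invariance_under_monotone_transform(self):
        """AD on per-kidney ranks is unchanged by any within-kidney monotone
        transform of the raw values."""
        rng = np.random.default_rng(9)
        values = rng.normal(size=40)
        kidneys = np.repeat(["k1", "k2"], 20)
        groups = np.tile([0, 1], 20)
        r1 = rank_within_kidney(values, kidneys)
        r2 = rank_within_kidney(np.exp(3 * values), kidneys)
        s1, p1 = ad_ksample(r1, groups, method="permutation", n_perm=499, seed=0)
        s2, p2 = ad_ksample(r2, groups, method="permutation", n_perm=499, seed=0)
        assert s1 == pytest.approx(s2, abs=1e-12)
        assert p1 == p2

    def test_empty_group_is_error(self):
        with pytest.raises(DataError):
            ad_ksample([1.0, 2.0, 3.0], [0, 0, 0])


class TestMultipleTesting:
    def test_all_ones_no_rejections(self):
        assert not bh_adjust(np.ones(10), q=0.015).any()

    def test_single_small_p_rejected(self):
        assert bh_adjust([0.01], q=0.05).all()

    def test_step_up_hand_check_18_of_78(self):
        """18 p-values at 0.001 among 78 (rest >= 0.5), q=0.015: threshold
        18*0.015/78 = 0.00346 >= 0.001, so exactly 18 rejections."""
        p = np.concatenate([np.full(18, 0.001), np.full(60, 0.6)])
        flags = bh_adjust(p, q=0.015)
        assert flags.sum() == 18
        assert flags[:18].all() and not flags[18:].any()

    def test_matches_manual_step_up_on_random_p(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=40)
        q = 0.1
        flags = bh_adjust(p, q)
        order = np.argsort(p)
        ks = [k for k in range(1, 41) if p[order][k - 1] <= k * q / 40]
        k_max = max(ks) if ks else 0
        manual = np.zeros(40, dtype=bool)
        manual[order[:k_max]] = True
        np.testing.assert_array_equal(flags, manual)

    def test_empty_input(self):
        assert bh_adjust([], q=0.015).size == 0

    def test_fdr_bound_headline(self):
        """78 tests, 18 rejections all with p <= 0.001: plug-in bound 0.00433,
        below the 0.015 budget."""
        bound = fdr_bound(78, 18, 0.001)
        assert bound == pytest.approx(78 * 0.001 / 18, abs=1e-12)
        assert bound < 0.015

    def test_fdr_bound_degenerate_and_monotone(self):
        assert fdr_bound(10, 10, 0.1) == pytest.approx(0.1)
        bounds = [fdr_bound(50, k, 0.002) for k in range(1, 51)]
        assert all(a >= b for a, b in zip(bounds, bounds[1:]))
        with pytest.raises(DataError):
            fdr_bound(10, 0, 0.01)


class TestBattery:
    def test_default_battery_size(self, derived):
        res = run_dependence_battery(derived, method="asymptotic")
        assert len(res) == 78
        assert len(default_pairs()) == 78
        assert set(res["processing_variable"]) == {"technique", "stain", "medulla_present"}

    def test_untestable_pairs_flagged_not_rejected(self, derived):
        res = run_dependence_battery(derived, method="asymptotic")
        unt = res[res["untestable"]]
        # intensive variables are missing exactly when medulla is present
        assert (unt["processing_variable"] == "medulla_present").all()
        assert not unt["rejected"].any()
        assert unt["p_value"].isna().all()

    def test_strong_stain_effect_detected(self):
        """A stain shift of >= 2 slide SDs on IF% must be rejected with
        p <= 0.001."""
        from nephrometry import SimConfig

        cfg = SimConfig(seed=21, stain_effect_ifta_pct=8.0)
        d = derive_variables(simulate_cohort(cfg))
        res = run_dependence_battery(d, method="permutation", n_perm=9999, seed=3)
        row = res[(res["processing_variable"] == "stain")
                  & (res["morphometric_variable"] == "if_pct")].iloc[0]
        assert row["p_value"] <= 0.001
        assert row["rejected"]

    def test_null_cohort_rejects_nothing_much(self):
        d = derive_variables(simulate_cohort(null_config(seed=77)))
        res = run_dependence_battery(d, method="asymptotic")
        assert int(res["rejected"].sum()) <= 2

    def test_permutation_seed_reproducible(self, derived):
        r1 = run_dependence_battery(derived, method="permutation", n_perm=99, seed=4)
        r2 = run_dependence_battery(derived, method="permutation", n_perm=99, seed=4)
        np.testing.assert_array_equal(r1["p_value"].to_numpy(), r2["p_value"].to_numpy())
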