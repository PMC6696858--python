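"""Validation statistics: MAPE, Dunnett, correlations, Bland-Altman."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from paee.agreement import (
    DeviceValidation,
    PairedSample,
    bland_altman_modified,
    build_validation_table,
    correlations,
    dunnett_many_to_one,
    dunnett_paired,
    mape,
    partial_correlation,
)


class TestMape:
    def test_identical_vectors(self):
        c = np.array([500.0, 600, 700])
        assert mape(c, c) == (0.0, 0.0)

    def test_constant_ratio(self):
        c = np.array([500.0, 600, 700])
        m, s = mape(1.2 * c, c)
        assert m == pytest.approx(20.0, rel=1e-12)
        assert s == pytest.approx(0.0, abs=1e-9)

    def test_matches_elementwise_oracle(self, rng):
        c = rng.uniform(300, 900, 19)
        d = rng.uniform(100, 900, 19)
        m, s = mape(d, c)
        ape = 100 * np.abs(d - c) / c
        assert m == pytest.approx(ape.mean(), rel=1e-12)
        assert s == pytest.approx(ape.std(ddof=1), rel=1e-12)

    def test_zero_criterion_names_subject(self):
        with pytest.raises(ValueError, match="index 1"):
            mape(np.ones(3), np.array([1.0, 0.0, 2.0]))


class TestDunnett:
    def test_k1_collapses_to_pooled_t(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.6, 1, 15)
        res = dunnett_many_to_one(a, [b], mc_draws=200_000, seed=5)
        p_ref = stats.ttest_ind(b, a, equal_var=True).pvalue
        assert res.p_adjusted[0] == pytest.approx(p_ref, abs=0.005)

    def test_identical_groups_give_p_near_one(self, rng):
        a = rng.normal(0, 1, 12)
        res = dunnett_many_to_one(a, [a.copy(), a.copy()], mc_draws=50_000, seed=1)
        assert np.all(res.p_adjusted > 0.95)

    def test_matches_scipy_dunnett(self, rng):
        # independent implementation check on a k=3 balanced problem
        control = rng.normal(0, 1, 12)
        groups = [rng.normal(mu, 1, 12) for mu in (0.0, 0.8, 1.6)]
        ours = dunnett_many_to_one(control, groups, mc_draws=400_000, seed=9)
        ref = stats.dunnett(*groups, control=control)
        np.testing.assert_allclose(ours.t_stats, ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(ours.p_adjusted, ref.pvalue, atol=0.01)

    def test_adjusted_p_never_below_pairwise(self, rng):
        control = rng.normal(0, 1, 10)
        groups = [rng.normal(mu, 1, 10) for mu in (0.3, 0.6, 0.9, 1.2)]
        res = dunnett_many_to_one(control, groups, mc_draws=100_000, seed=2)
        # pairwise p from the same pooled-variance t and df
        pair_p = 2 * stats.t.sf(np.abs(res.t_stats), res.df)
        assert np.all(res.p_adjusted >= pair_p - 0.004)

    def test_seeded_runs_are_bit_reproducible(self, rng):
        a = rng.normal(0, 1, 10)
        gs = [rng.normal(0.5, 1, 10)]
        r1 = dunnett_many_to_one(a, gs, seed=7)
        r2 = dunnett_many_to_one(a, gs, seed=7)
        assert np.array_equal(r1.p_adjusted, r2.p_adjusted)
        assert r1.critical_value == r2.critical_value

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            dunnett_many_to_one(np.ones(5), [np.ones(5)], seed=0)

    def test_paired_variant_flags_consistent_shift(self, rng):
        c = rng.normal(700, 150, 19)
        shifted = c - 120 + rng.normal(0, 20, 19)
        unbiased = c + rng.normal(0, 20, 19)
        res = dunnett_paired(c, np.vstack([shifted, unbiased]), seed=3)
        assert res.p_adjusted[0] < 0.05
        assert res.p_adjusted[1] > 0.05


class TestCorrelations:
    def test_affine_relation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, rp, rho, rhop = correlations(x, 2 * x + 3)
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.array([-2.0, -1, 0.5, 1, 2, 3])
        r, _, rho, _ = correlations(x, x**3)
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_ties_match_average_rank_oracle(self):
        x = np.array([1.0, 2, 2, 3, 4, 4, 4, 5])
        y = np.array([2.0, 1, 3, 3, 5, 4, 6, 7])
        _, _, rho, _ = correlations(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlations(np.ones(5), np.arange(5.0))

    @given(a=st.floats(0.1, 5), b=st.floats(-10, 10))
    @settings(derandomize=True, max_examples=30)
    def test_pearson_invariant_under_positive_affine(self, a, b):
        x = np.array([1.0, 2, 4, 8, 9, 12])
        y = np.array([3.0, 1, 4, 6, 8, 7])
        r1, _, _, _ = correlations(x, y)
        r2, _, _, _ = correlations(a * x + b, y)
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_spearman_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(1, 10, 20)
        y = rng.uniform(1, 10, 20)
        _, _, rho1, _ = correlations(x, y)
        _, _, rho2, _ = correlations(np.exp(x), y)
        assert rho2 == pytest.approx(rho1, rel=1e-12)


class TestPartialCorrelation:
    def test_recursion_formula_oracle(self, rng):
        x = rng.normal(0, 1, 30)
        z = rng.normal(0, 1, 30)
        y = 0.5 * x + 0.3 * z + rng.normal(0, 1, 30)
        r, p = partial_correlation(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert r == pytest.approx(expected, rel=1e-9)

    def test_uncorrelated_covariate_approximates_marginal(self, rng):
        x = rng.normal(0, 1, 500)
        y = 0.7 * x + rng.normal(0, 0.5, 500)
        z = rng.normal(0, 1, 500)
        r_marg = np.corrcoef(x, y)[0, 1]
        r_part, _ = partial_correlation(x, y, z)
        assert r_part == pytest.approx(r_marg, abs=0.02)

    def test_collinear_with_covariate_degenerates_to_zero(self, rng):
        z = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        r, p = partial_correlation(z, y, z)
        assert r == 0.0
        assert p == 1.0

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(0, 1, 25)
        z = rng.normal(0, 1, 25)
        y = 0.4 * x + 0.6 * z + rng.normal(0, 1, 25)
        r, p = partial_correlation(x, y, z)
        ref = pingouin.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)


class TestBlandAltman:
    def test_constant_offset(self, rng):
        c = rng.uniform(400, 900, 19)
        bias, loa, prop_r, prop_p = bland_altman_modified(c, c + 50)
        assert bias == pytest.approx(50.0, rel=1e-12)
        assert prop_r == pytest.approx(0.0, abs=1e-9)

    def test_proportional_device_gives_prop_r_minus_one(self):
        c = np.array([400.0, 550, 700, 850, 1000])
        _, _, prop_r, _ = bland_altman_modified(c, 0.8 * c)
        assert prop_r == pytest.approx(-1.0, rel=1e-12)

    def test_matches_brute_force_formulas(self, rng):
        c = rng.uniform(400, 900, 19)
        d = 0.9 * c + rng.normal(0, 40, 19)
        bias, (lo, hi), prop_r, _ = bland_altman_modified(c, d)
        diff = d - c
        assert bias == pytest.approx(diff.mean(), rel=1e-12)
        assert lo == pytest.approx(diff.mean() - 1.96 * diff.std(ddof=1), rel=1e-12)
        assert hi == pytest.approx(diff.mean() + 1.96 * diff.std(ddof=1), rel=1e-12)
        assert prop_r == pytest.approx(np.corrcoef(c, diff)[0, 1], rel=1e-9)

    @given(a=st.sampled_from([0.6, 0.8, 1.0, 1.3, 1.7]), b=st.floats(-100, 100))
    @settings(derandomize=True, max_examples=25)
    def test_prop_r_sign_tracks_slope(self, a, b):
        c = np.array([400.0, 550, 700, 850, 1000])
        _, _, prop_r, _ = bland_altman_modified(c, a * c + b)
        if a == 1.0:
            assert prop_r == pytest.approx(0.0, abs=1e-9)
        else:
            assert np.sign(prop_r) == np.sign(a - 1.0)


class TestValidationTable:
    def _study(self, rng, device_fn, n=19):
        c = rng.uniform(450, 950, n)
        w = rng.uniform(45, 80, n)
        return [
            PairedSample(
                participant_id=f"P{i:02d}",
                criterion_paee=c[i],
                device_paee=device_fn(c[i], i),
                weight_kg=w[i],
            )
            for i in range(n)
        ]

    def test_perfect_devices_show_no_differences(self, rng):
        study = self._study(rng, lambda c, i: {"a": c, "b": c})
        res = build_validation_table(study, seed=11)
        paee = [r for r in res if r.measure == "paee"]
        assert len(paee) == 2
        for r in paee:
            assert not r.significant
            assert r.mape_mean_pct == pytest.approx(0.0, abs=1e-9)
            assert abs(r.ba_prop_r) < 1e-6

    def test_injected_proportional_error_is_detected(self, rng):
        study = self._study(
            rng,
            lambda c, i: {"biased": 0.7 * c, "fine": c},
        )
        res = build_validation_table(study, seed=13, paired=True)
        by_id = {(r.device_id, r.measure): r for r in res}
        biased = by_id[("biased", "paee")]
        fine = by_id[("fine", "paee")]
        assert biased.significant and biased.mean_diff < 0
        assert biased.ba_prop_r < -0.9
        assert not fine.significant

    def test_row_count_covers_devices_and_measures(self, rng):
        study = self._study(rng, lambda c, i: {"a": c * 1.01, "b": c * 0.99})
        res = build_validation_table(study, seed=3)
        # weights present: paee + paee_per_wt for each device
        assert len(res) == 4

    def test_model_interface_and_summary(self, rng):
        study = self._study(rng, lambda c, i: {"a": 0.8 * c})
        res = DeviceValidation(study, paired=True).fit(seed=21)
        df = res.to_frame()
        assert set(df["device_id"]) == {"a"}
        assert "Dunnett" in res.summary()
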