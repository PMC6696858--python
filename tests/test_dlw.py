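"""Doubly-labeled-water kinetics: fits, pools, CO2 production, TEE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paee.constants import DLWConstants
from paee.dlw import (
    DLWModel,
    DoseRecord,
    EliminationFit,
    InsufficientDataError,
    IsotopeSeries,
    NonPositiveExcessError,
    fit_elimination,
    isotope_pools,
    pool_size,
    rco2_rate,
    run_dlw,
    tee_from_rco2,
)
from paee.isotopes import Isotope, water_mole_fraction_to_delta
from paee.simulate import SimConfig, simulate_cohort, simulate_dlw_samples

SAMPLING = np.array([0.0, 1, 2, 3, 8, 9, 13, 14, 15])


def _series_from_excess(excess, iso=Isotope.O18, days=SAMPLING):
    """Build a delta-per-mil series from per-water mole-fraction excess."""
    base = {"H2": 2 * 155.76e-6 / (1 + 155.76e-6),
            "O18": 2005.2e-6 / (1 + 2005.2e-6)}[Isotope(iso).value]
    delta = water_mole_fraction_to_delta(base + np.asarray(excess), iso)
    return IsotopeSeries(
        participant_id="T",
        isotope=iso,
        elapsed_days=days,
        enrichment=delta,
        is_baseline=days == 0,
        units="delta_permil",
        dose=DoseRecord(84.0, 10.0, 60.0),
    )


class TestFitElimination:
    def test_exact_exponential_recovered_to_machine_precision(self):
        k, e0 = 0.11, 1.2e-4
        excess = np.where(SAMPLING == 0, 0.0, e0 * np.exp(-k * SAMPLING))
        fit = fit_elimination(_series_from_excess(excess))
        assert fit.k == pytest.approx(k, rel=1e-10)
        assert fit.intercept_excess == pytest.approx(e0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points == 8

    def test_noisy_fit_matches_closed_form_ols(self, rng):
        k, e0 = 0.09, 2.0e-4
        t = SAMPLING[1:]
        noise = np.exp(rng.normal(0, 0.01, t.size))
        excess = np.concatenate([[0.0], e0 * np.exp(-k * t) * noise])
        fit = fit_elimination(_series_from_excess(excess))
        # independent oracle: OLS normal equations on ln(excess)
        y = np.log(excess[1:])
        tb, yb = t.mean(), y.mean()
        slope = np.sum((t - tb) * (y - yb)) / np.sum((t - tb) ** 2)
        intercept = yb - slope * tb
        assert fit.k == pytest.approx(-slope, rel=1e-9)
        assert fit.intercept_excess == pytest.approx(np.exp(intercept), rel=1e-9)

    def test_two_points_insufficient(self):
        days = np.array([0.0, 1, 2])
        excess = np.array([0.0, 1e-4, 0.9e-4])
        with pytest.raises(InsufficientDataError):
            fit_elimination(_series_from_excess(excess, days=days))

    def test_enrichment_below_baseline_names_sample(self):
        excess = np.where(SAMPLING == 0, 0.0, 1e-4 * np.exp(-0.1 * SAMPLING))
        excess[-1] = -1e-6
        with pytest.raises(NonPositiveExcessError, match="day 15"):
            fit_elimination(_series_from_excess(excess))

    def test_k_confidence_interval_covers_k(self):
        excess = np.where(SAMPLING == 0, 0.0, 1e-4 * np.exp(-0.1 * SAMPLING))
        fit = fit_elimination(_series_from_excess(excess))
        lo, hi = fit.k_confint()
        assert lo <= fit.k <= hi


class TestPools:
    def test_pool_size_is_dose_over_intercept(self):
        fit = EliminationFit(Isotope.O18, 0.1, 4.0e-4, 1.0, 0.0, 8)
        dose = DoseRecord(84.0, 10.0, 60.0)
        n = pool_size(fit, dose)
        assert n == pytest.approx(dose.excess_mol(Isotope.O18) / 4.0e-4, rel=1e-12)

    def test_pool_size_linear_in_dose(self):
        fit = EliminationFit(Isotope.O18, 0.1, 4.0e-4, 1.0, 0.0, 8)
        n1 = pool_size(fit, DoseRecord(84.0, 10.0, 60.0))
        n2 = pool_size(fit, DoseRecord(168.0, 10.0, 60.0))
        assert n2 == pytest.approx(2 * n1, rel=1e-9)

    def test_pool_size_rejects_nonpositive_intercept(self):
        fit = EliminationFit(Isotope.O18, 0.1, 0.0, 1.0, 0.0, 8)
        with pytest.raises(ValueError):
            pool_size(fit, DoseRecord(84.0, 10.0, 60.0))

    def test_tbw_constants_cancel(self):
        x = 2100.0
        pools = isotope_pools(1.041 * x, 1.007 * x)
        assert pools.TBW == pytest.approx(x, rel=1e-12)
        assert pools.ratio == pytest.approx(1.041 / 1.007, rel=1e-12)
        assert not pools.qc_flags

    def test_tbw_direct_arithmetic(self):
        pools = isotope_pools(40.0, 39.0)
        assert pools.TBW == pytest.approx((38.4246 + 38.7289) / 2, abs=5e-5)
        assert pools.ratio == pytest.approx(40 / 39, rel=1e-12)
        assert not pools.qc_flags

    def test_ratio_qc_flag_outside_window(self):
        pools = isotope_pools(40.0, 40.0)
        assert pools.ratio == 1.0
        assert "dilution-space ratio out of range" in pools.qc_flags


class TestRates:
    def test_rco2_zero_when_bracket_vanishes(self):
        kd = 0.1
        ko = kd * 1.041 / 1.007
        mol, L, flags = rco2_rate(2000.0, kd, ko)
        assert mol == pytest.approx(0.0, abs=1e-12)
        assert "non-positive rCO2" in flags

    def test_rco2_direct_arithmetic(self):
        mol, L, flags = rco2_rate(2000.0, 0.10, 0.12)
        assert mol == pytest.approx(0.4554 * 2000 * (0.12084 - 0.10410), rel=1e-12)
        assert mol == pytest.approx(15.2468, abs=1e-3)
        assert L == pytest.approx(mol * 22.414, rel=1e-12)
        assert not flags

    @given(scale=st.floats(0.1, 10))
    @settings(derandomize=True, max_examples=25)
    def test_rco2_homogeneous_in_tbw(self, scale):
        base, _, _ = rco2_rate(1500.0, 0.09, 0.11)
        scaled, _, _ = rco2_rate(1500.0 * scale, 0.09, 0.11)
        assert scaled == pytest.approx(scale * base, rel=1e-12)

    def test_tee_collapses_at_fq_one(self):
        assert tee_from_rco2(100.0, 1.0) == pytest.approx(500.0, rel=1e-12)

    def test_tee_direct_arithmetic(self):
        tee = tee_from_rco2(450.0, 0.85)
        assert tee == pytest.approx(495.0 + 3.9 * 450.0 / 0.85, rel=1e-12)
        assert tee == pytest.approx(2559.71, abs=0.01)

    def test_tee_zero_at_zero_rco2(self):
        assert tee_from_rco2(0.0, 0.85) == 0.0

    @given(scale=st.floats(0.1, 10))
    @settings(derandomize=True, max_examples=25)
    def test_tee_homogeneous_in_rco2(self, scale):
        assert tee_from_rco2(300.0 * scale, 0.85) == pytest.approx(
            scale * tee_from_rco2(300.0, 0.85), rel=1e-12
        )

    def test_fq_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="FQ"):
            tee_from_rco2(300.0, 0.5)


class TestRunDLW:
    def _simulated(self, noise=0.0, seed=3):
        cfg = SimConfig(seed=seed, enrichment_noise_sd=noise)
        rng = np.random.default_rng(seed)
        p = simulate_cohort(cfg, rng)[0]
        s_d, s_o, truth = simulate_dlw_samples(p, cfg, rng)
        return p, s_d, s_o, truth, cfg

    def test_noiseless_round_trip_within_half_percent(self):
        p, s_d, s_o, truth, cfg = self._simulated()
        result, summary = run_dlw(s_d, s_o, cfg.fq, p.true_bmr_kcal_day)
        assert result.tee_kcal_day == pytest.approx(
            truth["tee_kcal_day"], rel=0.005
        )
        assert result.kd == pytest.approx(truth["kd"], rel=1e-8)
        assert result.ko == pytest.approx(truth["ko"], rel=1e-8)
        assert result.pools.ratio == pytest.approx(truth["ratio"], rel=1e-8)

    def test_paee_zero_when_bmr_is_ninety_pct_tee(self):
        p, s_d, s_o, truth, cfg = self._simulated()
        result, summary = run_dlw(s_d, s_o, cfg.fq, 0.9 * truth["tee_kcal_day"])
        assert summary.paee_kcal_day == pytest.approx(0.0, abs=1e-9)

    def test_pal_is_tee_over_bmr(self):
        p, s_d, s_o, truth, cfg = self._simulated()
        bmr = 1300.0
        result, summary = run_dlw(s_d, s_o, cfg.fq, bmr)
        assert summary.pal == pytest.approx(result.tee_kcal_day / bmr, rel=1e-12)

    def test_model_results_interface(self):
        p, s_d, s_o, truth, cfg = self._simulated()
        res = DLWModel(s_d, s_o, cfg.fq, p.true_bmr_kcal_day,
                       weight_kg=p.weight_kg).fit()
        assert res.tee_kcal_day > 0
        txt = res.summary()
        assert "kd" in txt and "TEE" in txt and p.id in txt

    def test_swapped_isotopes_rejected(self):
        p, s_d, s_o, truth, cfg = self._simulated()
        with pytest.raises(ValueError):
            run_dlw(s_o, s_d, cfg.fq, 1400.0)
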