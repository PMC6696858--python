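"""Doubly-labeled-water kinetics: isotope washout fits to TEE.

The DLW method doses a participant with 2H2O and H2-18O and follows the
urinary enrichment of both tracers over ~two weeks.  Deuterium leaves the
body only as water, oxygen-18 as both water and CO2, so the difference of
the two first-order elimination rates measures CO2 production.  The
pipeline is:

1. ``fit_elimination`` — OLS on ln(excess enrichment) vs elapsed days
   gives the elimination rate k (negative slope) and the zero-time
   intercept for each isotope.
2. ``pool_size`` — the intercept dilutes the known tracer dose into the
   isotope dilution space N (mol water).
3. ``isotope_pools`` — Nd/No is a quality-control statistic; total body
   water is the mean of the two fractionation-corrected spaces.
4. ``rco2_rate`` — rCO2 = 0.4554 * TBW * (1.007 ko - 1.041 kd), assuming
   isotope fractionation only in breath water.
5. ``tee_from_rco2`` — a food-quotient Weir equation,
   TEE = 1.1 rCO2 + 3.9 rCO2 / FQ, with rCO2 in L/day.

``DLWModel``/``DLWResults`` wrap the chain in a fit/results interface;
the stage functions remain importable for piecewise use and testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import DLWConstants
from .energy import EnergySummary, energy_summary
from .isotopes import Isotope, dose_excess_mol, to_water_mole_fraction


class InsufficientDataError(ValueError):
    """Raised when a washout series has too few usable samples."""


class NonPositiveExcessError(ValueError):
    """Raised when a post-dose enrichment does not exceed baseline."""


@dataclass
class DoseRecord:
    """One tracer dose: mass, isotopic purity and dosing body weight."""

    dose_mass_g: float
    atom_percent: float
    participant_weight_kg: float

    def excess_mol(self, isotope: Isotope) -> float:
        return dose_excess_mol(self.dose_mass_g, self.atom_percent, isotope)


@dataclass
class IsotopeSeries:
    """Urine enrichment time series for one participant and isotope.

    ``elapsed_days`` counts from dose administration; baseline samples
    (pre-dose) carry ``is_baseline=True``.  Enrichments may be recorded
    as delta per-mil vs VSMOW or ppm atom-fraction excess; they are
    normalized to tracer-per-water mole fraction on access.
    """

    participant_id: str
    isotope: Isotope
    elapsed_days: np.ndarray
    enrichment: np.ndarray
    is_baseline: np.ndarray
    units: str = "delta_permil"
    dose: DoseRecord | None = None

    def __post_init__(self):
        self.elapsed_days = np.asarray(self.elapsed_days, dtype=float)
        self.enrichment = np.asarray(self.enrichment, dtype=float)
        self.is_baseline = np.asarray(self.is_baseline, dtype=bool)
        self.isotope = Isotope(self.isotope)
        if not np.any(self.is_baseline):
            raise ValueError(
                f"{self.participant_id}/{self.isotope.value}: no baseline sample"
            )
        post = self.elapsed_days[~self.is_baseline]
        if np.any(np.diff(post) <= 0):
            raise ValueError("post-dose elapsed_days must be strictly increasing")

    @property
    def mole_fraction(self) -> np.ndarray:
        return to_water_mole_fraction(self.enrichment, self.units, self.isotope)

    def baseline_mole_fraction(self) -> float:
        """Mean baseline enrichment (single baseline sample allowed)."""
        return float(np.mean(self.mole_fraction[self.is_baseline]))

    def excess(self) -> tuple[np.ndarray, np.ndarray]:
        """Post-dose (elapsed_days, mole-fraction excess over baseline)."""
        base = self.baseline_mole_fraction()
        mask = ~self.is_baseline
        return self.elapsed_days[mask], self.mole_fraction[mask] - base


@dataclass
class EliminationFit:
    """First-order washout fit for one isotope."""

    isotope: Isotope
    k: float                      # per day
    intercept_excess: float       # zero-time mole-fraction excess
    r_squared: float
    se_k: float
    n_points: int

    def k_confint(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided CI on the elimination rate from OLS theory."""
        tcrit = stats.t.ppf(1 - alpha / 2, self.n_points - 2)
        return self.k - tcrit * self.se_k, self.k + tcrit * self.se_k


@dataclass
class IsotopePools:
    """Isotope dilution spaces and derived total body water (mol)."""

    Nd: float
    No: float
    ratio: float
    TBW: float
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class DLWResult:
    """Full kinetic output for one participant."""

    participant_id: str
    kd: float
    ko: float
    fit_d: EliminationFit
    fit_o: EliminationFit
    pools: IsotopePools
    rco2_mol_day: float
    rco2_L_day: float
    fq: float
    tee_kcal_day: float
    qc_flags: list[str] = field(default_factory=list)


def fit_elimination(series: IsotopeSeries) -> EliminationFit:
    """Fit ln(excess enrichment) = ln(E0) - k*t by ordinary least squares.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 post-dose samples above baseline.
    NonPositiveExcessError
        Any post-dose enrichment at or below the baseline mean, naming
        the offending sample day.
    """
    t, excess = series.excess()
    if len(t) < 3:
        raise InsufficientDataError(
            f"{series.participant_id}/{series.isotope.value}: "
            f"{len(t)} post-dose samples, need >= 3"
        )
    bad = np.nonzero(excess <= 0)[0]
    if bad.size:
        raise NonPositiveExcessError(
            f"{series.participant_id}/{series.isotope.value}: enrichment at "
            f"day {t[bad[0]]:g} does not exceed baseline"
        )
    res = stats.linregress(t, np.log(excess))
    return EliminationFit(
        isotope=series.isotope,
        k=-res.slope,
        intercept_excess=math.exp(res.intercept),
        r_squared=res.rvalue**2,
        se_k=res.stderr,
        n_points=len(t),
    )


def pool_size(fit: EliminationFit, dose: DoseRecord) -> float:
    """Dilution space N (mol water) by the intercept dose-dilution method.

    N = excess tracer moles in the dose / zero-time mole-fraction excess.
    """
    if fit.intercept_excess <= 0:
        raise ValueError("non-positive zero-time intercept")
    return dose.excess_mol(fit.isotope) / fit.intercept_excess


def isotope_pools(
    Nd: float,
    No: float,
    constants: DLWConstants = DLWConstants(),
) -> IsotopePools:
    """Combine dilution spaces into TBW with a ratio QC check.

    TBW = mean(Nd / 1.041, No / 1.007).  The Nd/No ratio is expected a
    few percent above 1; values outside the configured window raise a QC
    flag (never an error).
    """
    if Nd <= 0 or No <= 0:
        raise ValueError("dilution spaces must be positive")
    ratio = Nd / No
    tbw = 0.5 * (Nd / constants.tbw_div_d + No / constants.tbw_div_o)
    flags = []
    if not constants.ratio_qc_lo < ratio < constants.ratio_qc_hi:
        flags.append("dilution-space ratio out of range")
    return IsotopePools(Nd=Nd, No=No, ratio=ratio, TBW=tbw, qc_flags=flags)


def rco2_rate(
    tbw_mol: float,
    kd: float,
    ko: float,
    constants: DLWConstants = DLWConstants(),
) -> tuple[float, float, list[str]]:
    """CO2 production from TBW and the two elimination rates.

    Returns (rCO2 mol/day, rCO2 L/day, qc_flags).  A non-positive rate —
    possible when ko barely exceeds kd — is flagged, not raised.
    """
    if tbw_mol <= 0:
        raise ValueError("TBW must be positive")
    rco2_mol = constants.rco2_coef * tbw_mol * (
        constants.frac_o * ko - constants.frac_d * kd
    )
    flags = ["non-positive rCO2"] if rco2_mol <= 0 else []
    return rco2_mol, rco2_mol * constants.molar_volume_L, flags


def tee_from_rco2(
    rco2_L_day: float,
    fq: float,
    constants: DLWConstants = DLWConstants(),
) -> float:
    """Food-quotient Weir equation: TEE = 1.1 rCO2 + 3.9 rCO2/FQ (kcal/day)."""
    if not 0.7 <= fq <= 1.0:
        raise ValueError(f"FQ={fq} outside physiologic range [0.7, 1.0]")
    if rco2_L_day < 0:
        raise ValueError("rCO2 must be non-negative")
    return constants.weir_co2_coef * rco2_L_day + constants.weir_fq_coef * rco2_L_day / fq


def run_dlw(
    series_d: IsotopeSeries,
    series_o: IsotopeSeries,
    fq: float,
    bmr_kcal_day: float,
    constants: DLWConstants = DLWConstants(),
    weight_kg: float | None = None,
) -> tuple[DLWResult, EnergySummary]:
    """Full DLW chain for one participant.

    ``bmr_kcal_day`` is the chamber-measured BMR used to split TEE into
    components; PAEE = TEE - BMR - 0.1*TEE and PAL = TEE/BMR.
    """
    if series_d.isotope is not Isotope.H2 or series_o.isotope is not Isotope.O18:
        raise ValueError("expected (H2 series, O18 series)")
    if series_d.dose is None or series_o.dose is None:
        raise ValueError("both series need dose records")

    fit_d = fit_elimination(series_d)
    fit_o = fit_elimination(series_o)
    Nd = pool_size(fit_d, series_d.dose)
    No = pool_size(fit_o, series_o.dose)
    pools = isotope_pools(Nd, No, constants)
    rco2_mol, rco2_L, rco2_flags = rco2_rate(pools.TBW, fit_d.k, fit_o.k, constants)
    tee = tee_from_rco2(max(rco2_L, 0.0), fq, constants)

    flags = pools.qc_flags + rco2_flags
    result = DLWResult(
        participant_id=series_d.participant_id,
        kd=fit_d.k,
        ko=fit_o.k,
        fit_d=fit_d,
        fit_o=fit_o,
        pools=pools,
        rco2_mol_day=rco2_mol,
        rco2_L_day=rco2_L,
        fq=fq,
        tee_kcal_day=tee,
        qc_flags=flags,
    )
    summary = energy_summary(
        "dlw", tee, bmr_kcal_day, weight_kg=weight_kg
    )
    summary.flags.extend(flags)
    return result, summary


class DLWModel:
    """Model object for one participant's DLW study.

    Parameters
    ----------
    series_d, series_o : IsotopeSeries
        Deuterium and oxygen-18 washout series with dose records.
    fq : float
        Food quotient from dietary assessment (CO2/O2 of the diet).
    bmr_kcal_day : float
        Criterion basal metabolic rate (chamber-measured).
    """

    def __init__(
        self,
        series_d: IsotopeSeries,
        series_o: IsotopeSeries,
        fq: float,
        bmr_kcal_day: float,
        weight_kg: float | None = None,
        constants: DLWConstants = DLWConstants(),
    ):
        self.series_d = series_d
        self.series_o = series_o
        self.fq = fq
        self.bmr_kcal_day = bmr_kcal_day
        self.weight_kg = weight_kg
        self.constants = constants

    def fit(self) -> "DLWResults":
        result, summary = run_dlw(
            self.series_d,
            self.series_o,
            self.fq,
            self.bmr_kcal_day,
            self.constants,
            self.weight_kg,
        )
        return DLWResults(self, result, summary)


class DLWResults:
    """Fitted DLW kinetics with energy components and QC flags."""

    def __init__(self, model: DLWModel, result: DLWResult, energy: EnergySummary):
        self.model = model
        self.kinetics = result
        self.energy = energy

    @property
    def tee_kcal_day(self) -> float:
        return self.kinetics.tee_kcal_day

    @property
    def paee_kcal_day(self) -> float:
        return self.energy.paee_kcal_day

    @property
    def pal(self) -> float:
        return self.energy.pal

    def summary(self) -> str:
        k = self.kinetics
        lo_d, hi_d = k.fit_d.k_confint()
        lo_o, hi_o = k.fit_o.k_confint()
        lines = [
            f"DLW results — participant {k.participant_id}",
            f"  kd = {k.kd:.5f} /day  (95% CI {lo_d:.5f}–{hi_d:.5f}, "
            f"R²={k.fit_d.r_squared:.4f})",
            f"  ko = {k.ko:.5f} /day  (95% CI {lo_o:.5f}–{hi_o:.5f}, "
            f"R²={k.fit_o.r_squared:.4f})",
            f"  Nd = {k.pools.Nd:.1f} mol   No = {k.pools.No:.1f} mol   "
            f"Nd/No = {k.pools.ratio:.4f}",
            f"  TBW = {k.pools.TBW:.1f} mol ({k.pools.TBW * 18.0153 / 1000:.1f} kg)",
            f"  rCO2 = {k.rco2_L_day:.1f} L/day   FQ = {k.fq:.2f}",
            f"  TEE = {k.tee_kcal_day:.1f} kcal/day   "
            f"PAEE = {self.energy.paee_kcal_day:.1f} kcal/day   "
            f"PAL = {self.energy.pal:.2f}",
        ]
        if k.qc_flags:
            lines.append("  QC: " + "; ".join(k.qc_flags))
        return "\n".join(lines)
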