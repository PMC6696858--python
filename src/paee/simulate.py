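"""Seeded synthetic studies with known ground truth.

Generates everything the pipeline consumes: a cohort of healthy adults
(normal-range BMI, ages 21-50), isotope washout curves consistent with
the DLW dosing scheme (0.06 g/kg 2H2O at 99.8 atom%, 1.4 g/kg H2-18O at
10 atom%, urine on days 1, 2, 3, 8, 9, 13, 14, 15), a standardized-day
chamber gas trace driven by a MET timetable, and per-device daily
outputs with configurable multiplicative/additive bias, noise and
non-wear patterns.

Truth is defined at the TEE level and propagated downward: the free-
living criterion PAEE follows 0.9*TEE - BMR, the chamber trace is
anchored to the participant's BMR so the supine window extrapolates
exactly, and device outputs are biased transformations of the same
truth.  Every quantity needed to score recovery is returned alongside
the generated data and written to ``truth.json`` by
:func:`simulate_study`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chamber import DAY_START_MIN, ProtocolEntry, clock_to_offset_min
from .constants import DLWConstants, WeirConstants, MET_VO2_ML_KG_MIN
from .devices import ActivityLogEntry, DeviceDay, DeviceProfile
from .dlw import DoseRecord, IsotopeSeries
from .isotopes import (
    Isotope,
    dose_excess_mol,
    to_water_mole_fraction,
    water_mole_fraction_to_delta,
)

#: urine collection schedule, days after dosing (0 = pre-dose baseline)
DEFAULT_SAMPLING_DAYS = (0, 1, 2, 3, 8, 9, 13, 14, 15)


@dataclass
class DeviceBias:
    """Error model and reduction metadata for one simulated device."""

    mult: float = 1.0            # multiplicative bias on the reported quantity
    add: float = 0.0             # additive bias, kcal/day
    noise_sd: float = 0.0        # daily Gaussian noise, kcal/day
    provides: str = "TEE"        # TEE or PAEE
    dit_included_in_tee: bool = False
    bmr_source: str = "app_value"
    placement: str = "wrist"
    bmr_mult: float = 1.0        # bias of the device's own BMR estimate
    bmr_noise_sd: float = 0.0


def default_device_biases() -> dict[str, DeviceBias]:
    """Four archetype devices spanning the reduction rules.

    An unbiased TEE tracker, a 30%-underestimating TEE tracker, a
    tracker whose stationary-day TEE folds in DIT, and a research unit
    that reports PAEE directly.
    """
    return {
        "tracker_unbiased": DeviceBias(mult=1.0, noise_sd=25.0, placement="wrist"),
        "tracker_under30": DeviceBias(mult=0.7, noise_sd=25.0, placement="waist"),
        "tracker_dit_inlined": DeviceBias(
            mult=1.0,
            noise_sd=25.0,
            placement="pocket",
            dit_included_in_tee=True,
            bmr_source="stationary_day_tee",
        ),
        "research_paee_only": DeviceBias(
            mult=1.0, noise_sd=20.0, provides="PAEE", placement="waist"
        ),
    }


@dataclass
class SimConfig:
    """Study-generator configuration; the defaults are the study design."""

    n_participants: int = 19
    seed: int = 0
    n_days: int = 15
    sampling_days: tuple = DEFAULT_SAMPLING_DAYS
    # free-living energy metabolism
    pal_mean: float = 1.73
    pal_sd: float = 0.21
    pal_min: float = 1.1
    fq: float = 0.85
    # basal metabolism, linear in fat-free mass (kcal/day)
    bmr_intercept: float = 370.0
    bmr_slope_ffm: float = 21.6
    # DLW kinetics
    kd_mean: float = 0.09        # deuterium elimination, per day
    kd_sd: float = 0.008
    ratio_mean: float = 1.036    # dilution-space ratio Nd/No
    ratio_sd: float = 0.008
    ratio_bounds: tuple = (1.021, 1.056)
    enrichment_noise_sd: float = 0.01   # multiplicative log-normal, ~IRMS 1%
    #: correlation of the log-noise between the two isotopes of one urine
    #: sample; biological water-pool fluctuation and aliquot handling are
    #: shared across tracers, analytic error is isotope-specific
    enrichment_noise_corr: float = 0.8
    dose_d2o_g_per_kg: float = 0.06
    dose_d2o_atom_pct: float = 99.8
    dose_h218o_g_per_kg: float = 1.4
    dose_h218o_atom_pct: float = 10.0
    # chamber
    chamber_rer: float = 0.85
    chamber_flow_L_min: float = 250.0
    # devices and wear behaviour
    device_bias: dict[str, DeviceBias] = field(default_factory=default_device_biases)
    day_tee_cv: float = 0.07             # day-to-day variation of true TEE
    nonwear_mean_min: float = 42.0
    nonwear_sd_min: float = 13.0
    nonwear_met: float = 1.8             # mostly bathing/showering
    sleep_mean_h: float = 7.5
    sleep_sd_h: float = 0.8
    invalid_day_prob: float = 0.007
    dlw_constants: DLWConstants = field(default_factory=DLWConstants)
    weir: WeirConstants = field(default_factory=WeirConstants)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.device_bias = {
            k: (v if isinstance(v, DeviceBias) else DeviceBias(**v))
            for k, v in self.device_bias.items()
        }

    def profiles(self) -> list[DeviceProfile]:
        return [
            DeviceProfile(
                device_id=dev,
                placement=b.placement,
                provides=b.provides,
                dit_included_in_tee=b.dit_included_in_tee,
                bmr_source=b.bmr_source,
            )
            for dev, b in self.device_bias.items()
        ]


@dataclass
class Participant:
    """Ground-truth participant state."""

    id: str
    sex: str
    age_y: float
    height_cm: float
    weight_kg: float
    body_fat_pct: float
    true_bmr_kcal_day: float
    true_tee_kcal_day: float
    true_pal: float

    @property
    def ffm_kg(self) -> float:
        return self.weight_kg * (1.0 - self.body_fat_pct / 100.0)

    @property
    def tbw_mol(self) -> float:
        # hydration of fat-free mass ~73.2%
        return self.ffm_kg * 0.732 * 1000.0 / 18.0153


def _trunc_normal(rng, mean, sd, lo=-np.inf, hi=np.inf, size=None):
    """Rejection-sampled truncated normal (cheap at these scales)."""
    if sd == 0:
        return np.full(size, mean) if size is not None else float(mean)
    shape = size if size is not None else ()
    out = rng.normal(mean, sd, shape)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, shape), out)
        bad = (out < lo) | (out > hi)
    return out if size is not None else float(out)


def simulate_cohort(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[Participant]:
    """Draw a cohort of healthy adults with known energy truth.

    Anthropometrics follow sex-specific normal distributions with BMI
    truncated to the normal range; BMR is linear in fat-free mass; PAL
    is normal truncated above ``pal_min`` and defines true TEE.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    cohort = []
    for i in range(cfg.n_participants):
        sex = "M" if i % 2 == 0 else "F"
        age = float(rng.uniform(21, 50))
        if sex == "M":
            height = _trunc_normal(rng, 171.0, 6.0, 155, 190)
            bf = _trunc_normal(rng, 22.0, 3.5, 14.8, 32.2)
        else:
            height = _trunc_normal(rng, 158.0, 6.0, 145, 175)
            bf = _trunc_normal(rng, 30.0, 3.5, 14.8, 32.2)
        bmi = _trunc_normal(rng, 21.5, 1.6, 18.5, 25.0)
        weight = bmi * (height / 100.0) ** 2
        ffm = weight * (1.0 - bf / 100.0)
        bmr = cfg.bmr_intercept + cfg.bmr_slope_ffm * ffm
        pal = _trunc_normal(rng, cfg.pal_mean, cfg.pal_sd, lo=cfg.pal_min)
        cohort.append(
            Participant(
                id=f"P{i + 1:02d}",
                sex=sex,
                age_y=age,
                height_cm=height,
                weight_kg=weight,
                body_fat_pct=bf,
                true_bmr_kcal_day=bmr,
                true_tee_kcal_day=pal * bmr,
                true_pal=pal,
            )
        )
    return cohort


def simulate_dlw_samples(
    p: Participant,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[IsotopeSeries, IsotopeSeries, dict]:
    """Isotope washout series for one participant, plus kinetic truth.

    The target CO2 production is found by inverting the FQ-Weir
    equation from true TEE; dilution spaces are placed around the
    participant's body water with a ratio drawn inside the acceptable
    window; kd comes from a water-turnover distribution and ko is set so
    the CO2 equation reproduces the target exactly.  Enrichments are
    exact exponentials in tracer-per-water mole fraction with optional
    multiplicative log-normal noise on the excess, reported as delta
    per-mil.
    """
    c = cfg.dlw_constants
    rco2_L = p.true_tee_kcal_day / (c.weir_co2_coef + c.weir_fq_coef / cfg.fq)
    rco2_mol = rco2_L / c.molar_volume_L
    tbw = p.tbw_mol
    ratio = _trunc_normal(rng, cfg.ratio_mean, cfg.ratio_sd, *cfg.ratio_bounds)
    # TBW = (Nd/1.041 + No/1.007)/2 with Nd = ratio*No
    No = 2.0 * tbw / (ratio / c.tbw_div_d + 1.0 / c.tbw_div_o)
    Nd = ratio * No
    kd = _trunc_normal(rng, cfg.kd_mean, cfg.kd_sd, lo=0.03)
    ko = (rco2_mol / (c.rco2_coef * tbw) + c.frac_d * kd) / c.frac_o
    if ko <= kd:
        raise ValueError("infeasible kinetics: ko <= kd for configured turnover")

    dose_d = DoseRecord(
        cfg.dose_d2o_g_per_kg * p.weight_kg, cfg.dose_d2o_atom_pct, p.weight_kg
    )
    dose_o = DoseRecord(
        cfg.dose_h218o_g_per_kg * p.weight_kg, cfg.dose_h218o_atom_pct, p.weight_kg
    )

    days = np.asarray(cfg.sampling_days, dtype=float)
    shared = rng.standard_normal(days.size)
    series = {}
    for iso, dose, N, k in (
        (Isotope.H2, dose_d, Nd, kd),
        (Isotope.O18, dose_o, No, ko),
    ):
        baseline_mf = to_water_mole_fraction(0.0, "delta_permil", iso)
        e0 = dose_excess_mol(dose.dose_mass_g, dose.atom_percent, iso) / N
        excess = np.where(days == 0, 0.0, e0 * np.exp(-k * days))
        if cfg.enrichment_noise_sd > 0:
            rho = cfg.enrichment_noise_corr
            z = rho * shared + np.sqrt(1 - rho**2) * rng.standard_normal(days.size)
            noise = np.exp(cfg.enrichment_noise_sd * z)
            excess = excess * np.where(days == 0, 1.0, noise)
        delta = water_mole_fraction_to_delta(baseline_mf + excess, iso)
        series[iso] = IsotopeSeries(
            participant_id=p.id,
            isotope=iso,
            elapsed_days=days,
            enrichment=delta,
            is_baseline=days == 0,
            units="delta_permil",
            dose=dose,
        )

    truth = {
        "participant_id": p.id,
        "kd": kd,
        "ko": ko,
        "Nd": Nd,
        "No": No,
        "ratio": ratio,
        "tbw_mol": tbw,
        "rco2_L_day": rco2_L,
        "tee_kcal_day": p.true_tee_kcal_day,
    }
    return series[Isotope.H2], series[Isotope.O18], truth


def simulate_chamber_trace(
    p: Participant,
    timetable: list[ProtocolEntry],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
):
    """Minute-level chamber gas trace driven by a MET timetable.

    Minute VO2 is MET * resting VO2, with resting VO2 anchored so the
    Weir EE of a 1-MET minute equals true BMR / 1440 (hence the supine
    window extrapolates to the participant's BMR exactly).  VCO2 is
    RER * VO2.  Outlet concentrations are back-computed at fixed outlet
    flow with a consistent nitrogen balance, so Haldane-corrected gas
    exchange inverts the construction exactly.

    Returns (ChamberTrace, true minute EE kcal/min, true TEE kcal/day).
    """
    from .chamber import ChamberTrace  # local import to avoid cycle at module load

    minutes = np.arange(1440.0)
    mets = np.empty(1440)
    mets.fill(np.nan)
    for e in timetable:
        s = clock_to_offset_min(e.start)
        dur = int(round(e.duration_h() * 60))
        idx = (np.arange(s, s + dur)) % 1440
        mets[idx.astype(int)] = e.met
    if np.any(np.isnan(mets)):
        raise ValueError("timetable does not cover the 24-h chamber day")

    w = cfg.weir
    rer = cfg.chamber_rer
    # resting VO2 (L/min) such that weir_ee(vo2, rer*vo2) == BMR/1440
    vo2_rest = (p.true_bmr_kcal_day / 1440.0) / (w.o2_coef + w.co2_coef * rer)
    vo2 = mets * vo2_rest
    vco2 = rer * vo2
    ee_min = w.o2_coef * vo2 + w.co2_coef * vco2

    o2_in = np.full(1440, 0.2093)
    co2_in = np.full(1440, 0.0004)
    f_out = np.full(1440, cfg.chamber_flow_L_min)
    f_in = f_out + vo2 - vco2          # nitrogen balance
    o2_out = (f_in * o2_in - vo2) / f_out
    co2_out = (vco2 + f_in * co2_in) / f_out
    trace = ChamberTrace(
        minutes=minutes,
        o2_in=o2_in,
        o2_out=o2_out,
        co2_in=co2_in,
        co2_out=co2_out,
        flow_L_min=f_out,
    )
    return trace, ee_min, float(ee_min.sum())


def simulate_device_outputs(
    p: Participant,
    daily_tee: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[DeviceDay], list[ActivityLogEntry], dict[str, float]]:
    """Daily device outputs and non-wear logs for one participant.

    ``daily_tee`` is the true TEE series over the free-living days.
    Device TEE (or PAEE) is mult*truth + add + Gaussian noise; wear
    minutes reflect sleep (waist/pocket units are off-body overnight),
    a daily non-wear bout, and rare invalid days.  Returns the days,
    the activity-log entries for the non-wear bouts, and each device's
    own BMR estimate.
    """
    true_paee_daily = 0.9 * daily_tee - p.true_bmr_kcal_day
    days_list: list[DeviceDay] = []
    log: list[ActivityLogEntry] = []
    bmr_dev: dict[str, float] = {}

    n_days = len(daily_tee)
    sleep_h = _trunc_normal(rng, cfg.sleep_mean_h, cfg.sleep_sd_h, 4, 12, size=n_days)
    nonwear = _trunc_normal(
        rng, cfg.nonwear_mean_min, cfg.nonwear_sd_min, 5, 240, size=n_days
    )
    for d in range(n_days):
        date = f"day{d + 1:02d}"
        log.append(
            ActivityLogEntry(
                participant_id=p.id,
                date=date,
                start="20:30",
                duration_min=float(round(nonwear[d])),
                met=cfg.nonwear_met,
                description="bathing/showering",
            )
        )

    for dev, b in cfg.device_bias.items():
        if b.dit_included_in_tee:
            # stationary-day TEE as baseline: BMR plus that day's DIT
            base = p.true_bmr_kcal_day + 0.1 * p.true_tee_kcal_day
        else:
            base = p.true_bmr_kcal_day
        bmr_dev[dev] = float(base * b.bmr_mult + rng.normal(0.0, b.bmr_noise_sd))
        worn_asleep = b.placement == "wrist"
        for d in range(n_days):
            date = f"day{d + 1:02d}"
            if b.provides == "PAEE":
                reported = b.mult * true_paee_daily[d] + b.add
            else:
                reported = b.mult * daily_tee[d] + b.add
            reported += rng.normal(0.0, b.noise_sd)
            invalid = rng.random() < cfg.invalid_day_prob
            if invalid:
                wear = float(rng.uniform(0, 600))
            else:
                wear = 1440.0 - nonwear[d] - (0.0 if worn_asleep else sleep_h[d] * 60.0)
            days_list.append(
                DeviceDay(
                    device_id=dev,
                    participant_id=p.id,
                    date=date,
                    tee_kcal=None if b.provides == "PAEE" else float(reported),
                    paee_kcal=float(reported) if b.provides == "PAEE" else None,
                    bmr_kcal=bmr_dev[dev],
                    wear_minutes=wear,
                    sleep_hours=float(sleep_h[d]),
                )
            )
    return days_list, log, bmr_dev


def default_timetable() -> list[ProtocolEntry]:
    """The packaged standardized-day timetable with compendium METs."""
    from .io import load_default_timetable

    return load_default_timetable()


def simulate_study(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Generate a full study bundle on disk; returns the truth dict.

    Writes the exact input surface of the CLI commands: isotopes.csv,
    doses.csv, bmr.csv, chamber/<participant>.csv, timetable.csv,
    device_days.csv, activity_log.csv, profiles.yaml, truth.json.
    """
    from .io import write_profiles_yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "chamber").mkdir(exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    cohort = simulate_cohort(cfg, rng)
    timetable = default_timetable()

    iso_rows, dose_rows, bmr_rows, day_rows, log_rows = [], [], [], [], []
    truth: dict = {"seed": cfg.seed, "fq": cfg.fq, "participants": {}}
    for p in cohort:
        s_d, s_o, kin = simulate_dlw_samples(p, cfg, rng)
        for s in (s_d, s_o):
            for t, e, b in zip(s.elapsed_days, s.enrichment, s.is_baseline):
                iso_rows.append(
                    dict(
                        participant_id=p.id,
                        isotope=s.isotope.value,
                        elapsed_days=t,
                        enrichment=e,
                        enrichment_units=s.units,
                        is_baseline=bool(b),
                    )
                )
            dose_rows.append(
                dict(
                    participant_id=p.id,
                    isotope=s.isotope.value,
                    dose_g=s.dose.dose_mass_g,
                    atom_percent=s.dose.atom_percent,
                    weight_kg=p.weight_kg,
                )
            )
        trace, ee_min, tee_cha = simulate_chamber_trace(p, timetable, cfg, rng)
        pd.DataFrame(
            dict(
                minute=trace.minutes,
                o2_in=trace.o2_in,
                o2_out=trace.o2_out,
                co2_in=trace.co2_in,
                co2_out=trace.co2_out,
                flow_L_min=trace.flow_L_min,
            )
        ).to_csv(out / "chamber" / f"{p.id}.csv", index=False)
        bmr_rows.append(dict(participant_id=p.id, bmr_kcal_day=p.true_bmr_kcal_day))

        daily = p.true_tee_kcal_day * (
            1.0 + rng.normal(0.0, cfg.day_tee_cv, cfg.n_days)
        )
        dd, logs, bmr_dev = simulate_device_outputs(p, daily, cfg, rng)
        day_rows.extend(dataclasses.asdict(d) for d in dd)
        log_rows.extend(dataclasses.asdict(e) for e in logs)
        truth["participants"][p.id] = dict(
            **dataclasses.asdict(p),
            kinetics=kin,
            tee_cha_kcal_day=tee_cha,
            true_paee_kcal_day=0.9 * p.true_tee_kcal_day - p.true_bmr_kcal_day,
            bmr_dev=bmr_dev,
        )

    pd.DataFrame(iso_rows).to_csv(out / "isotopes.csv", index=False)
    pd.DataFrame(dose_rows).to_csv(out / "doses.csv", index=False)
    pd.DataFrame(bmr_rows).to_csv(out / "bmr.csv", index=False)
    pd.DataFrame(day_rows).to_csv(out / "device_days.csv", index=False)
    pd.DataFrame(log_rows).to_csv(out / "activity_log.csv", index=False)
    pd.DataFrame(
        [dict(start=e.start, end=e.end, activity=e.activity, met=e.met) for e in timetable]
    ).to_csv(out / "timetable.csv", index=False)
    write_profiles_yaml(cfg.profiles(), out / "profiles.yaml")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
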