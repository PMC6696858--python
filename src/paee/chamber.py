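"""Whole-room indirect calorimetry: gas exchange, Weir EE, BMR, protocol.

A metabolic chamber measures O2 and CO2 volume fractions of inlet and
outlet air plus the outlet flow rate.  Minute-level VO2/VCO2 follow from
the concentration differences, optionally with the Haldane nitrogen-
balance transformation (inlet flow inferred from the inert-gas balance,
the default).  Energy expenditure uses the classic Weir equation without
a urinary-nitrogen term.  BMR is the supine-window mean extrapolated to
24 h; the standardized-day protocol is summarized as time-weighted METs
and a predicted activity energy expenditure.

The chamber day runs 09:00 to 09:00 the next day and is treated as one
24-h record; clock times are expressed as minutes from the record start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import WeirConstants
from .energy import EnergySummary, energy_summary

#: default start of the 24-h chamber record, minutes after midnight
DAY_START_MIN = 9 * 60


def clock_to_offset_min(clock: str, day_start_min: int = DAY_START_MIN) -> int:
    """Minutes from record start for an ``HH:MM`` clock time.

    Times earlier than the record start are taken to belong to the next
    calendar day (e.g. ``07:15`` on a 09:00-start record maps to minute
    1335).
    """
    h, m = clock.split(":")
    t = int(h) * 60 + int(m)
    return (t - day_start_min) % 1440


@dataclass
class ChamberTrace:
    """Minute-level chamber gas record over one 24-h measurement day."""

    minutes: np.ndarray          # minute marks from record start
    o2_in: np.ndarray            # volume fractions, [0, 1]
    o2_out: np.ndarray
    co2_in: np.ndarray
    co2_out: np.ndarray
    flow_L_min: np.ndarray       # outlet flow

    def __post_init__(self):
        for name in ("minutes", "o2_in", "o2_out", "co2_in", "co2_out", "flow_L_min"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.minutes) <= 0):
            raise ValueError("minute marks must be strictly increasing")
        for name in ("o2_in", "o2_out", "co2_in", "co2_out"):
            frac = getattr(self, name)
            if np.any((frac < 0) | (frac > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        if np.any(self.flow_L_min <= 0):
            raise ValueError("flow must be positive")


@dataclass
class GasExchange:
    """Per-minute oxygen uptake and carbon dioxide output (L/min)."""

    vo2_L_min: np.ndarray
    vco2_L_min: np.ndarray
    flagged: np.ndarray  # boolean, physiologically implausible minutes

    @property
    def rer(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.vo2_L_min > 0, self.vco2_L_min / self.vo2_L_min, np.nan)


def gas_exchange(trace: ChamberTrace, haldane: bool = True) -> GasExchange:
    """Minute VO2/VCO2 from inlet/outlet fractions and outlet flow.

    With ``haldane`` (default) the inlet flow is recovered from the
    nitrogen balance  flow_in * (1 - Fo2_in - Fco2_in) =
    flow_out * (1 - Fo2_out - Fco2_out), so that RER != 1 does not bias
    VO2.  Without it both gases use the outlet flow directly.

    Minutes with negative VO2 beyond tolerance, or RER outside
    (0.6, 1.3), are flagged, not dropped.
    """
    f_out = trace.flow_L_min
    if haldane:
        n2_in = 1.0 - trace.o2_in - trace.co2_in
        n2_out = 1.0 - trace.o2_out - trace.co2_out
        f_in = f_out * n2_out / n2_in
        vo2 = f_in * trace.o2_in - f_out * trace.o2_out
        vco2 = f_out * trace.co2_out - f_in * trace.co2_in
    else:
        vo2 = f_out * (trace.o2_in - trace.o2_out)
        vco2 = f_out * (trace.co2_out - trace.co2_in)

    flagged = vo2 < -1e-9 * f_out
    with np.errstate(divide="ignore", invalid="ignore"):
        rer = np.where(vo2 > 0, vco2 / vo2, np.nan)
    flagged = flagged | ((vo2 > 0) & ((rer <= 0.6) | (rer >= 1.3)))
    return GasExchange(vo2_L_min=vo2, vco2_L_min=vco2, flagged=flagged)


def weir_ee(vo2_L, vco2_L, constants: WeirConstants = WeirConstants()):
    """Weir energy expenditure, kcal = 3.941 VO2 + 1.106 VCO2 (litres).

    Accepts scalars or arrays; additive over concatenated intervals by
    linearity.
    """
    vo2 = np.asarray(vo2_L, dtype=float)
    vco2 = np.asarray(vco2_L, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas volumes must be non-negative")
    out = constants.o2_coef * vo2 + constants.co2_coef * vco2
    return float(out) if out.ndim == 0 else out


def bmr_from_window(
    minutes: np.ndarray,
    ee_kcal_min: np.ndarray,
    window: tuple[int, int],
) -> float:
    """BMR (kcal/day) as the mean kcal/min over a supine window * 1440.

    ``window`` is (start, end) in minutes from record start; the supine
    rest should span at least 30 min.
    """
    start, end = window
    if end - start < 30:
        raise ValueError("BMR window must span at least 30 min")
    minutes = np.asarray(minutes, dtype=float)
    mask = (minutes >= start) & (minutes < end)
    if minutes.size == 0 or minutes[0] > start or minutes[-1] < end - 1:
        raise ValueError(f"trace does not cover BMR window [{start}, {end})")
    return float(np.mean(np.asarray(ee_kcal_min, dtype=float)[mask]) * 1440.0)


@dataclass
class ProtocolEntry:
    """One timetable slot of the standardized chamber day."""

    start: str            # clock "HH:MM"
    end: str
    activity: str
    met: float

    def duration_h(self) -> float:
        d = (clock_to_offset_min(self.end) - clock_to_offset_min(self.start)) % 1440
        if d == 0:
            d = 1440
        return d / 60.0


def _check_coverage(timetable: list[ProtocolEntry]) -> None:
    slots = sorted(
        (clock_to_offset_min(e.start), clock_to_offset_min(e.start) + e.duration_h() * 60)
        for e in timetable
    )
    cursor = 0.0
    gaps = []
    for s, e in slots:
        if s > cursor + 1e-9:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < 1440 - 1e-9:
        gaps.append((cursor, 1440.0))
    if gaps:
        raise ValueError(f"timetable does not cover 24 h; missing minutes {gaps}")


def protocol_summary(
    timetable: list[ProtocolEntry],
    weight_kg: float,
    bmr_kcal_day: float,
    net_mets: bool = True,
) -> tuple[float, float, float]:
    """Summarize a 24-h protocol: (avg METs, predicted PAEE, meal energy).

    Average METs are time-weighted.  Predicted PAEE uses the MET-hour
    convention 1 MET = 1 kcal/kg/h, with net METs (MET - 1, activity
    above rest) by default.  Meal energy assumes intake at 1.6 * BMR
    split equally over three meals.
    """
    _check_coverage(timetable)
    met_hours = sum(e.met * e.duration_h() for e in timetable)
    hours = sum(e.duration_h() for e in timetable)
    avg_mets = met_hours / hours
    if net_mets:
        paee = sum((e.met - 1.0) * e.duration_h() for e in timetable) * weight_kg
    else:
        paee = met_hours * weight_kg
    meal_energy = bmr_kcal_day * 1.6 / 3.0
    return avg_mets, paee, meal_energy


class ChamberModel:
    """Model object for one participant's chamber day.

    Wraps the gas-exchange → Weir → BMR-window chain and produces an
    energy summary with TEE, BMR, PAEE and PAL.
    """

    def __init__(
        self,
        trace: ChamberTrace,
        bmr_window: tuple[int, int],
        weight_kg: float | None = None,
        haldane: bool = True,
        weir: WeirConstants = WeirConstants(),
    ):
        self.trace = trace
        self.bmr_window = bmr_window
        self.weight_kg = weight_kg
        self.haldane = haldane
        self.weir = weir

    def fit(self) -> "ChamberResults":
        gx = gas_exchange(self.trace, haldane=self.haldane)
        ee_min = weir_ee(
            np.clip(gx.vo2_L_min, 0, None), np.clip(gx.vco2_L_min, 0, None), self.weir
        )
        # integrate over the actual record span, then scale to 24 h
        span_min = self.trace.minutes[-1] - self.trace.minutes[0] + 1
        tee = float(np.sum(ee_min) * 1440.0 / span_min)
        bmr = bmr_from_window(self.trace.minutes, ee_min, self.bmr_window)
        summary = energy_summary("chamber", tee, bmr, weight_kg=self.weight_kg)
        if np.any(gx.flagged):
            summary.flags.append(f"{int(np.sum(gx.flagged))} flagged minutes")
        return ChamberResults(self, gx, ee_min, summary)


class ChamberResults:
    """Fitted chamber day: minute EE plus the daily energy summary."""

    def __init__(
        self,
        model: ChamberModel,
        exchange: GasExchange,
        ee_kcal_min: np.ndarray,
        energy: EnergySummary,
    ):
        self.model = model
        self.exchange = exchange
        self.ee_kcal_min = ee_kcal_min
        self.energy = energy

    @property
    def tee_kcal_day(self) -> float:
        return self.energy.tee_kcal_day

    @property
    def bmr_kcal_day(self) -> float:
        return self.energy.bmr_kcal_day

    def summary(self) -> str:
        e = self.energy
        mean_rer = float(np.nanmean(self.exchange.rer))
        return "\n".join(
            [
                "Chamber results",
                f"  TEE  = {e.tee_kcal_day:.1f} kcal/day   mean RER = {mean_rer:.3f}",
                f"  BMR  = {e.bmr_kcal_day:.1f} kcal/day (supine window)",
                f"  PAEE = {e.paee_kcal_day:.1f} kcal/day   PAL = {e.pal:.2f}",
            ]
            + (["  flags: " + "; ".join(e.flags)] if e.flags else [])
        )
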