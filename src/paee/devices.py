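"""Wearable-device data reduction: PAEE derivation, valid days, non-wear.

Consumer and research devices report daily TEE (or, for some research
units, PAEE directly) plus wear time.  Reduction rules:

* PAEE = TEE - BMR - 0.1*TEE, except for devices whose stationary-day
  TEE already includes diet-induced thermogenesis, where
  PAEE = TEE - BMR.
* A day is valid when the device was worn for more than 10 h, with a
  long-sleep exception (more than 14 h asleep).
* Free-living PAEE is the mean over valid days, requiring at least 10
  valid days.
* Energy expended while the device was off-body is imputed from an
  activity log via MET-hours.
* Devices that publish only a body-surface-area BMR rule are served by
  ``predict_bmr_bsa``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .constants import DIT_FRACTION
from .energy import EnergySummary, energy_summary

#: minimum daily wear for a valid day (strict inequality), minutes
WEAR_THRESHOLD_MIN = 600
#: sleep duration admitting the long-sleep exception (strict), hours
SLEEP_EXCEPTION_H = 14.0
#: minimum number of valid days for a free-living summary
MIN_VALID_DAYS = 10


class Placement(str, Enum):
    wrist = "wrist"
    pocket = "pocket"
    waist = "waist"


class Provides(str, Enum):
    TEE = "TEE"
    PAEE = "PAEE"


class BMRSource(str, Enum):
    app_value = "app_value"
    stationary_day_tee = "stationary_day_tee"
    bsa_formula = "bsa_formula"


@dataclass
class DeviceProfile:
    """Static reduction metadata for one device model."""

    device_id: str
    placement: Placement
    provides: Provides = Provides.TEE
    dit_included_in_tee: bool = False
    bmr_source: BMRSource = BMRSource.app_value

    def __post_init__(self):
        self.placement = Placement(self.placement)
        self.provides = Provides(self.provides)
        self.bmr_source = BMRSource(self.bmr_source)


@dataclass
class DeviceDay:
    """One device-day of output."""

    device_id: str
    participant_id: str
    date: str
    tee_kcal: float | None = None
    paee_kcal: float | None = None
    bmr_kcal: float | None = None
    wear_minutes: float = 0.0
    sleep_hours: float = 0.0
    valid: bool | None = None


@dataclass
class ActivityLogEntry:
    """Logged non-wear activity (for energy imputation)."""

    participant_id: str
    date: str
    start: str
    duration_min: float
    met: float
    description: str = ""


def derive_paee(
    tee_kcal: float,
    bmr_kcal: float,
    profile: DeviceProfile,
    weight_kg: float | None = None,
    dit_fraction: float = DIT_FRACTION,
) -> EnergySummary:
    """Device PAEE from reported TEE and the device's BMR.

    Standard rule subtracts BMR and DIT (0.1*TEE); for profiles with
    ``dit_included_in_tee`` only BMR is subtracted.  Implausibly negative
    PAEE (below -BMR/2) is flagged, never raised.
    """
    return energy_summary(
        profile.device_id,
        tee_kcal,
        bmr_kcal,
        weight_kg=weight_kg,
        dit_fraction=dit_fraction,
        dit_included_in_tee=profile.dit_included_in_tee,
    )


def classify_valid_day(day: DeviceDay) -> bool:
    """Valid when worn > 10 h, or on a long-sleep (> 14 h) exception day."""
    if not 0 <= day.wear_minutes <= 1440:
        raise ValueError("wear_minutes outside [0, 1440]")
    if not 0 <= day.sleep_hours <= 24:
        raise ValueError("sleep_hours outside [0, 24]")
    return day.wear_minutes > WEAR_THRESHOLD_MIN or day.sleep_hours > SLEEP_EXCEPTION_H


class InsufficientValidDaysError(ValueError):
    def __init__(self, n_valid: int, minimum: int):
        self.n_valid = n_valid
        super().__init__(f"only {n_valid} valid days, need >= {minimum}")


def summarize_freeliving(
    days: list[DeviceDay],
    values: list[float] | None = None,
    min_valid: int = MIN_VALID_DAYS,
) -> float:
    """Mean over valid days of the per-day quantity (default: PAEE).

    ``values`` may supply the per-day quantity explicitly (already
    reduced PAEE); otherwise each day's ``paee_kcal`` is used.  Raises
    :class:`InsufficientValidDaysError` below ``min_valid`` valid days.
    """
    flags = [classify_valid_day(d) if d.valid is None else d.valid for d in days]
    if values is None:
        values = [d.paee_kcal for d in days]
    picked = [v for v, ok in zip(values, flags) if ok]
    if len(picked) < min_valid:
        raise InsufficientValidDaysError(len(picked), min_valid)
    return float(np.mean(picked))


def impute_nonwear_ee(
    entries: list[ActivityLogEntry],
    weight_kg: float,
    net_mets: bool = True,
) -> float:
    """Energy (kcal) of logged non-wear activity via MET-hours.

    kcal = sum over entries of (MET - 1 if net else MET) * hours * kg.
    Entries within one participant-day must not overlap.
    """
    by_day: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for e in entries:
        if e.duration_min <= 0:
            raise ValueError("duration must be positive")
        h, m = e.start.split(":")
        s = int(h) * 60 + int(m)
        by_day.setdefault((e.participant_id, e.date), []).append((s, s + e.duration_min))
    for (pid, date), ivals in by_day.items():
        ivals.sort()
        for (s0, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping log entries for {pid} on {date}")
    return float(
        sum((e.met - 1.0 if net_mets else e.met) * (e.duration_min / 60.0) for e in entries)
        * weight_kg
    )


def fujimoto_bsa(height_cm: float, weight_kg: float) -> float:
    """Fujimoto body surface area (m²): 0.008883 * wt^0.444 * ht^0.663."""
    return 0.008883 * weight_kg**0.444 * height_cm**0.663


def predict_bmr_bsa(
    height_cm: float,
    weight_kg: float,
    age_y: float,
    sex: str,
    coef_table: dict[tuple[str, tuple[float, float]], float],
    bsa_fn=fujimoto_bsa,
) -> float:
    """BMR (kcal/day) = BSA * basal coefficient (kcal/m²/h) * 24.

    ``coef_table`` maps (sex, (age_lo, age_hi)) to the basal-metabolism
    coefficient for that stratum; ``bsa_fn`` defaults to the Fujimoto
    surface-area formula used by Japanese references.
    """
    for (s, (lo, hi)), coef in coef_table.items():
        if s == sex and lo <= age_y < hi:
            return bsa_fn(height_cm, weight_kg) * coef * 24.0
    raise KeyError(f"no basal coefficient for sex={sex!r}, age={age_y}")


def count_invalid_days(days: list[DeviceDay]) -> dict[str, int]:
    """Per-device invalid-day counts over a study (validity accounting)."""
    counts: dict[str, int] = {}
    for d in days:
        ok = classify_valid_day(d) if d.valid is None else d.valid
        counts.setdefault(d.device_id, 0)
        if not ok:
            counts[d.device_id] += 1
    return counts
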