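"""Readers and writers for every file surface of the pipeline.

CSV schemas
-----------
``isotopes.csv``   participant_id, isotope (H2|O18), elapsed_days,
                   enrichment, enrichment_units, is_baseline
``doses.csv``      participant_id, isotope, dose_g, atom_percent, weight_kg
``bmr.csv``        participant_id, bmr_kcal_day
``chamber/*.csv``  minute, o2_in, o2_out, co2_in, co2_out, flow_L_min
``timetable.csv``  start, end, activity[, met]
``device_days.csv`` device_id, participant_id, date, tee_kcal, paee_kcal,
                   bmr_kcal, wear_minutes, sleep_hours
``activity_log.csv`` participant_id, date, start, duration_min, met,
                   description
``profiles.yaml``  one DeviceProfile mapping per device

Dates are ISO-8601 or opaque day labels; energies kcal/day, masses kg.
Validation failures raise with the file, column and row; orphan
identifiers across files raise integrity errors.  Report values are
rounded only at the CSV edge (kcal to 0.1, p to 3 decimals); the JSON
report carries full precision.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agreement import AgreementResult, results_to_frame
from .chamber import ChamberTrace, ProtocolEntry
from .devices import ActivityLogEntry, DeviceDay, DeviceProfile
from .dlw import DoseRecord, IsotopeSeries
from .isotopes import Isotope

_ENRICHMENT_UNITS = {"delta_permil", "ppm_excess"}


class SchemaError(ValueError):
    """A file violates its expected schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# packaged reference data
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("paee.data") / name


def load_reference_devices() -> pd.DataFrame:
    """Study device metadata: placement, reduction rules, invalid days."""
    with resources.as_file(_data_path("reference_devices.csv")) as p:
        return pd.read_csv(p)


def load_compendium_mets() -> dict[str, float]:
    """Activity label -> MET assignments from the physical-activity compendium."""
    with resources.as_file(_data_path("compendium_mets.csv")) as p:
        df = pd.read_csv(p)
    return dict(zip(df["activity"], df["met"].astype(float)))


def load_default_timetable() -> list[ProtocolEntry]:
    """The packaged standardized chamber-day timetable with METs attached."""
    mets = load_compendium_mets()
    with resources.as_file(_data_path("standard_day_timetable.csv")) as p:
        return read_timetable(p, met_table=mets)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_isotope_series(
    isotopes_csv, doses_csv
) -> dict[str, dict[Isotope, IsotopeSeries]]:
    """Parse isotope enrichments and doses into per-participant series."""
    iso = pd.read_csv(isotopes_csv)
    _require_columns(
        iso,
        ["participant_id", "isotope", "elapsed_days", "enrichment",
         "enrichment_units", "is_baseline"],
        isotopes_csv,
    )
    bad_units = set(iso["enrichment_units"]) - _ENRICHMENT_UNITS
    if bad_units:
        raise SchemaError(f"{isotopes_csv}: unknown enrichment_units {bad_units}")
    doses = pd.read_csv(doses_csv)
    _require_columns(
        doses, ["participant_id", "isotope", "dose_g", "atom_percent", "weight_kg"],
        doses_csv,
    )
    dose_map = {
        (str(r.participant_id), Isotope(r.isotope)): DoseRecord(
            float(r.dose_g), float(r.atom_percent), float(r.weight_kg)
        )
        for r in doses.itertuples()
    }
    out: dict[str, dict[Isotope, IsotopeSeries]] = {}
    for (pid, iso_name), grp in iso.groupby(["participant_id", "isotope"]):
        pid = str(pid)
        isotope = Isotope(iso_name)
        key = (pid, isotope)
        if key not in dose_map:
            raise SchemaError(
                f"{doses_csv}: no dose record for participant {pid} / {iso_name}"
            )
        units = grp["enrichment_units"].unique()
        if len(units) > 1:
            raise SchemaError(f"{isotopes_csv}: mixed units for {pid}/{iso_name}")
        grp = grp.sort_values("elapsed_days")
        out.setdefault(pid, {})[isotope] = IsotopeSeries(
            participant_id=pid,
            isotope=isotope,
            elapsed_days=grp["elapsed_days"].to_numpy(float),
            enrichment=grp["enrichment"].to_numpy(float),
            is_baseline=grp["is_baseline"].astype(bool).to_numpy(),
            units=units[0],
            dose=dose_map[key],
        )
    return out


def read_bmr(path) -> dict[str, float]:
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "bmr_kcal_day"], path)
    return {str(r.participant_id): float(r.bmr_kcal_day) for r in df.itertuples()}


def read_chamber_trace(path) -> ChamberTrace:
    df = pd.read_csv(path)
    _require_columns(
        df, ["minute", "o2_in", "o2_out", "co2_in", "co2_out", "flow_L_min"], path
    )
    return ChamberTrace(
        minutes=df["minute"].to_numpy(float),
        o2_in=df["o2_in"].to_numpy(float),
        o2_out=df["o2_out"].to_numpy(float),
        co2_in=df["co2_in"].to_numpy(float),
        co2_out=df["co2_out"].to_numpy(float),
        flow_L_min=df["flow_L_min"].to_numpy(float),
    )


def read_timetable(path, met_table: dict[str, float] | None = None) -> list[ProtocolEntry]:
    """Read a timetable CSV; METs come from a ``met`` column or ``met_table``."""
    df = pd.read_csv(path)
    _require_columns(df, ["start", "end", "activity"], path)
    entries = []
    for i, r in enumerate(df.itertuples()):
        if "met" in df.columns and not pd.isna(getattr(r, "met", np.nan)):
            met = float(r.met)
        elif met_table is not None:
            if r.activity not in met_table:
                raise SchemaError(f"{path}: row {i}: no MET assignment for "
                                  f"activity {r.activity!r}")
            met = float(met_table[r.activity])
        else:
            raise SchemaError(f"{path}: row {i}: no met column and no MET table")
        entries.append(ProtocolEntry(start=r.start, end=r.end,
                                     activity=r.activity, met=met))
    return entries


def read_device_days(path) -> list[DeviceDay]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["device_id", "participant_id", "date", "wear_minutes", "sleep_hours"],
        path,
    )
    def opt(r, col):
        v = getattr(r, col, None)
        return None if v is None or pd.isna(v) else float(v)
    return [
        DeviceDay(
            device_id=str(r.device_id),
            participant_id=str(r.participant_id),
            date=str(r.date),
            tee_kcal=opt(r, "tee_kcal"),
            paee_kcal=opt(r, "paee_kcal"),
            bmr_kcal=opt(r, "bmr_kcal"),
            wear_minutes=float(r.wear_minutes),
            sleep_hours=float(r.sleep_hours),
        )
        for r in df.itertuples()
    ]


def read_activity_log(path) -> list[ActivityLogEntry]:
    df = pd.read_csv(path)
    _require_columns(
        df, ["participant_id", "date", "start", "duration_min", "met"], path
    )
    return [
        ActivityLogEntry(
            participant_id=str(r.participant_id),
            date=str(r.date),
            start=str(r.start),
            duration_min=float(r.duration_min),
            met=float(r.met),
            description=str(getattr(r, "description", "")),
        )
        for r in df.itertuples()
    ]


def read_profiles_yaml(path) -> dict[str, DeviceProfile]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        dev: DeviceProfile(device_id=dev, **spec) for dev, spec in raw.items()
    }


def write_profiles_yaml(profiles: list[DeviceProfile], path) -> None:
    raw = {
        p.device_id: dict(
            placement=p.placement.value,
            provides=p.provides.value,
            dit_included_in_tee=p.dit_included_in_tee,
            bmr_source=p.bmr_source.value,
        )
        for p in profiles
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# study bundle
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StudyBundle:
    """Parsed and cross-validated study inputs."""

    root: Path
    isotopes: dict[str, dict[Isotope, IsotopeSeries]]
    bmr: dict[str, float]
    timetable: list[ProtocolEntry]
    device_days: list[DeviceDay]
    activity_log: list[ActivityLogEntry]
    profiles: dict[str, DeviceProfile]
    chamber_traces: dict[str, Path]

    def chamber_trace(self, participant_id: str) -> ChamberTrace:
        return read_chamber_trace(self.chamber_traces[participant_id])


def read_bundle(root) -> StudyBundle:
    """Load a study directory and check cross-file referential integrity."""
    root = Path(root)
    isotopes = read_isotope_series(root / "isotopes.csv", root / "doses.csv")
    bmr = read_bmr(root / "bmr.csv")
    timetable = read_timetable(root / "timetable.csv")
    device_days = read_device_days(root / "device_days.csv")
    log = read_activity_log(root / "activity_log.csv")
    profiles = read_profiles_yaml(root / "profiles.yaml")
    traces = {p.stem: p for p in sorted((root / "chamber").glob("*.csv"))}

    participants = set(isotopes)
    for d in device_days:
        if d.participant_id not in participants:
            raise SchemaError(
                f"device_days.csv: unknown participant {d.participant_id!r}"
            )
        if d.device_id not in profiles:
            raise SchemaError(f"device_days.csv: unknown device {d.device_id!r}")
    for e in log:
        if e.participant_id not in participants:
            raise SchemaError(
                f"activity_log.csv: unknown participant {e.participant_id!r}"
            )
    missing_bmr = participants - set(bmr)
    if missing_bmr:
        raise SchemaError(f"bmr.csv: missing participants {sorted(missing_bmr)}")
    return StudyBundle(
        root=root,
        isotopes=isotopes,
        bmr=bmr,
        timetable=timetable,
        device_days=device_days,
        activity_log=log,
        profiles=profiles,
        chamber_traces=traces,
    )


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

_KCAL_COLS = [
    "device_mean", "device_sd", "mean_diff", "ba_bias", "ba_loa_lower",
    "ba_loa_upper",
]
_P_COLS = [
    "dunnett_p", "pearson_p", "spearman_p", "partial_p_weight", "ba_prop_p",
    "mape_mean_pct", "mape_sd_pct", "pearson_r", "spearman_rho",
    "partial_r_weight", "ba_prop_r",
]


def write_report(results: list[AgreementResult], csv_path=None, json_path=None):
    """Emit the validation report; CSV rounded, JSON full precision."""
    if not results:
        raise ValueError("no results to report")
    df = results_to_frame(results)
    if csv_path is not None:
        out = df.copy()
        for c in _KCAL_COLS:
            out[c] = out[c].round(1)
        for c in _P_COLS:
            out[c] = out[c].astype(float).round(3)
        out.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(
                [dataclasses.asdict(r) for r in results],
                fh,
                indent=1,
                default=lambda o: None if o is None else float(o),
            )
    return df
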