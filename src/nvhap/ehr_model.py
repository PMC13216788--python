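"""Typed data model for the EHR streams used in nvHAP surveillance.

The surveillance minimum data set consists of five event streams, all keyed
by hospital stay: patient stays (with admission/discharge timestamps,
department and discharge ICD codes), chest radiology procedures with their
free-text reports, leukocyte counts, body-temperature measurements, and
intubation (device) episodes.  This module holds the in-memory container
(:class:`SurveillanceDataset`, a bundle of pandas DataFrames), the
delimited-file readers/writers, dataset validation, and the readmission
linkage used by the ">48 h after admission, or anytime after a recent
readmission" relevance rule.

Timestamps are ISO-8601 at minute resolution, timezone-naive: surveillance
is intra-hospital, so a single implicit local clock is assumed and no
timezone arithmetic is performed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TS_FORMAT = "%Y-%m-%dT%H:%M"

#: Column contracts for the delimited files (UTF-8, header row, comma).
STAY_COLUMNS = ["stay_id", "patient_id", "admission_ts", "discharge_ts", "department", "icd_codes"]
RADIOLOGY_COLUMNS = ["event_id", "stay_id", "ts", "modality", "report_text"]
LAB_COLUMNS = ["stay_id", "ts", "leukocytes"]
VITAL_COLUMNS = ["stay_id", "ts", "temperature"]
DEVICE_COLUMNS = ["stay_id", "intubation_ts", "extubation_ts"]


class SurveillanceError(ValueError):
    """A dataset or configuration violates a surveillance contract."""


class Indicator(str, enum.Enum):
    """The five composable EHR indicators of the preselection algorithm."""

    RADIOLOGY_PROCEDURE = "RADIOLOGY_PROCEDURE"
    RADIOLOGY_REPORT = "RADIOLOGY_REPORT"
    LEUKOCYTES = "LEUKOCYTES"
    TEMPERATURE = "TEMPERATURE"
    DEVICE = "DEVICE"


class Modality(str, enum.Enum):
    CHEST_XRAY = "CHEST_XRAY"
    CHEST_CT = "CHEST_CT"
    OTHER = "OTHER"


#: Which dataset table carries each optional indicator stream.
STREAM_TABLES: dict[Indicator, str] = {
    Indicator.RADIOLOGY_PROCEDURE: "radiology",
    Indicator.RADIOLOGY_REPORT: "radiology",
    Indicator.LEUKOCYTES: "labs",
    Indicator.TEMPERATURE: "vitals",
    Indicator.DEVICE: "devices",
}


@dataclass
class LoadLog:
    """Row-level bookkeeping from :func:`load_dataset`.

    ``dropped`` counts rejected rows per table and reason; every input row is
    either retained in the dataset or accounted for here.
    """

    dropped: dict[str, int] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)

    def drop(self, table: str, reason: str, n: int) -> None:
        if n:
            key = f"{table}:{reason}"
            self.dropped[key] = self.dropped.get(key, 0) + int(n)
            self.messages.append(f"{table}: dropped {n} row(s) ({reason})")

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


@dataclass
class ValidationLog:
    """Diagnostic (non-fatal) findings from :func:`validate_dataset`."""

    warnings: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def __bool__(self) -> bool:
        return bool(self.warnings)


@dataclass
class SurveillanceDataset:
    """The five surveillance streams plus the declared available indicators.

    ``available_streams`` is declared by the hospital configuration, not
    inferred from table emptiness: a hospital may legitimately have an empty
    labs table for a quiet month while the stream exists.
    """

    stays: pd.DataFrame
    radiology: pd.DataFrame
    labs: pd.DataFrame
    vitals: pd.DataFrame
    devices: pd.DataFrame
    available_streams: frozenset[Indicator]
    load_log: LoadLog = field(default_factory=LoadLog)

    def stay_ids(self) -> pd.Index:
        return pd.Index(self.stays["stay_id"])

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


def _empty_table(columns: list[str], ts_cols: Iterable[str]) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype="object") for c in columns})
    for c in ts_cols:
        df[c] = pd.Series(dtype="datetime64[ns]")
    return df


def empty_tables() -> dict[str, pd.DataFrame]:
    return {
        "stays": _empty_table(STAY_COLUMNS, ["admission_ts", "discharge_ts"]),
        "radiology": _empty_table(RADIOLOGY_COLUMNS, ["ts"]),
        "labs": _empty_table(LAB_COLUMNS, ["ts"]),
        "vitals": _empty_table(VITAL_COLUMNS, ["ts"]),
        "devices": _empty_table(DEVICE_COLUMNS, ["intubation_ts", "extubation_ts"]),
    }


def _parse_ts(series: pd.Series, *, allow_missing: bool = False) -> tuple[pd.Series, pd.Series]:
    """Parse an ISO timestamp column; return (parsed, bad-row mask)."""
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    bad = parsed.isna()
    if allow_missing:
        bad &= series.notna() & (series.astype(str).str.strip() != "")
    return parsed, bad


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SurveillanceError(f"{path}: missing required column(s) {missing}")
    return df[columns]


def load_dataset(
    paths: Mapping[str, str | Path],
    declared_streams: Iterable[Indicator | str] = (),
) -> SurveillanceDataset:
    """Load the delimited tables into a cross-referenced dataset.

    ``paths`` maps table names (``stays``, ``radiology``, ``labs``,
    ``vitals``, ``devices``) to file paths.  The stays and radiology tables
    are mandatory (chest radiology is the minimum indicator).  Rows with a
    malformed timestamp or an unresolvable ``stay_id`` are rejected and
    counted in the returned dataset's :class:`LoadLog`.
    """
    declared = {Indicator(s) for s in declared_streams}
    declared.add(Indicator.RADIOLOGY_PROCEDURE)
    log = LoadLog()

    for required in ("stays", "radiology"):
        if required not in paths:
            raise SurveillanceError(
                f"mandatory table '{required}' not provided (radiology is the minimum indicator)"
            )
        if not Path(paths[required]).exists():
            raise SurveillanceError(f"mandatory table '{required}' not found: {paths[required]}")

    stays = _read_csv(Path(paths["stays"]), STAY_COLUMNS)
    if stays.empty:
        raise SurveillanceError("no population under surveillance: stays table is empty")
    for col in ("admission_ts", "discharge_ts"):
        stays[col], bad = _parse_ts(stays[col])
        log.drop("stays", f"malformed {col}", bad.sum())
        stays = stays[~bad]
    inverted = stays["discharge_ts"] <= stays["admission_ts"]
    log.drop("stays", "discharge not after admission", inverted.sum())
    stays = stays[~inverted]
    if stays["stay_id"].duplicated().any():
        raise SurveillanceError("duplicate stay_id in stays table")
    if stays.empty:
        raise SurveillanceError("no population under surveillance: all stay rows rejected")
    stays = stays.reset_index(drop=True)
    stays["icd_codes"] = stays["icd_codes"].map(
        lambda s: tuple(c for c in str(s).split("|") if c)
    )
    stays["prior_stay_id"] = None

    known = set(stays["stay_id"])
    interval = stays.set_index("stay_id")[["admission_ts", "discharge_ts"]]
    tables = empty_tables()
    tables["stays"] = stays

    def load_events(name: str, columns: list[str], ts_cols: list[str], optional_ts: set[str] = frozenset()) -> None:
        if name not in paths:
            return
        df = _read_csv(Path(paths[name]), columns)
        for col in ts_cols:
            df[col], bad = _parse_ts(df[col], allow_missing=col in optional_ts)
            log.drop(name, f"malformed {col}", bad.sum())
            df = df[~bad]
        unresolved = ~df["stay_id"].isin(known)
        log.drop(name, "unresolvable stay_id", unresolved.sum())
        df = df[~unresolved]
        tables[name] = df.reset_index(drop=True)

    load_events("radiology", RADIOLOGY_COLUMNS, ["ts"])
    rad = tables["radiology"]
    if len(rad):
        bad_mod = ~rad["modality"].isin([m.value for m in Modality])
        log.drop("radiology", "unknown modality", bad_mod.sum())
        rad = rad[~bad_mod]
        adm = interval["admission_ts"].reindex(rad["stay_id"]).to_numpy()
        dis = interval["discharge_ts"].reindex(rad["stay_id"]).to_numpy()
        ts = rad["ts"].to_numpy()
        outside = (ts < adm) | (ts > dis)
        log.drop("radiology", "timestamp outside stay interval", outside.sum())
        tables["radiology"] = rad[~outside].reset_index(drop=True)

    load_events("labs", LAB_COLUMNS, ["ts"])
    labs = tables["labs"]
    if len(labs):
        labs["leukocytes"] = pd.to_numeric(labs["leukocytes"], errors="coerce")
        bad = labs["leukocytes"].isna() | (labs["leukocytes"] < 0)
        log.drop("labs", "invalid leukocyte value", bad.sum())
        tables["labs"] = labs[~bad].reset_index(drop=True)

    load_events("vitals", VITAL_COLUMNS, ["ts"])
    vit = tables["vitals"]
    if len(vit):
        vit["temperature"] = pd.to_numeric(vit["temperature"], errors="coerce")
        bad = vit["temperature"].isna() | (vit["temperature"] < 25) | (vit["temperature"] > 45)
        log.drop("vitals", "temperature outside [25, 45] degC", bad.sum())
        tables["vitals"] = vit[~bad].reset_index(drop=True)

    load_events("devices", DEVICE_COLUMNS, ["intubation_ts", "extubation_ts"], optional_ts={"extubation_ts"})
    dev = tables["devices"]
    if len(dev):
        bad = dev["extubation_ts"].notna() & (dev["extubation_ts"] <= dev["intubation_ts"])
        log.drop("devices", "extubation not after intubation", bad.sum())
        tables["devices"] = dev[~bad].reset_index(drop=True)

    return SurveillanceDataset(
        stays=tables["stays"],
        radiology=tables["radiology"],
        labs=tables["labs"],
        vitals=tables["vitals"],
        devices=tables["devices"],
        available_streams=frozenset(declared),
        load_log=log,
    )


def _format_ts(series: pd.Series) -> pd.Series:
    out = series.dt.strftime(TS_FORMAT)
    return out.fillna("")


def write_dataset(dataset: SurveillanceDataset, directory: str | Path) -> dict[str, Path]:
    """Write the five tables back to CSV; inverse of :func:`load_dataset`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    stays = dataset.stays.copy()
    stays["admission_ts"] = _format_ts(stays["admission_ts"])
    stays["discharge_ts"] = _format_ts(stays["discharge_ts"])
    stays["icd_codes"] = stays["icd_codes"].map("|".join)
    frames = {
        "stays": stays[STAY_COLUMNS],
        "radiology": dataset.radiology.assign(ts=_format_ts(dataset.radiology["ts"]))[RADIOLOGY_COLUMNS]
        if len(dataset.radiology)
        else dataset.radiology[RADIOLOGY_COLUMNS],
        "labs": dataset.labs.assign(ts=_format_ts(dataset.labs["ts"]))[LAB_COLUMNS]
        if len(dataset.labs)
        else dataset.labs[LAB_COLUMNS],
        "vitals": dataset.vitals.assign(ts=_format_ts(dataset.vitals["ts"]))[VITAL_COLUMNS]
        if len(dataset.vitals)
        else dataset.vitals[VITAL_COLUMNS],
        "devices": dataset.devices.assign(
            intubation_ts=_format_ts(dataset.devices["intubation_ts"]),
            extubation_ts=_format_ts(dataset.devices["extubation_ts"]),
        )[DEVICE_COLUMNS]
        if len(dataset.devices)
        else dataset.devices[DEVICE_COLUMNS],
    }
    for name, frame in frames.items():
        path = directory / f"{name}.csv"
        frame.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def link_readmissions(stays: pd.DataFrame, max_gap_days: int = 10) -> pd.DataFrame:
    """Set ``prior_stay_id`` for stays that are recent readmissions.

    A stay is linked to the same patient's immediately preceding stay when
    the discharge-to-admission gap is strictly positive and at most
    ``max_gap_days`` whole days (day-``max_gap_days`` inclusive).  Such
    readmitted patients keep their "anytime" radiology relevance.  Stays of
    one patient that overlap in time are a hard error: the surveillance
    timeline is undefined on overlaps.

    Idempotent and independent of input row order.
    """
    stays = stays.copy()
    stays["prior_stay_id"] = None
    order = stays.sort_values(["patient_id", "admission_ts", "discharge_ts"], kind="mergesort")
    prev = order.groupby("patient_id", sort=False).shift(1)
    overlap = prev["discharge_ts"].notna() & (order["admission_ts"] < prev["discharge_ts"])
    if overlap.any():
        bad = order.loc[overlap, "stay_id"].iloc[0]
        raise SurveillanceError(
            f"overlapping stays for one patient (e.g. stay {bad!r}); timeline is ambiguous"
        )
    gap = order["admission_ts"] - prev["discharge_ts"]
    linked = gap.notna() & (gap > pd.Timedelta(0)) & (gap // pd.Timedelta(days=1) <= max_gap_days)
    stays.loc[order.index[linked], "prior_stay_id"] = prev.loc[linked, "stay_id"].to_numpy()
    return stays


def validate_dataset(dataset: SurveillanceDataset, config=None) -> ValidationLog:
    """Diagnostic checks against the indicator configuration; never raises.

    Reports streams a configuration requires but the dataset does not
    declare or populate, timestamp-range anomalies, and the fraction of
    radiology events with empty reports when the report rule is enabled.
    """
    log = ValidationLog()
    enabled: set[Indicator] = set(getattr(config, "enabled_indicators", dataset.available_streams))
    for ind in sorted(enabled, key=lambda i: i.value):
        table = dataset.table(STREAM_TABLES[ind])
        if ind not in dataset.available_streams:
            log.warn(f"indicator {ind.value} enabled but stream not declared available")
        elif table.empty and ind is not Indicator.RADIOLOGY_REPORT:
            log.warn(f"indicator {ind.value} enabled but table '{STREAM_TABLES[ind]}' is empty")

    inverted = int((dataset.stays["discharge_ts"] <= dataset.stays["admission_ts"]).sum())
    if inverted:
        log.warn(f"{inverted} stay(s) with discharge before admission")

    interval = dataset.stays.set_index("stay_id")[["admission_ts", "discharge_ts"]]
    for name, ts_col in (("labs", "ts"), ("vitals", "ts"), ("devices", "intubation_ts")):
        table = dataset.table(name)
        if table.empty:
            continue
        adm = interval["admission_ts"].reindex(table["stay_id"]).to_numpy()
        dis = interval["discharge_ts"].reindex(table["stay_id"]).to_numpy()
        ts = table[ts_col].to_numpy()
        n_out = int(((ts < adm) | (ts > dis)).sum())
        if n_out:
            log.warn(f"{name}: {n_out} event(s) timestamped outside their stay interval")

    if Indicator.RADIOLOGY_REPORT in enabled and len(dataset.radiology):
        empty = dataset.radiology["report_text"].astype(str).str.strip() == ""
        frac = float(empty.mean())
        if frac > 0:
            log.warn(f"radiology: fraction of events with empty report = {frac:.2f}")
    return log
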