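"""The adaptable nvHAP preselection algorithm.

A stay is preselected for manual review when it has at least one chest
radiology procedure "of relevance".  Relevance is a conjunction over the
*enabled* indicators:

* RADIOLOGY_PROCEDURE (always enabled — the minimum indicator): the
  procedure is a chest image taken strictly more than 48 h after admission,
  or at any time during a stay that is a recent (≤ 10-day) readmission.
* RADIOLOGY_REPORT: the report does not explicitly rule out pneumonia
  (see :mod:`nvhap.report_textrules`).
* LEUKOCYTES: some leukocyte count within ±48 h of the image is abnormal
  (< 4.0 or ≥ 12.0 ×10⁹/L).
* TEMPERATURE: some body temperature within ±48 h of the image exceeds
  38.0 °C.
* DEVICE: the patient was NOT continuously intubated throughout the 48 h
  before the image (continuous full-window intubation marks a VAP
  candidate, outside nvHAP surveillance; partial-window intubation stays
  in scope so indeterminate HAP is not lost).

Disabled or unavailable indicators never veto: a hospital without a lab
feed runs the same algorithm with that flag set to "not applicable".
Hence nested configurations are antitone — enabling more indicators can
only shrink the preselected set, which is why reduced algorithms have
equal or higher sensitivity at the price of more manual review.

All windows and thresholds are configuration, not constants.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .ehr_model import (
    Indicator,
    Modality,
    STREAM_TABLES,
    SurveillanceDataset,
    SurveillanceError,
    link_readmissions,
)
from .report_textrules import TermSet, classify_report, load_termset

ALL_INDICATORS = frozenset(Indicator)


class AlgorithmConfig(BaseModel):
    """Everything adaptable about the preselection algorithm.

    Thresholds follow the ECDC HAP definition (fever > 38.0 °C, leukocytes
    < 4.0 or ≥ 12.0 ×10⁹/L); signal windows default to a symmetric ±48 h
    around the radiology timestamp.
    """

    model_config = {"frozen": True, "arbitrary_types_allowed": True}

    enabled_indicators: frozenset[Indicator] = ALL_INDICATORS
    min_hours_after_admission: float = Field(default=48.0, gt=0)
    readmission_gap_days: int = Field(default=10, ge=0)
    lab_window_hours: float = Field(default=48.0, gt=0)
    temp_window_hours: float = Field(default=48.0, gt=0)
    leukopenia_threshold: float = Field(default=4.0, gt=0)
    leukocytosis_threshold: float = Field(default=12.0, gt=0)
    fever_threshold: float = Field(default=38.0, gt=0)
    vap_exclusion_hours: float = Field(default=48.0, gt=0)
    termset: TermSet = Field(default_factory=lambda: load_termset(language_tag="de"))

    @model_validator(mode="after")
    def _check(self):
        if Indicator.RADIOLOGY_PROCEDURE not in self.enabled_indicators:
            # the minimum indicator cannot be switched off
            object.__setattr__(
                self, "enabled_indicators", self.enabled_indicators | {Indicator.RADIOLOGY_PROCEDURE}
            )
        if self.leukopenia_threshold >= self.leukocytosis_threshold:
            raise ValueError("leukopenia_threshold must be below leukocytosis_threshold")
        return self

    def with_indicators(self, indicators: Iterable[Indicator | str]) -> "AlgorithmConfig":
        return self.model_copy(
            update={"enabled_indicators": frozenset(Indicator(i) for i in indicators) | {Indicator.RADIOLOGY_PROCEDURE}}
        )

    def fingerprint(self) -> str:
        """Stable hash of the effective configuration (for run manifests)."""
        payload = self.model_dump(mode="json")
        payload["enabled_indicators"] = sorted(i.value for i in self.enabled_indicators)
        canonical = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    @classmethod
    def from_mapping(cls, data: Mapping) -> "AlgorithmConfig":
        """Build from a config document with optional sections
        ``indicators`` (list), ``windows``, ``thresholds`` and ``termset``."""
        kwargs: dict = {}
        if "indicators" in data:
            kwargs["enabled_indicators"] = frozenset(Indicator(i) for i in data["indicators"])
        windows = data.get("windows", {})
        for key in (
            "min_hours_after_admission",
            "readmission_gap_days",
            "lab_window_hours",
            "temp_window_hours",
            "vap_exclusion_hours",
        ):
            if key in windows:
                kwargs[key] = windows[key]
        thresholds = data.get("thresholds", {})
        for src, dst in (
            ("leukopenia", "leukopenia_threshold"),
            ("leukocytosis", "leukocytosis_threshold"),
            ("fever", "fever_threshold"),
        ):
            if src in thresholds:
                kwargs[dst] = thresholds[src]
        ts = data.get("termset")
        if ts is not None:
            if isinstance(ts, Mapping) and set(ts) <= {"language", "language_tag"}:
                kwargs["termset"] = load_termset(language_tag=ts.get("language") or ts.get("language_tag"))
            else:
                kwargs["termset"] = load_termset(ts)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AlgorithmConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_mapping(data)


@dataclass(frozen=True)
class IndicatorVerdict:
    """Per-indicator flags for one radiology event; None means the
    indicator is disabled/unavailable (not applicable, never vetoing)."""

    radiology_timing_ok: bool
    report_not_excluding: bool | None
    leukocyte_signal: bool | None
    temperature_signal: bool | None
    device_ok: bool | None

    @property
    def relevant(self) -> bool:
        flags = (
            self.radiology_timing_ok,
            self.report_not_excluding,
            self.leukocyte_signal,
            self.temperature_signal,
            self.device_ok,
        )
        return all(f for f in flags if f is not None) and any(f is not None for f in flags)

    def compact(self) -> str:
        def sym(f):
            return "NA" if f is None else ("1" if f else "0")

        return (
            f"timing={sym(self.radiology_timing_ok)},report={sym(self.report_not_excluding)},"
            f"leuko={sym(self.leukocyte_signal)},temp={sym(self.temperature_signal)},"
            f"device={sym(self.device_ok)}"
        )


@dataclass(frozen=True)
class PreselectionResult:
    stay_id: str
    preselected: bool
    triggering_events: tuple[tuple[str, IndicatorVerdict], ...]
    first_trigger_ts: pd.Timestamp | None = None


def radiology_timing_ok(
    rad_ts: pd.Timestamp,
    admission_ts: pd.Timestamp,
    discharge_ts: pd.Timestamp,
    is_readmission: bool,
    config: AlgorithmConfig,
) -> bool:
    """Timing arm of relevance: strictly > ``min_hours_after_admission``
    after admission, or anytime for a recent readmission."""
    if rad_ts < admission_ts or rad_ts > discharge_ts:
        raise SurveillanceError(
            f"radiology timestamp {rad_ts} outside stay interval [{admission_ts}, {discharge_ts}]"
        )
    if is_readmission:
        return True
    return (rad_ts - admission_ts) > pd.Timedelta(hours=config.min_hours_after_admission)


def leukocyte_signal(labs: pd.DataFrame, t: pd.Timestamp, config: AlgorithmConfig) -> bool:
    """True iff an abnormal leukocyte count lies within ±lab_window_hours
    of ``t`` (window boundaries inclusive)."""
    if labs.empty:
        return False
    dt = (labs["ts"] - t).abs()
    in_window = dt <= pd.Timedelta(hours=config.lab_window_hours)
    values = labs["leukocytes"]
    abnormal = (values < config.leukopenia_threshold) | (values >= config.leukocytosis_threshold)
    return bool((in_window & abnormal).any())


def temperature_signal(vitals: pd.DataFrame, t: pd.Timestamp, config: AlgorithmConfig) -> bool:
    """True iff a temperature strictly above the fever threshold lies
    within ±temp_window_hours of ``t``."""
    if vitals.empty:
        return False
    dt = (vitals["ts"] - t).abs()
    in_window = dt <= pd.Timedelta(hours=config.temp_window_hours)
    return bool((in_window & (vitals["temperature"] > config.fever_threshold)).any())


def _covers_window(
    episodes: Iterable[tuple[pd.Timestamp, pd.Timestamp | None]],
    start: pd.Timestamp,
    end: pd.Timestamp,
) -> bool:
    """Whether the union of intubation episodes covers [start, end]
    without gaps (abutting episodes merge; open-ended episodes run to
    ``end``)."""
    ivals = sorted(
        (intub, end if extub is None or pd.isna(extub) else extub) for intub, extub in episodes
    )
    cur_s = cur_e = None
    for lo, hi in ivals:
        if cur_s is None:
            cur_s, cur_e = lo, hi
        elif lo <= cur_e:
            cur_e = max(cur_e, hi)
        else:
            if cur_s <= start and cur_e >= end:
                return True
            cur_s, cur_e = lo, hi
    return cur_s is not None and cur_s <= start and cur_e >= end


def device_ok(devices: pd.DataFrame, t: pd.Timestamp, config: AlgorithmConfig) -> bool:
    """False iff the patient was continuously intubated throughout the full
    ``vap_exclusion_hours`` before ``t`` (a pure-VAP candidate, excluded
    from nvHAP preselection).  Partial-window intubation passes, keeping
    indeterminate HAP in scope."""
    if devices.empty:
        return True
    window_start = t - pd.Timedelta(hours=config.vap_exclusion_hours)
    eps = [
        (row.intubation_ts, None if pd.isna(row.extubation_ts) else row.extubation_ts)
        for row in devices.itertuples()
    ]
    return not _covers_window(eps, window_start, t)


def check_streams(dataset: SurveillanceDataset, config: AlgorithmConfig) -> None:
    missing = {
        ind for ind in config.enabled_indicators if ind not in dataset.available_streams
    }
    if missing:
        names = ", ".join(sorted(i.value for i in missing))
        raise SurveillanceError(f"configuration enables stream(s) the dataset lacks: {names}")


def evaluate_radiology_event(
    rad: pd.Series,
    stay: pd.Series,
    dataset: SurveillanceDataset,
    config: AlgorithmConfig,
) -> IndicatorVerdict:
    """Full relevance verdict for one radiology event (conjunction over
    enabled indicators; modality OTHER never triggers)."""
    enabled = config.enabled_indicators
    if rad["modality"] == Modality.OTHER.value:
        return IndicatorVerdict(False, None, None, None, None)
    timing = radiology_timing_ok(
        rad["ts"], stay["admission_ts"], stay["discharge_ts"],
        stay.get("prior_stay_id") is not None and not pd.isna(stay.get("prior_stay_id")),
        config,
    )
    report = None
    if Indicator.RADIOLOGY_REPORT in enabled:
        report = not classify_report(str(rad["report_text"]), config.termset)
    leuko = None
    if Indicator.LEUKOCYTES in enabled:
        leuko = leukocyte_signal(
            dataset.labs[dataset.labs["stay_id"] == rad["stay_id"]], rad["ts"], config
        )
    temp = None
    if Indicator.TEMPERATURE in enabled:
        temp = temperature_signal(
            dataset.vitals[dataset.vitals["stay_id"] == rad["stay_id"]], rad["ts"], config
        )
    device = None
    if Indicator.DEVICE in enabled:
        device = device_ok(
            dataset.devices[dataset.devices["stay_id"] == rad["stay_id"]], rad["ts"], config
        )
    return IndicatorVerdict(timing, report, leuko, temp, device)


def _group_by_stay(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    if df.empty:
        return {}
    return {sid: g for sid, g in df.groupby("stay_id", sort=False)}


def _group_arrays(df: pd.DataFrame, ts_col: str, value_col: str | None) -> dict[str, tuple]:
    """Per-stay (timestamps[int64 ns], values) arrays for the fast path."""
    if df.empty:
        return {}
    out: dict[str, tuple] = {}
    for sid, g in df.groupby("stay_id", sort=False):
        ts = g[ts_col].to_numpy().astype("datetime64[ns]").astype(np.int64)
        out[sid] = (ts, g[value_col].to_numpy(float) if value_col else None)
    return out


def preselect(dataset: SurveillanceDataset, config: AlgorithmConfig) -> list[PreselectionResult]:
    """Run the algorithm over every stay; one result per stay, sorted by
    stay_id.  Deterministic and independent of input row order.

    Internally uses per-stay numpy arrays for the window joins; the
    per-event operations above define the semantics and are held equal to
    this path by the oracle tests.
    """
    check_streams(dataset, config)
    stays = link_readmissions(dataset.stays, config.readmission_gap_days)
    stays = stays.sort_values("stay_id", kind="mergesort")

    enabled = config.enabled_indicators
    use_report = Indicator.RADIOLOGY_REPORT in enabled
    use_leuko = Indicator.LEUKOCYTES in enabled
    use_temp = Indicator.TEMPERATURE in enabled
    use_device = Indicator.DEVICE in enabled

    labs_by_stay = _group_arrays(dataset.labs, "ts", "leukocytes") if use_leuko else {}
    vitals_by_stay = _group_arrays(dataset.vitals, "ts", "temperature") if use_temp else {}
    devices_by_stay: dict[str, list] = {}
    if use_device and len(dataset.devices):
        for sid, g in dataset.devices.groupby("stay_id", sort=False):
            devices_by_stay[sid] = [
                (row.intubation_ts, None if pd.isna(row.extubation_ts) else row.extubation_ts)
                for row in g.itertuples()
            ]
    rad_sorted = dataset.radiology.sort_values(["ts", "event_id"], kind="mergesort")
    rad_by_stay = _group_by_stay(rad_sorted)

    lab_win = np.int64(config.lab_window_hours * 3.6e12)
    temp_win = np.int64(config.temp_window_hours * 3.6e12)

    # report verdicts are per event, not per (event, stay): cache by event
    report_ok: dict[str, bool] = {}
    if use_report:
        for rad in dataset.radiology.itertuples():
            report_ok[rad.event_id] = not classify_report(str(rad.report_text), config.termset)

    results: list[PreselectionResult] = []
    for stay in stays.itertuples():
        triggers: list[tuple[str, IndicatorVerdict]] = []
        first_ts: pd.Timestamp | None = None
        rads = rad_by_stay.get(stay.stay_id)
        if rads is not None:
            is_readm = stay.prior_stay_id is not None and not pd.isna(stay.prior_stay_id)
            labs = labs_by_stay.get(stay.stay_id)
            vitals = vitals_by_stay.get(stay.stay_id)
            episodes = devices_by_stay.get(stay.stay_id)
            for rad in rads.itertuples():
                if rad.modality == Modality.OTHER.value:
                    continue
                timing = radiology_timing_ok(
                    rad.ts, stay.admission_ts, stay.discharge_ts, is_readm, config
                )
                if not timing:
                    continue
                report = report_ok[rad.event_id] if use_report else None
                leuko = temp = device = None
                t_ns = rad.ts.value
                if use_leuko:
                    if labs is None:
                        leuko = False
                    else:
                        ts, values = labs
                        near = np.abs(ts - t_ns) <= lab_win
                        leuko = bool(
                            np.any(
                                near
                                & (
                                    (values < config.leukopenia_threshold)
                                    | (values >= config.leukocytosis_threshold)
                                )
                            )
                        )
                if use_temp:
                    if vitals is None:
                        temp = False
                    else:
                        ts, values = vitals
                        temp = bool(
                            np.any(
                                (np.abs(ts - t_ns) <= temp_win)
                                & (values > config.fever_threshold)
                            )
                        )
                if use_device:
                    device = (
                        not _covers_window(
                            episodes,
                            rad.ts - pd.Timedelta(hours=config.vap_exclusion_hours),
                            rad.ts,
                        )
                        if episodes
                        else True
                    )
                verdict = IndicatorVerdict(timing, report, leuko, temp, device)
                if verdict.relevant:
                    triggers.append((rad.event_id, verdict))
                    if first_ts is None or rad.ts < first_ts:
                        first_ts = rad.ts
        results.append(
            PreselectionResult(
                stay_id=stay.stay_id,
                preselected=bool(triggers),
                triggering_events=tuple(triggers),
                first_trigger_ts=first_ts,
            )
        )
    return results


def preselected_ids(results: Iterable[PreselectionResult]) -> set[str]:
    return {r.stay_id for r in results if r.preselected}


def results_frame(results: Iterable[PreselectionResult]) -> pd.DataFrame:
    """Tabular audit-trail view (one row per stay) for CSV export."""
    rows = []
    for r in results:
        rows.append(
            {
                "stay_id": r.stay_id,
                "preselected": int(r.preselected),
                "n_triggering_events": len(r.triggering_events),
                "first_trigger_ts": ""
                if r.first_trigger_ts is None
                else r.first_trigger_ts.strftime("%Y-%m-%dT%H:%M"),
                "indicator_flags": r.triggering_events[0][1].compact() if r.triggering_events else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["stay_id", "preselected", "n_triggering_events", "first_trigger_ts", "indicator_flags"],
    )
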