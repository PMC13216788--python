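"""Shared fixtures: tiny hand-built surveillance datasets and helpers."""

from __future__ import annotations

import pandas as pd
import pytest

from nvhap import (
    AlgorithmConfig,
    Indicator,
    ScenarioParams,
    SurveillanceDataset,
    generate_hospital,
    load_termset,
)
from nvhap.ehr_model import (
    DEVICE_COLUMNS,
    LAB_COLUMNS,
    RADIOLOGY_COLUMNS,
    STAY_COLUMNS,
    VITAL_COLUMNS,
)

T0 = pd.Timestamp("2023-03-01 08:00")


def ts(hours: float) -> pd.Timestamp:
    """Timestamp ``hours`` after the fixture epoch, at minute resolution."""
    return (T0 + pd.Timedelta(hours=hours)).floor("min")


def make_stays(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "patient_id": None,
        "admission_ts": ts(0),
        "discharge_ts": ts(240),
        "department": "MED",
        "icd_codes": (),
        "prior_stay_id": None,
    }
    full = []
    for row in rows:
        r = {**defaults, **row}
        if r["patient_id"] is None:
            r["patient_id"] = "pat-" + r["stay_id"]
        full.append(r)
    return pd.DataFrame(full, columns=STAY_COLUMNS + ["prior_stay_id"])


def make_dataset(
    stays: list[dict],
    radiology: list[dict] = (),
    labs: list[dict] = (),
    vitals: list[dict] = (),
    devices: list[dict] = (),
    streams: set[Indicator] = frozenset(Indicator),
) -> SurveillanceDataset:
    def frame(rows, columns, ts_cols):
        df = pd.DataFrame(list(rows), columns=columns)
        for c in ts_cols:
            df[c] = pd.to_datetime(df[c]) if len(df) else pd.Series(dtype="datetime64[ns]")
        return df

    return SurveillanceDataset(
        stays=make_stays(stays),
        radiology=frame(radiology, RADIOLOGY_COLUMNS, ["ts"]),
        labs=frame(labs, LAB_COLUMNS, ["ts"]),
        vitals=frame(vitals, VITAL_COLUMNS, ["ts"]),
        devices=frame(devices, DEVICE_COLUMNS, ["intubation_ts", "extubation_ts"]),
        available_streams=frozenset(streams),
    )


@pytest.fixture(scope="session")
def termset_de():
    return load_termset(language_tag="de")


@pytest.fixture(scope="session")
def default_config(termset_de):
    return AlgorithmConfig(termset=termset_de)


@pytest.fixture(scope="session")
def small_hospital():
    """A 300-stay noisy synthetic hospital shared across read-only tests."""
    params = ScenarioParams(
        n_stays=300, nvhap_incidence=40.0, signal_noise=0.2, seed=20230301
    )
    return generate_hospital(params)
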