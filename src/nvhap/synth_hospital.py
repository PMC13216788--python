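"""Seeded synthetic-hospital generator with ground-truth pneumonia episodes.

Real surveillance data never leaves the hospitals, so every other module is
exercised on generated populations: hospital stays with log-normal lengths
of stay, background chest imaging with templated reports (a configurable
fraction of which explicitly rule out pneumonia), routine leukocyte and
temperature measurements, intubation episodes, and injected pneumonia
episodes whose structured features satisfy the ECDC-style definition by
construction.

Injected episodes emit a qualifying chest radiology event more than 48 h
after admission (or anytime on a recent readmission), an abnormal
leukocyte count and a fever measurement near the image, and device
episodes consistent with the episode's NVHAP/IHAP/VAP label.
``signal_noise`` is the probability that a true case's lab or temperature
measurement is *missing from the record* (the chart reviewer still sees
the case; the algorithm's indicator may not), which is the mechanism by
which indicator-rich algorithms lose sensitivity on imperfect data.

One RNG stream per output table, all spawned from the scenario seed, so
extending one table never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .case_classification import CaseFeatures, Category, ClinicalSign
from .ehr_model import (
    Indicator,
    Modality,
    SurveillanceDataset,
    SurveillanceError,
    link_readmissions,
    load_dataset,
    write_dataset,
)
from .report_textrules import TermSet, Verdict, classify_report, load_termset

_EPOCH = pd.Timestamp("2023-01-01 00:00")
_DEPARTMENTS = ["MED", "SURG", "GER", "ONC", "ICU"]
_ICD_POOL = ["I10", "E11.9", "J44.1", "N39.0", "K57.30", "M16.1", "I48.0", "C34.9"]
_HAP_CODE = "U69.00"


class ScenarioParams(BaseModel):
    """Knobs of the synthetic hospital.

    Defaults describe a desk-scale general hospital: 5 000 stays over half
    a year, log-normal length of stay with median ≈ 4 days, an nvHAP
    incidence of 10 episodes per 1 000 stays, and noise-free case signals
    (``signal_noise = 0``).
    """

    model_config = {"frozen": True}

    n_stays: int = Field(default=5000, gt=0)
    los_meanlog: float = 1.4  # log-days; median exp(1.4) ~ 4.1 d
    los_sdlog: float = Field(default=0.7, gt=0)
    nvhap_incidence: float = Field(default=10.0, ge=0)  # episodes per 1000 stays
    ihap_fraction: float = Field(default=0.10, ge=0, le=1)
    vap_fraction: float = Field(default=0.12, ge=0, le=1)
    background_radiology_rate: float = Field(default=0.5, ge=0)  # per stay-week
    report_negation_rate: float = Field(default=0.35, ge=0, le=1)
    signal_noise: float = Field(default=0.0, ge=0, le=1)
    readmission_rate: float = Field(default=0.05, ge=0, le=0.5)
    seed: int = 0

    @model_validator(mode="after")
    def _feasible(self):
        if self.ihap_fraction + self.vap_fraction > 1:
            raise ValueError("ihap_fraction + vap_fraction must not exceed 1")
        if self.nvhap_incidence > 1000:
            raise ValueError("incidence implies more cases than stays")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioParams":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)


@dataclass(frozen=True)
class Episode:
    """One injected pneumonia episode with its provenance."""

    stay_id: str
    category: Category
    features: CaseFeatures
    event_ids: tuple[str, ...]  # radiology events emitted by the episode
    lab_emitted: bool
    vital_emitted: bool


@dataclass(frozen=True)
class GroundTruth:
    episodes: tuple[Episode, ...]

    def case_ids(self) -> set[str]:
        return {e.stay_id for e in self.episodes}

    def umbrella_ids(self) -> set[str]:
        return {e.stay_id for e in self.episodes if e.category in (Category.NVHAP, Category.IHAP)}


# ---------------------------------------------------------------------------
# report rendering

_FILLERS = [
    "heart size within normal range",
    "degenerative changes of the thoracic spine",
    "comparison with the prior study",
    "central venous line in unchanged position",
    "costophrenic angles are sharp",
]
_POSITIVE = [
    "new {inf} in the right lower lobe",
    "progressive {inf} with air bronchogram",
    "patchy {inf} consistent with pneumonia",
]
_ADVERSARIAL = [
    "{neg} {inf} {res} basal opacity persists",
    "{neg} clear {inf} {res} follow up advised",
]
_SPLIT = "{neg} pleural effusion. new {inf} at the base"
_NEUTRAL = ["findings stable", "unremarkable study"]
_EXCLUDING = [
    "{neg} {inf}",
    "{neg} evidence of {inf}",
    "{neg} pneumonic {inf} visible",
]


def _safe_fillers(terms: TermSet) -> list[str]:
    all_terms = {
        t for lst in (terms.negation_terms, terms.infiltrate_terms, terms.restricting_terms) for t in lst
    }
    out = [s for s in _FILLERS if not set(s.split()) & all_terms]
    return out or ["---"]


def render_report(is_excluding: bool, terms: TermSet, rng: np.random.Generator) -> str:
    """Generate a report whose verdict under :func:`classify_report` is
    guaranteed to match ``is_excluding`` (verified, with a minimal
    fallback), including adversarial negation+restricting templates on the
    non-excluding side."""
    neg = str(rng.choice(terms.negation_terms))
    inf = str(rng.choice(terms.infiltrate_terms))
    res = str(rng.choice(terms.restricting_terms))
    fillers = _safe_fillers(terms)
    sentences = [str(rng.choice(fillers)) for _ in range(int(rng.integers(1, 3)))]

    if is_excluding:
        core = str(rng.choice(_EXCLUDING)).format(neg=neg, inf=inf)
    else:
        kind = rng.choice(["positive", "adversarial", "split", "none"], p=[0.35, 0.25, 0.2, 0.2])
        if kind == "positive":
            core = str(rng.choice(_POSITIVE)).format(inf=inf)
        elif kind == "adversarial":
            core = str(rng.choice(_ADVERSARIAL)).format(neg=neg, inf=inf, res=res)
        elif kind == "split":
            core = _SPLIT.format(neg=neg, inf=inf)
        else:
            core = str(rng.choice(_NEUTRAL))
    pos = int(rng.integers(0, len(sentences) + 1))
    sentences.insert(pos, core)
    text = ". ".join(sentences) + "."

    intended = Verdict.EXCLUDES_PNEUMONIA if is_excluding else Verdict.NOT_EXCLUDING
    if classify_report(text, terms).verdict is not intended:
        # custom term sets may collide with template vocabulary; fall back
        # to the minimal construction
        text = f"{neg} {inf}." if is_excluding else "stable appearance."
        if classify_report(text, terms).verdict is not intended:
            raise SurveillanceError("term set defeats report templating")
    return text


# ---------------------------------------------------------------------------
# generation

def _minutes(rng: np.random.Generator, low_h: float, high_h: float) -> pd.Timedelta:
    return pd.Timedelta(minutes=int(rng.uniform(low_h * 60, high_h * 60)))


def generate_hospital(params: ScenarioParams) -> tuple[SurveillanceDataset, GroundTruth]:
    """Generate one synthetic hospital; byte-identical for a fixed seed."""
    streams = np.random.SeedSequence(params.seed).spawn(7)
    rng_stays, rng_cases, rng_rad, rng_labs, rng_vitals, rng_dev, rng_rep = (
        np.random.default_rng(s) for s in streams
    )
    terms = load_termset(language_tag="de")

    # --- stays ------------------------------------------------------------
    n_re = min(int(round(params.readmission_rate * params.n_stays)), params.n_stays // 2)
    n_primary = params.n_stays - n_re
    adm_min = rng_stays.integers(0, 180 * 24 * 60, size=n_primary)
    los_days = np.clip(
        rng_stays.lognormal(params.los_meanlog, params.los_sdlog, size=n_primary), 0.5, 60.0
    )
    admission = [_EPOCH + pd.Timedelta(minutes=int(m)) for m in adm_min]
    discharge = [a + pd.Timedelta(minutes=int(d * 1440)) for a, d in zip(admission, los_days)]
    patient = [f"P{i:05d}" for i in range(n_primary)]
    dept = [str(rng_stays.choice(_DEPARTMENTS)) for _ in range(n_primary)]

    re_of = rng_stays.choice(n_primary, size=n_re, replace=False) if n_re else np.array([], int)

    n = params.n_stays
    stay_ids = [f"S{i:05d}" for i in range(n)]
    is_readmission = np.zeros(n, bool)
    is_readmission[n_primary:] = True

    # --- case injection ---------------------------------------------------
    p_case = params.nvhap_incidence / 1000.0
    case_mask = rng_cases.random(n) < p_case
    cat_draw = rng_cases.random(n)
    p_nv = 1.0 - params.ihap_fraction - params.vap_fraction

    episodes: list[Episode] = []
    rad_rows: list[dict] = []
    lab_rows: list[dict] = []
    vital_rows: list[dict] = []
    dev_rows: list[dict] = []
    onset_by_stay: dict[int, pd.Timestamp] = {}
    next_event = 0

    def new_event_id() -> str:
        nonlocal next_event
        next_event += 1
        return f"R{next_event:06d}"

    def inject_case(i: int) -> None:
        if not case_mask[i]:
            return
        if cat_draw[i] < p_nv:
            cat = Category.NVHAP
        elif cat_draw[i] < p_nv + params.ihap_fraction:
            cat = Category.IHAP
        else:
            cat = Category.VAP

        adm, dis = admission[i], discharge[i]
        # VAP needs a full 48 h in-stay window before onset
        if is_readmission[i] and cat is not Category.VAP:
            onset = (adm + _minutes(rng_cases, 4, 72)).floor("min")
        else:
            onset = (adm + pd.Timedelta(hours=48) + _minutes(rng_cases, 2, 96)).floor("min")
        if dis < onset + pd.Timedelta(hours=36):
            dis = (onset + pd.Timedelta(hours=36)).floor("min")
            discharge[i] = dis
        onset_by_stay[i] = onset

        eid = new_event_id()
        modality = Modality.CHEST_XRAY if rng_cases.random() < 0.8 else Modality.CHEST_CT
        rad_rows.append(
            {
                "event_id": eid,
                "stay_id": stay_ids[i],
                "ts": onset,
                "modality": modality.value,
                "report_text": render_report(False, terms, rng_rep),
            }
        )

        leukocytosis = rng_cases.random() < 0.85
        leukopenia = not leukocytosis
        signs = {
            s
            for s, p in (
                (ClinicalSign.COUGH, 0.6),
                (ClinicalSign.DYSPNEA, 0.45),
                (ClinicalSign.WORSENING_GAS_EXCHANGE, 0.35),
                (ClinicalSign.PURULENT_SPUTUM, 0.25),
            )
            if rng_cases.random() < p
        }
        if not signs:
            signs = {ClinicalSign(str(rng_cases.choice([s.value for s in ClinicalSign])))}

        lab_emitted = rng_cases.random() >= params.signal_noise
        if lab_emitted:
            value = rng_labs.uniform(12.5, 20.0) if leukocytosis else rng_labs.uniform(1.2, 3.7)
            ts = (onset + _minutes(rng_labs, -24, 24)).floor("min")
            ts = min(max(ts, adm), dis)
            lab_rows.append({"stay_id": stay_ids[i], "ts": ts, "leukocytes": round(value, 1)})
        vital_emitted = rng_cases.random() >= params.signal_noise
        if vital_emitted:
            ts = (onset + _minutes(rng_vitals, -24, 24)).floor("min")
            ts = min(max(ts, adm), dis)
            vital_rows.append(
                {"stay_id": stay_ids[i], "ts": ts, "temperature": round(rng_vitals.uniform(38.3, 39.8), 1)}
            )

        win_start = onset - pd.Timedelta(hours=48)
        if cat is Category.NVHAP:
            if rng_dev.random() < 0.15:
                if win_start > adm + pd.Timedelta(hours=1):
                    intub = adm + _minutes(rng_dev, 0, (win_start - adm) / pd.Timedelta(hours=1) / 2)
                    boundary = rng_dev.random() < 0.3
                    extub = win_start if boundary else intub + _minutes(
                        rng_dev, 0.5, (win_start - intub) / pd.Timedelta(hours=1)
                    )
                    dev_rows.append(
                        {"stay_id": stay_ids[i], "intubation_ts": intub.floor("min"), "extubation_ts": min(extub, win_start).floor("min")}
                    )
                elif dis > onset + pd.Timedelta(hours=13):
                    intub = (onset + _minutes(rng_dev, 1, 12)).floor("min")
                    dev_rows.append(
                        {"stay_id": stay_ids[i], "intubation_ts": intub, "extubation_ts": (intub + pd.Timedelta(hours=6)).floor("min")}
                    )
        elif cat is Category.IHAP:
            intub = max(adm, onset - _minutes(rng_dev, 8, 46)).floor("min")
            extub = (onset - _minutes(rng_dev, 0.5, 6)).floor("min")
            if extub <= intub:
                extub = (intub + pd.Timedelta(minutes=30)).floor("min")
            dev_rows.append({"stay_id": stay_ids[i], "intubation_ts": intub, "extubation_ts": extub})
        else:  # VAP: continuously intubated throughout the window
            intub = max(adm, onset - _minutes(rng_dev, 49, 120)).floor("min")
            still = rng_dev.random() < 0.5
            extub = None if still else min(dis, onset + _minutes(rng_dev, 1, 24)).floor("min")
            dev_rows.append({"stay_id": stay_ids[i], "intubation_ts": intub, "extubation_ts": extub})

        features = CaseFeatures(
            stay_id=stay_ids[i],
            onset_ts=onset,
            radiological_signs=True,
            fever=True,
            leukopenia=leukopenia,
            leukocytosis=leukocytosis,
            clinical_signs=frozenset(signs),
            hospital_acquired=True,
        )
        episodes.append(
            Episode(
                stay_id=stay_ids[i],
                category=cat,
                features=features,
                event_ids=(eid,),
                lab_emitted=lab_emitted,
                vital_emitted=vital_emitted,
            )
        )

    # inject primary-stay cases first: their discharge may be extended, and
    # readmission children must start after the final parent discharge
    for i in range(n_primary):
        inject_case(i)

    for idx in re_of:
        gap = pd.Timedelta(minutes=int(rng_stays.uniform(120, 10 * 1440 - 60)))
        a = discharge[idx] + gap
        d = a + pd.Timedelta(
            minutes=int(np.clip(rng_stays.lognormal(params.los_meanlog, params.los_sdlog), 0.5, 60.0) * 1440)
        )
        admission.append(a)
        discharge.append(d)
        patient.append(patient[idx])
        dept.append(str(rng_stays.choice(_DEPARTMENTS)))

    for i in range(n_primary, n):
        inject_case(i)

    # --- background events (all stays) ------------------------------------
    for i in range(n):
        adm, dis = admission[i], discharge[i]
        los_d = (dis - adm) / pd.Timedelta(days=1)
        span_min = int((dis - adm) / pd.Timedelta(minutes=1))

        for _ in range(rng_rad.poisson(params.background_radiology_rate * los_d / 7.0)):
            ts = (adm + pd.Timedelta(minutes=int(rng_rad.uniform(0, span_min)))).floor("min")
            u = rng_rad.random()
            modality = Modality.CHEST_XRAY if u < 0.7 else (Modality.CHEST_CT if u < 0.85 else Modality.OTHER)
            excl = modality is not Modality.OTHER and rng_rad.random() < params.report_negation_rate
            rad_rows.append(
                {
                    "event_id": new_event_id(),
                    "stay_id": stay_ids[i],
                    "ts": ts,
                    "modality": modality.value,
                    "report_text": render_report(excl, terms, rng_rep),
                }
            )

        for _ in range(rng_labs.poisson(max(los_d, 1.0) / 3.0)):
            ts = (adm + pd.Timedelta(minutes=int(rng_labs.uniform(0, span_min)))).floor("min")
            value = rng_labs.uniform(12.5, 16.0) if rng_labs.random() < 0.03 else rng_labs.uniform(4.5, 11.0)
            lab_rows.append({"stay_id": stay_ids[i], "ts": ts, "leukocytes": round(value, 1)})

        for _ in range(1 + rng_vitals.poisson(max(los_d, 1.0) / 2.0)):
            ts = (adm + pd.Timedelta(minutes=int(rng_vitals.uniform(0, span_min)))).floor("min")
            temp = rng_vitals.uniform(38.2, 39.0) if rng_vitals.random() < 0.03 else rng_vitals.uniform(36.2, 37.7)
            vital_rows.append({"stay_id": stay_ids[i], "ts": ts, "temperature": round(temp, 1)})

        if not case_mask[i] and rng_dev.random() < 0.02 and los_d > 1.0:
            intub = (adm + pd.Timedelta(minutes=int(rng_dev.uniform(0, span_min / 2)))).floor("min")
            max_h = min(72.0, (dis - intub) / pd.Timedelta(hours=1) - 0.5)
            if max_h > 6.0:
                extub = None if rng_dev.random() < 0.1 else (intub + _minutes(rng_dev, 6, max_h)).floor("min")
                dev_rows.append({"stay_id": stay_ids[i], "intubation_ts": intub, "extubation_ts": extub})

    # --- discharge ICD codes ----------------------------------------------
    icd: list[tuple[str, ...]] = []
    for i in range(n):
        codes = list(
            rng_stays.choice(_ICD_POOL, size=int(rng_stays.integers(0, 4)), replace=False)
        )
        has_hap = case_mask[i] and rng_stays.random() < 0.8
        miscode = (not case_mask[i]) and rng_stays.random() < 0.004
        if has_hap or miscode:
            codes.append(_HAP_CODE)
        icd.append(tuple(codes))

    stays = pd.DataFrame(
        {
            "stay_id": stay_ids,
            "patient_id": patient,
            "admission_ts": pd.to_datetime([a.floor("min") for a in admission]),
            "discharge_ts": pd.to_datetime([d.floor("min") for d in discharge]),
            "department": dept,
            "icd_codes": icd,
        }
    )
    stays = link_readmissions(stays)

    def frame(rows: list[dict], columns: list[str], ts_cols: list[str]) -> pd.DataFrame:
        if not rows:
            df = pd.DataFrame(columns=columns)
        else:
            df = pd.DataFrame(rows, columns=columns)
        for c in ts_cols:
            df[c] = pd.to_datetime(df[c] if len(df) else pd.Series(dtype="datetime64[ns]"))
        return df

    dataset = SurveillanceDataset(
        stays=stays,
        radiology=frame(rad_rows, ["event_id", "stay_id", "ts", "modality", "report_text"], ["ts"]),
        labs=frame(lab_rows, ["stay_id", "ts", "leukocytes"], ["ts"]),
        vitals=frame(vital_rows, ["stay_id", "ts", "temperature"], ["ts"]),
        devices=frame(dev_rows, ["stay_id", "intubation_ts", "extubation_ts"], ["intubation_ts", "extubation_ts"]),
        available_streams=frozenset(Indicator),
    )
    return dataset, GroundTruth(tuple(episodes))


def features_for_all_stays(
    dataset: SurveillanceDataset, ground_truth: GroundTruth
) -> dict[str, CaseFeatures]:
    """Per-stay structured features for the emulated manual reference:
    episode features for case stays, all-negative features otherwise."""
    features = {e.stay_id: e.features for e in ground_truth.episodes}
    for row in dataset.stays.itertuples():
        if row.stay_id not in features:
            features[row.stay_id] = CaseFeatures(
                stay_id=row.stay_id,
                onset_ts=row.admission_ts,
                radiological_signs=False,
                fever=False,
                leukopenia=False,
                leukocytosis=False,
                clinical_signs=frozenset(),
                hospital_acquired=False,
            )
    return features


GROUND_TRUTH_COLUMNS = [
    "stay_id",
    "category",
    "onset_ts",
    "radiological_signs",
    "fever",
    "leukopenia",
    "leukocytosis",
    "clinical_signs",
    "hospital_acquired",
    "event_ids",
]


def ground_truth_frame(ground_truth: GroundTruth) -> pd.DataFrame:
    rows = [
        {
            "stay_id": e.stay_id,
            "category": e.category.value,
            "onset_ts": e.features.onset_ts.strftime("%Y-%m-%dT%H:%M"),
            "radiological_signs": int(e.features.radiological_signs),
            "fever": int(e.features.fever),
            "leukopenia": int(e.features.leukopenia),
            "leukocytosis": int(e.features.leukocytosis),
            "clinical_signs": "|".join(sorted(s.value for s in e.features.clinical_signs)),
            "hospital_acquired": int(e.features.hospital_acquired),
            "event_ids": "|".join(e.event_ids),
        }
        for e in ground_truth.episodes
    ]
    return pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


def write_scenario(
    dataset: SurveillanceDataset,
    ground_truth: GroundTruth,
    directory: str | Path,
    params: ScenarioParams | None = None,
) -> dict[str, Path]:
    """Write the five stream CSVs plus ground_truth.csv and the generating
    parameters; :func:`nvhap.ehr_model.load_dataset` round-trips the
    result."""
    directory = Path(directory)
    paths = write_dataset(dataset, directory)
    gt_path = directory / "ground_truth.csv"
    ground_truth_frame(ground_truth).to_csv(gt_path, index=False, lineterminator="\n")
    paths["ground_truth"] = gt_path
    if params is not None:
        params_path = directory / "params.yaml"
        params_path.write_text(yaml.safe_dump(params.model_dump(), sort_keys=True), encoding="utf-8")
        paths["params"] = params_path
    return paths


def load_scenario(directory: str | Path) -> tuple[SurveillanceDataset, pd.DataFrame]:
    """Load a written scenario directory; returns the dataset and the raw
    ground-truth table (empty when absent)."""
    directory = Path(directory)
    paths = {
        name: directory / f"{name}.csv"
        for name in ("stays", "radiology", "labs", "vitals", "devices")
        if (directory / f"{name}.csv").exists()
    }
    dataset = load_dataset(paths, declared_streams=frozenset(Indicator))
    gt_path = directory / "ground_truth.csv"
    gt = (
        pd.read_csv(gt_path, dtype=str, keep_default_na=False)
        if gt_path.exists()
        else pd.DataFrame(columns=GROUND_TRUTH_COLUMNS)
    )
    return dataset, gt
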