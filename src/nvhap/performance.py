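"""Validation statistics for semi-automated nvHAP surveillance.

Sensitivity is the fraction of reference-standard nvHAP cases (umbrella:
NVHAP + IHAP) that appear on the preselected list; the workload fraction
is the share of the surveilled population that must be manually reviewed;
NNS (number needed to screen) is preselected stays reviewed per detected
case.  Sample-size planning for a sensitivity validation uses the normal
approximation n = ceil(z² p(1−p) / m²) — e.g. demonstrating 95%
sensitivity to ±5% at 95% confidence needs 73 cases — with an
exact-binomial alternative.

Interval choices (the source protocols do not state theirs): exact
Clopper–Pearson for sensitivity — sensitivity estimates sit at or near
100%, where exact intervals are the defensible default and reproduce the
printed "100% (95% CI: 92.6–100)" form at n = 48 — and Wilson for the
workload fraction.  Both are selectable.

Only aggregate quantities leave this module: a serialized
:class:`PerformanceReport` carries counts and proportions, never stay or
patient identifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .case_classification import CaseLabel, NVHAP_UMBRELLA, umbrella_case_ids
from .ehr_model import SurveillanceDataset, SurveillanceError
from .preselection import AlgorithmConfig, PreselectionResult, preselect, preselected_ids


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with a two-sided confidence interval."""

    x: int
    n: int
    point: float
    ci_lower: float
    ci_upper: float
    method: str
    confidence: float = 0.95

    def as_percent(self) -> tuple[float, float, float]:
        return (100 * self.point, 100 * self.ci_lower, 100 * self.ci_upper)

    def __str__(self) -> str:
        p, lo, hi = self.as_percent()
        return f"{p:.1f}% (95% CI: {lo:.1f}-{hi:.1f})"


_CI_METHODS = {"clopper-pearson": "beta", "wilson": "wilson"}


def proportion_ci(x: int, n: int, method: str = "clopper-pearson", confidence: float = 0.95) -> ProportionEstimate:
    if n <= 0:
        raise SurveillanceError("proportion undefined for n = 0")
    if not 0 <= x <= n:
        raise SurveillanceError(f"count {x} outside [0, {n}]")
    lo, hi = proportion_confint(x, n, alpha=1 - confidence, method=_CI_METHODS[method])
    lo = 0.0 if x == 0 else float(lo)  # exact at the degenerate endpoints
    hi = 1.0 if x == n else float(hi)
    return ProportionEstimate(x, n, x / n, lo, hi, method, confidence)


def sensitivity(
    preselected: Iterable[str] | Iterable[PreselectionResult],
    reference_labels: Sequence[CaseLabel],
    method: str = "clopper-pearson",
) -> ProportionEstimate:
    """Detected / reference nvHAP cases, with an exact 95% CI by default.

    ``preselected`` is a set of stay ids or the preselection results.
    Errors when the reference contains no nvHAP-umbrella cases.
    """
    pre = _as_id_set(preselected)
    cases = umbrella_case_ids(reference_labels)
    if not cases:
        raise SurveillanceError("sensitivity undefined: zero reference nvHAP cases")
    detected = len(cases & pre)
    return proportion_ci(detected, len(cases), method=method)


def workload_fraction(
    n_preselected: int, n_population: int, method: str = "wilson"
) -> ProportionEstimate:
    """Share of the surveilled population flagged for manual review."""
    if n_population <= 0:
        raise SurveillanceError("workload undefined: zero population")
    if n_preselected > n_population:
        raise SurveillanceError("preselected exceeds population")
    return proportion_ci(n_preselected, n_population, method=method)


def nns(n_preselected: int, n_detected: int) -> float:
    """Number needed to screen: preselected stays per detected case.

    Returns NaN (the undefined marker) when nothing was detected.
    """
    if n_detected < 0 or n_preselected < 0:
        raise SurveillanceError("counts must be non-negative")
    if n_detected > n_preselected:
        raise SurveillanceError("detected cases cannot exceed preselected stays")
    if n_detected == 0:
        return math.nan
    return n_preselected / n_detected


def sample_size_sensitivity(
    expected_sensitivity: float,
    margin: float,
    confidence: float = 0.95,
    method: str = "normal",
) -> int:
    """Cases needed to demonstrate a sensitivity to ± ``margin``.

    ``method='normal'``: ceil(z² p(1−p) / m²), z the two-sided normal
    quantile — (0.95, 0.05, 0.95) → 73.  ``method='exact'``: smallest n
    whose Clopper–Pearson interval at x = round(p·n) lies within
    [p − m, p + m].
    """
    p, m = expected_sensitivity, margin
    if not 0 < p < 1:
        raise SurveillanceError("expected sensitivity must be strictly between 0 and 1")
    if not 0 < m < 1:
        raise SurveillanceError("margin must be strictly between 0 and 1")
    if method == "normal":
        z = stats.norm.ppf(0.5 + confidence / 2)
        return math.ceil(z * z * p * (1 - p) / (m * m))
    if method == "exact":
        for n in range(1, 100_000):
            x = round(p * n)
            lo, hi = proportion_confint(x, n, alpha=1 - confidence, method="beta")
            if max(p - m, 0.0) <= lo and hi <= min(p + m, 1.0):
                return n
        raise SurveillanceError("no feasible exact sample size below 100000")
    raise SurveillanceError(f"unknown sample-size method {method!r}")


def build_validation_cohort(
    dataset: SurveillanceDataset,
    icd_prefix: str = "U69.0",
    n_random: int = 200,
    min_los_days: float = 14,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Enriched validation cohort: every stay carrying a discharge ICD code
    in the given family (dots ignored), plus up to ``n_random`` randomly
    sampled further stays of at least ``min_los_days`` length.

    Returns a sorted, deduplicated list of stay ids; identical for
    identical seeds.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    prefix = icd_prefix.replace(".", "").upper()
    stays = dataset.stays

    def coded(codes: tuple[str, ...]) -> bool:
        return any(c.replace(".", "").upper().startswith(prefix) for c in codes)

    coded_ids = set(stays.loc[stays["icd_codes"].map(coded), "stay_id"])
    los = stays["discharge_ts"] - stays["admission_ts"]
    long_stay = los >= pd.Timedelta(days=min_los_days)
    eligible = sorted(set(stays.loc[long_stay, "stay_id"]) - coded_ids)
    k = min(n_random, len(eligible))
    sampled = rng.choice(np.array(eligible, dtype=object), size=k, replace=False) if k else []
    return sorted(coded_ids | set(sampled))


@dataclass(frozen=True)
class PerformanceReport:
    """Aggregate validation report; contains no stay or patient ids."""

    n_population: int
    n_preselected: int
    n_reference_cases: int
    n_detected_cases: int
    sensitivity: ProportionEstimate
    workload_fraction: ProportionEstimate
    nns: float
    config_fingerprint: str

    def to_dict(self) -> dict:
        s_pct, s_lo, s_hi = self.sensitivity.as_percent()
        w_pct, w_lo, w_hi = self.workload_fraction.as_percent()
        return {
            "n_population": self.n_population,
            "n_preselected": self.n_preselected,
            "n_reference_cases": self.n_reference_cases,
            "n_detected_cases": self.n_detected_cases,
            "sensitivity_pct": round(s_pct, 1),
            "sensitivity_ci_lower_pct": round(s_lo, 1),
            "sensitivity_ci_upper_pct": round(s_hi, 1),
            "workload_pct": round(w_pct, 1),
            "workload_ci_lower_pct": round(w_lo, 1),
            "workload_ci_upper_pct": round(w_hi, 1),
            "nns": None if math.isnan(self.nns) else round(self.nns, 1),
            "config_fingerprint": self.config_fingerprint,
        }

    def __str__(self) -> str:
        nns_txt = "undefined" if math.isnan(self.nns) else f"{self.nns:.1f}"
        return (
            f"population={self.n_population} preselected={self.n_preselected} "
            f"reference_cases={self.n_reference_cases} detected={self.n_detected_cases}\n"
            f"sensitivity: {self.sensitivity}\n"
            f"workload:    {self.workload_fraction}\n"
            f"NNS:         {nns_txt}"
        )


def _as_id_set(preselected) -> set[str]:
    items = list(preselected)
    if items and isinstance(items[0], PreselectionResult):
        return preselected_ids(items)
    return set(items)


def evaluate(
    dataset: SurveillanceDataset,
    config: AlgorithmConfig,
    reference_labels: Sequence[CaseLabel],
    cohort: Iterable[str] | None = None,
    sensitivity_ci: str = "clopper-pearson",
    workload_ci: str = "wilson",
) -> PerformanceReport:
    """Run preselection and assemble the aggregate performance report.

    With ``cohort`` given, population, preselection and reference are all
    restricted to those stays (the enriched validation-cohort workflow).
    """
    results = preselect(dataset, config)
    pre = preselected_ids(results)
    population = set(dataset.stays["stay_id"])
    cases = umbrella_case_ids(reference_labels)
    if cohort is not None:
        cohort = set(cohort)
        population &= cohort
        pre &= cohort
        cases &= cohort
    if not cases:
        raise SurveillanceError("sensitivity undefined: zero reference nvHAP cases")
    detected = len(cases & pre)
    sens = proportion_ci(detected, len(cases), method=sensitivity_ci)
    work = workload_fraction(len(pre), len(population), method=workload_ci)
    return PerformanceReport(
        n_population=len(population),
        n_preselected=len(pre),
        n_reference_cases=len(cases),
        n_detected_cases=detected,
        sensitivity=sens,
        workload_fraction=work,
        nns=nns(len(pre), detected),
        config_fingerprint=config.fingerprint(),
    )
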