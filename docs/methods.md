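# Methods

## The surveillance problem

Nonventilator hospital-acquired pneumonia (nvHAP) is a frequent and
under-surveilled healthcare-associated infection.  Exhaustive manual chart
review of every hospitalization is infeasible outside research settings,
so this package implements *semi-automated* surveillance: a rule-based
algorithm preselects a small candidate list from routine EHR streams, and
human reviewers confirm or reject only those candidates.  The design goal
is near-perfect sensitivity — a case that never reaches the candidate
list is lost for good, while a false candidate only costs review minutes.

## The preselection algorithm

A stay enters the candidate list when it has at least one *chest radiology
procedure of relevance*.  Relevance is a conjunction over the indicator
streams the hospital has enabled:

| indicator            | rule                                                                 | parameters (defaults) |
|----------------------|----------------------------------------------------------------------|-----------------------|
| radiology procedure  | chest image (X-ray/CT) strictly > 48 h after admission, or anytime during a ≤ 10-day readmission | `min_hours_after_admission` = 48 h, `readmission_gap_days` = 10 |
| radiology report     | report does not explicitly rule out pneumonia (text rule below)      | term set |
| leukocytes           | some count within ± 48 h of the image is < 4.0 or ≥ 12.0 ×10⁹/L      | `lab_window_hours` = 48, thresholds 4.0 / 12.0 |
| body temperature     | some measurement within ± 48 h of the image is > 38.0 °C             | `temp_window_hours` = 48, threshold 38.0 °C |
| intubation           | patient NOT continuously intubated throughout the 48 h before the image | `vap_exclusion_hours` = 48 |

The radiology-procedure indicator is the mandatory minimum; the other
four are optional and individually switchable, which is what makes the
algorithm portable across hospitals with different data availability.
Disabled or unavailable indicators are *non-vetoing*: they evaluate to
"not applicable" rather than false, so absence of a data feed can never
suppress a candidate.  A direct consequence is antitone behaviour under
nesting: adding indicators can only shrink the candidate list, so reduced
algorithms are at least as sensitive and at most as workload-efficient as
the full five-indicator algorithm.  This monotonicity is property-tested,
not assumed.

Boundary semantics are deliberate and tested: the post-admission rule is
a strict inequality (an image at exactly +48.0 h does not qualify); the
signal windows are closed (a lab exactly 48 h from the image counts); the
leukocytosis threshold is inclusive (≥ 12.0) and the fever threshold
strict (> 38.0 °C), matching the ECDC-style definition the thresholds are
taken from.  The temporal windows around the image were not published for
the original system; we use symmetric ± 48 h windows and expose every
window and threshold as configuration rather than constants.

## The report text rule

A chest image is dropped from the candidate list when its report
*explicitly rules out* pneumonia: at least one sentence contains a
negation term ("no", "kein", …) and an infiltrate term ("infiltrate",
"Infiltrat", …) and no *restricting* term ("but", "left", …).  A
restricting term signals a qualified or lateralized negation, which must
still go to review.  Matching is whole-word, case-insensitive and
diacritics-folded; there is no stemming — inflections are enumerated in
the term set.  Sentences split on `.`, `!`, `?`, `;` and newlines;
abbreviations are not special-cased because a mis-split can only make
the rule *more* conservative (the sentence loses the negation/infiltrate
co-occurrence and the image stays on the list).

The bundled German-style and French-style term sets are reconstructions
from the published rule sketch — the original hospital lists are not
public — and are configuration, not code.  Every ambiguity resolves to
NOT_EXCLUDING, the fail-safe direction.

## Case definition and the nvHAP/iHAP/VAP split

The reference standard emulates full manual surveillance as a
deterministic classifier on structured features.  Pneumonia is confirmed
when radiological signs, at least one systemic sign (fever > 38 °C,
leukopenia < 4, or leukocytosis ≥ 12 ×10⁹/L) and at least one clinical
sign (cough, dyspnea, worsening gas exchange, purulent sputum) coincide,
with onset > 48 h after admission or during a qualifying readmission.
Confirmed cases split by intubation history in the 48 h before onset:

* **VAP** — continuously intubated throughout the window (excluded from
  nvHAP surveillance);
* **NVHAP** — never intubated within the window;
* **iHAP** — intubated *and* extubated within the window.

Downstream counts treat nvHAP as an umbrella including iHAP and always
excluding VAP.  Two definitional gaps had to be closed:

* The window is half-open, `(onset − 48 h, onset]`: extubation exactly at
  onset − 48 h counts as never intubated within the window.
* A patient intubated during part of the window and still intubated at
  onset matches neither published sentence.  We classify this cell as
  iHAP (VAP is defined by the full-window condition) and make it
  configurable to VAP; occurrences are logged.

Abutting device episodes merge, so splitting one episode into contiguous
parts never changes the category (tested by property).  The two-tier
human review is emulated by a deterministic escalation rule (escalate
when the only clinical sign is worsening gas exchange); escalation never
changes the label — it exists to exercise the review audit trail.

## Validation statistics

* **Sensitivity** = detected / reference nvHAP cases, with an exact
  Clopper–Pearson 95% interval (via `statsmodels`; the test suite checks
  the bounds against an independent binomial tail inversion).  Exact
  intervals are the defensible default when the point estimate sits at
  100%, where Wald intervals collapse; at 48/48 detected the interval
  prints as 100% (95% CI: 92.6–100).
* **Workload fraction** = preselected / population, with a Wilson 95%
  interval (good coverage at small proportions; a seeded 10,000-replicate
  simulation in the tests checks ≥ 94% empirical coverage).  The original
  reports do not name their interval procedures; both choices are
  selectable in the API.
* **NNS** = preselected / detected; NaN marks the undefined 0-detected
  case.
* **Sample size** for validating a sensitivity `p` to ± `m`:
  `ceil(z² p(1−p)/m²)`; at (0.95, 0.05, 95% confidence) this gives 73
  cases.  An exact-binomial planning mode (smallest `n` whose
  Clopper–Pearson interval fits inside ± `m`) is available as an
  alternative.
* **Validation cohort**: because nvHAP is rare, validation cohorts are
  enriched — all stays with a discharge ICD code in the U69.0x family
  (prefix match on dot-stripped codes) plus a seeded random sample of up
  to 200 further stays of ≥ 14 days.

The surveillance unit throughout is the *stay*, not the patient: a
patient with two qualifying stays counts twice in both numerators and
denominators.  Performance reports are aggregate-only by construction —
no stay or patient identifier appears in a serialized report, mirroring
the federated setting where only aggregates leave each hospital.

## The synthetic hospital

No real surveillance data is available, so the generator is the test
substrate.  The default scenario is a desk-scale general hospital:
5 000 stays admitted over 180 days, log-normal length of stay
(`meanlog` 1.4, `sdlog` 0.7 log-days; median ≈ 4 days, clipped to
0.5–60 days), nvHAP incidence 10 / 1 000 stays, 10% of episodes iHAP and
12% VAP, background chest-imaging rate 0.5 per stay-week, 35% of
non-case reports explicitly excluding pneumonia, 5% of stays being
≤ 10-day readmissions, and `signal_noise = 0`.

Injected episodes are internally consistent by construction: the
features satisfy the case definition (fever plus one leukocyte
abnormality are always present so that every enabled indicator has a
signal to find), the emitted events match the features, and the device
layout matches the label's window condition.  `signal_noise` is the
probability that a case's lab or temperature *record* is missing while
the chart feature remains true — the reviewer still confirms the case,
but an indicator-rich algorithm may miss it.  This single dial produces
the realistic trade-off: with noise, reduced algorithms keep 100%
sensitivity while the full algorithm loses cases, and workload moves the
opposite way.

Report texts are template-rendered from the active term set (with
adversarial negation+infiltrate+restricting sentences on the
non-excluding side) and verified against the classifier at render time.
One RNG stream per output table, all spawned from the scenario seed,
keeps generation reproducible under extension; fixed seeds give
byte-identical CSV output.

What the generator does *not* emulate — and hence what green tests do not
show about real data: free-text clinical notes (clinical signs are
structured flags), realistic ICD coding practice, radiology-report prose
beyond the templates, multi-episode stays (at most one pneumonia episode
per stay), inter-hospital heterogeneity, and any calibration to real
length-of-stay or incidence distributions.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run entirely on generated
data sized for a desktop: one clean 5 000-stay hospital for the
sensitivity-by-construction check (all 16 indicator subsets), twenty
(tests) / ten (script) noisy 500-stay hospitals for the monotonicity
checks, one hundred 200-stay hospitals for the naive-oracle equivalence
checks, 1 000 rendered reports for the text-rule round trip, and 3 000
random device layouts for the partition fuzz.

## Known limitations

* The reconstructed term sets are placeholders; production use requires
  locally curated lists.
* Symptom onset is operationalized as the timestamp of the episode's
  first qualifying chest image; manual reviewers may date onset
  differently.
* Indicator signals are evaluated relative to the radiology timestamp,
  not to an independently derived symptom-onset time.
* The ECDC definition is implemented at the summary level; the
  microbiology strata (PN1–PN5) are out of scope.
* Leukocyte values are fixed to ×10⁹/L; no unit auto-detection, by
  design (silent unit guessing is a classic surveillance bug).
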