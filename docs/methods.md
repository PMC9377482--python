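# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data does and does not emulate, and
the design choices made where the design was genuinely open.

## FHIR exchange

The platform exchanges FHIR R4 JSON `Bundle` documents of type `collection` —
the simplest shape for a one-shot CDS request. Five resource types are typed
(Patient, Encounter, Observation, MedicationRequest, ServiceRequest); anything
else is carried opaquely with its raw JSON preserved, so real-world bundles
degrade gracefully instead of failing. Serialization is the exact inverse of
parsing: `parse ∘ serialize` is the identity at field level, entry order
preserved.

Timestamps are ISO-8601; naive values are interpreted as UTC, which keeps
behaviour deterministic across machines. Invariant checking is split in two
deliberately: structural violations that prevent typing a resource at all
(both or neither of `valueQuantity`/`valueCodeableConcept` present, unknown
status or encounter class, empty codes) raise at parse time, while soft
violations (unparseable timestamps, duplicate entry ids, birth date after
encounter start) are collected as `ValidationIssue` data by `validate_bundle`
— issues are data, not exceptions, so a validator can report all of them at
once and in-memory bundles can be inspected the same way as parsed ones.

## Vocabulary and preprocessing

A bundled mini-vocabulary (CSV, versioned with the package) maps LOINC codes
for the eleven measured sepsis inputs plus triage vitals to canonical feature
names, OMOP concept ids, and canonical units. Order-type concepts are classes,
not point codes: "antibiotic" means any ATC code under `J01`,
"vasopressor/inotrope" any code under `C01CA`, and blood culture is the SNOMED
procedure 30088009. Unit conversion is a small registry (°F→°C, %→fraction,
kPa→mmHg, platelet-count aliases) rather than a complete UCUM algebra; every
conversion is idempotent once a value is in canonical units.

Feature extraction is latest-value-wins inside a per-engine lookback window
(default 24 h — the common CDS convention for "current" values): for each
declared feature, the newest `final` Observation within
`[reference_time − lookback, reference_time]` is selected, unit-normalized,
and stamped with provenance. Ties in observed time are broken by bundle entry
order, later entry winning, which makes extraction deterministic.
Preliminary-status observations never feed decisions. Order features are
booleans — true iff a matching active/completed request exists in-window —
so an absent order is `False`, not missing. Mental status arrives either as a
numeric GCS observation or as a coded AVPU value; the AVPU→GCS convention is
A→15, V→12, P→8, U→3 (a coarse but standard bedside mapping). Required
features with no in-window source land in the record's `missing` set and the
preprocessing log; missingness is data all the way down.

## SepsTreat rules

Screening: temperature strictly above 37.5 °C AND (blood culture ordered OR
antibiotics ordered). The inequality is strict — 37.5 °C itself does not
screen in — and a missing temperature screens out with a note.

qSOFA cutoffs (SBP ≤ 100 mmHg, RR ≥ 22/min, GCS < 15, positive at ≥ 2) and
the six-organ SOFA stratum table follow the Sepsis-3 consensus definitions.
The table ships as a data file of half-open intervals `[min, max)` per organ
variable, so boundary behaviour is explicit (e.g. bilirubin 2.0 mg/dL scores
liver 2, platelets 150 score coagulation 0). Both scores are always computed
and reported — qSOFA as the rapid signal, SOFA as the sepsis criterion —
rather than gating SOFA behind qSOFA positivity.

Decisions where the input schema forces a choice:

* **MAP** is derived as (SBP + 2·DBP)/3, the standard formula, because the
  schema carries SBP/DBP rather than MAP.
* **Cardiovascular with vasopressors**: the order flag is boolean, with no
  agent or dose, so it cannot distinguish the dose-based strata 2–4; an
  existing order scores the middle pressor stratum, 3. Consequently the
  engine's reachable SOFA ceiling through this schema is 23, not 24.
* **Baseline SOFA is assumed 0** (no prior-encounter data in a one-shot
  request), so sepsis = screened-in ∧ SOFA ≥ 2. This overcalls patients with
  chronic organ dysfunction; a known limitation.
* **Missing organs score 0** and are listed in `missing_organs` —
  conservative floor behaviour matching bedside practice, never imputation.
* Septic shock = sepsis ∧ vasopressor order ∧ lactate > 2 mmol/L. The
  consensus definition's "despite adequate volume resuscitation" clause is
  not observable in the schema and is therefore not enforced.

The treatment list is the five hour-1-bundle-style items (lactate, cultures
before antibiotics, broad-spectrum antibiotics, 30 mL/kg crystalloid for
hypotension or lactate ≥ 4, vasopressors for MAP < 65 after fluids), shipped
as a replaceable JSON data file. Completion marks are inferred from the input:
lactate item ↔ a lactate value present, cultures/antibiotics/vasopressors ↔
their order flags. Fluid administration is invisible to the schema, so the
crystalloid item is never auto-marked.

Present values are validated against plausibility bounds (temperature
25–45 °C, FiO₂ 0.21–1.0, GCS 3–15, …) at construction; this also excludes the
FiO₂ = 0 division hazard in the PaO₂/FiO₂ ratio by construction.

## Triage model

The engine contract is model-agnostic; the default is one unpenalized
logistic-regression head per outcome (mortality, critical care,
hospitalization — three independent binary heads, because the outcomes
co-occur), with an optional one-hidden-layer ReLU network. This is an honest
desk-scale stand-in for the deep model the platform originally hosted, not a
reproduction of it.

Encoding (frozen, version "1", 42 coordinates): numeric fields are
standardized with fixed population constants (e.g. age (x−50)/20,
SBP (x−120)/20) so coefficients are comparable across features and fits are
well-conditioned; a missing numeric contributes a zero fill plus a
missingness indicator. Categorical fields are indicator-coded against frozen
vocabularies with the first category as reference (sex female, arrival
walk-in, AVPU A, chief complaint "other") — reference coding keeps the design
full-rank, so the unpenalized maximum-likelihood fit is identifiable and
recovers generating coefficients on synthetic data. The chief-complaint
vocabulary is a frozen 20-item list; unknown codes bucket to "other".

Training splits rows by a seeded permutation (default 25 % test), fits with
L-BFGS to tolerance 1e-8, verifies all parameters finite (degenerate
single-class outcomes fail loudly, naming the outcome), and records AUROC on
both splits. Risk bands are the quintile edges (20/40/60/80th percentiles) of
the training-set predicted probabilities per outcome, frozen into the
artifact; band = 1 + number of edges strictly below the probability. A
prediction's headline band is the worst per-outcome band, so a patient
extreme on any single outcome surfaces as high-risk. The artifact is a
versioned JSON document; prediction refuses artifacts whose encoding version
differs from the encoder's.

## Federated summaries

Cohorts resolve against a minimal OMOP-like store (person, visit, measurement,
drug_exposure, condition, death as delimited tables; foreign keys validated on
load). A summary report has one cell per drug concept among cohort members
plus outcome cells (in-hospital death, hospitalization — the fixture cohort's
outcome pair). Suppression: any cell with 0 < count < k is marked suppressed
and its count and rate are withheld on the wire; k defaults to 10. Zero counts
stay visible — revealing absence is an accepted threat-model choice
(configurable by suppressing at the source if a site disagrees). Merging sums
counts over sites where a cell is unsuppressed, marks cells suppressed
anywhere as partially suppressed with the contributing-site count, and
re-suppresses the merged cells at the same k. Re-suppression only partially
prevents reconstruction by differencing across overlapping cohort requests;
eliminating that residual risk (differential privacy etc.) is out of scope
and documented as such.

The privacy gate is structural: a recursive schema validator rejects any
exchanged payload containing person-level field names (`person_id`,
`birth_date`, `visit_id`, …), and the only timestamp a report carries is its
own generation time. Peer transport degrades, never raises: an unreachable or
non-conforming peer becomes a typed `PeerUnavailable` marker and the CDS
response renders without it.

## Orchestration

`handle_request` is a deterministic pipeline: extract features per the
engine's descriptor → run the engine → optionally gather peer summaries →
compose the display payload. Engines are in-process plugins (descriptor +
callable) in a registry keyed by (name, version); the platform ships two.
Errors are typed response documents — unknown engine, engine failure — so the
calling EHR can always render something. The display payload has ordered
sections (headline scores; recommendations when the result carries them; peer
statistics when peers were asked; data-quality notes from the preprocessing
log) and contains no number that does not trace to an engine result or a
summary report. The HTTP surface is a thin stdlib server exposing the same
operations (`POST /cds/{engine}`, `GET /engines`, `POST /summary`); peers and
CDS clients share one wire format. Intervention is strictly on-demand — there
is no push alerting.

## Synthetic fixtures

The generator emulates single-visit ED/inpatient encounters: a septic flag at
configurable prevalence (default 0.3, a sick referral-stream rate), vitals and
labs drawn from truncated normal distributions with separate normal/deranged
parameter sets per septic status, order flags with per-status probabilities
(e.g. blood culture 0.9 | septic vs 0.08 | non-septic), 10 % per-lab
missingness, and outcome draws for death and admission. Triage outcomes are
sampled from a known logistic model over the frozen encoding; the generating
coefficients sit on the standardized numeric coordinates, where a
few-thousand-visit cohort pins them down tightly, and the generative
probability is emitted alongside each row so model AUROC can be compared to
the generative optimum. All sampling derives from
`default_rng([seed, stream, index])`, making every bundle reproducible
per-patient.

Ground truth (screening flag, qSOFA, SOFA) is computed at generation time by
straight-line `if/elif` oracle code in the fixtures module that shares nothing
with the table-driven engine — their agreement on ten thousand random
patients is a meaningful check, not a tautology.

What the fixtures do **not** emulate: longitudinal or multi-visit patients,
correlated organ failure (each value is drawn independently given septic
status), realistic code diversity (one code per concept), measurement error,
or epidemiologically calibrated prevalences. Passing tests therefore
demonstrate correctness of the pipeline's logic on well-formed data, not
clinical performance on real records.

## Problem sizes and tolerances

The default verification scales are: 10,000 patients for engine-vs-oracle
agreement (exact, zero disagreements required), 1,000 bundles for round-trip
identity, 200 random report pairs for suppression soundness, 5,000 visits for
triage parameter recovery (±0.15 on generating coefficients, test AUROC
within 0.03 of the generative optimum — both a few multiples of the
asymptotic standard errors at that n), and a 200-patient cohort for the
end-to-end screening-count check (exact). Logistic fits use L-BFGS with
`tol=1e-8` and up to 5,000 iterations; all randomness is seeded explicitly.
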