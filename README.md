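# cane

A desk-scale clinical decision support (CDS) platform for clinical
informaticians and CDS developers: it ingests HL7 FHIR R4 bundles, normalizes
them against a concept vocabulary, runs them through pluggable reasoning
engines, and exchanges privacy-preserving population-level summaries between
institutions that keep their data in OMOP-CDM-like stores.

Two reasoning engines ship with the platform:

* **SepsTreat** (knowledge-based) — a Sepsis-3 rule pipeline. A patient is
  screened as suspected of sepsis when body temperature T > 37.5 °C and a
  blood culture or antibiotics have been ordered. The bedside quick score
  qSOFA awards one point each for SBP ≤ 100 mmHg, respiratory rate ≥ 22/min,
  and GCS < 15 (positive at ≥ 2). Organ dysfunction is quantified by SOFA:
  six organ systems (respiration PaO₂/FiO₂, coagulation platelets, liver
  bilirubin, cardiovascular MAP/vasopressors, CNS GCS, renal creatinine) each
  scored 0–4, total 0–24, with MAP = (SBP + 2·DBP)/3. Sepsis = suspected
  infection ∧ SOFA ≥ 2 (baseline 0); septic shock additionally requires
  vasopressor support and lactate > 2 mmol/L. Sepsis-positive assessments get
  an hour-1-bundle-style treatment list with already-completed practices
  marked.
* **Triage** (nonknowledge-based) — a retrainable ED triage predictor. From
  triage-stage inputs (age, sex, chief complaint, onset-to-visit time,
  arrival mode, trauma, vitals, AVPU mental status) it predicts three
  non-exclusive outcomes — in-hospital mortality, critical care,
  hospitalization — as probabilities P(y|x) = σ(β₀ + βᵀx) per outcome head,
  plus a predefined 1–5 risk band read off quintile edges frozen at training
  time. Model artifacts are versioned JSON, never opaque binaries.

The federated integration layer builds `SummaryReport`s (per-drug usage and
outcome cells over a cohort) with small-cell suppression at threshold k
(default 10): no exchanged cell ever shows 0 < count < k, and a schema
validator rejects any inbound payload carrying person-level fields.

A seeded synthetic-fixtures module generates FHIR bundles, triage cohorts, and
OMOP-like stores with generation-time ground truth computed by an independent
straight-line oracle, so the whole platform is testable offline.

## Worked example

```python
from cane import SepstreatInput, assess_sepsis

a = assess_sepsis(SepstreatInput(
    gcs=13, sbp=88, dbp=52, resp_rate=26, body_temperature=38.9,
    pao2=70, fio2=0.4, platelets=85, creatinine=2.4, total_bilirubin=1.5,
    lactate=3.4, blood_culture_ordered=True, vasopressor_ordered=True,
))
print(a.qsofa.score, a.sofa.total, a.sepsis, a.septic_shock)
```

prints `3 12 True True`: all three qSOFA components fire (SBP 88 ≤ 100,
RR 26 ≥ 22, GCS 13 < 15); SOFA totals 12 (respiration 3 from PaO₂/FiO₂ = 175,
coagulation 2, liver 1, cardiovascular 3 from the vasopressor order, CNS 1,
renal 2); the fever-plus-culture screen plus SOFA ≥ 2 makes this sepsis, and
vasopressors with lactate 3.4 > 2 mmol/L make it septic shock. The
accompanying `a.recommendations` list marks lactate, cultures, and
vasopressors as already done and leaves antibiotics and fluids outstanding.

The same pipeline runs from the shell:

```bash
cane fixtures cohort --n 200 --prevalence 0.3 --seed 7 --out demo/
cane validate demo/bundles/bundle-p00000.json
cane run --engine sepstreat --bundle demo/bundles/bundle-p00001.json
cane triage train --data cohort.csv --seed 7 --out model.json
cane triage predict --model model.json --input visit.json
cane summary --store demo/store --k 10
cane serve --port 8470 --store demo/store   # POST /cds/{engine}, GET /engines, POST /summary
```

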