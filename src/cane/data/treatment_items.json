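{
  "version": "1",
  "items": [
    {
      "item_id": "measure_lactate",
      "label": "Measure serum lactate; remeasure if initial lactate > 2 mmol/L",
      "completed_when": "lactate_present",
      "rationale": "Lactate reflects tissue hypoperfusion and guides resuscitation."
    },
    {
      "item_id": "blood_cultures",
      "label": "Obtain blood cultures before starting antibiotics",
      "completed_when": "blood_culture_ordered",
      "rationale": "Cultures drawn after antibiotics lose sensitivity; identify the pathogen first."
    },
    {
      "item_id": "broad_spectrum_antibiotics",
      "label": "Administer broad-spectrum antibiotics",
      "completed_when": "antibiotics_ordered",
      "rationale": "Each hour of delayed antimicrobial therapy increases sepsis mortality."
    },
    {
      "item_id": "crystalloid_fluids",
      "label": "Begin rapid infusion of 30 mL/kg crystalloid for hypotension or lactate ≥ 4 mmol/L",
      "completed_when": "never",
      "rationale": "Early volume resuscitation restores perfusion; fluid administration is not visible in the input schema, so this item is never auto-marked."
    },
    {
      "item_id": "vasopressors",
      "label": "Start vasopressors if MAP < 65 mmHg during or after fluid resuscitation",
      "completed_when": "vasopressor_ordered",
      "rationale": "Maintain mean arterial pressure ≥ 65 mmHg to preserve organ perfusion."
    }
  ]
}
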