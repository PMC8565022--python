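[
  {"state_id": 1, "label": "TLM / TORS and lymph node resection",
   "snomed_exprs": ["10724008|Microsurgery|", "118438002|Trans-oral approach|"],
   "scenario_ref": null},
  {"state_id": 2, "label": "Re-intervention (TLM / TORS and lymph node resection)",
   "snomed_exprs": ["64695001|Repeat elective|", "10724008|Microsurgery|", "118438002|Trans-oral approach|"],
   "scenario_ref": null},
  {"state_id": 3, "label": "Radiotherapy (RT) after surgery",
   "snomed_exprs": ["169351001|Radiotherapy: infuse head/neck|", "262061000|Postoperative|"],
   "scenario_ref": null},
  {"state_id": 4, "label": "Chemo-radiotherapy (CRT) after surgery",
   "snomed_exprs": ["169400008|Chemo-radiotherapy: IV|", "262061000|Postoperative|"],
   "scenario_ref": "scenario_04_synthetic"},
  {"state_id": 5, "label": "Tracheotomy long duration",
   "snomed_exprs": ["48387007|Tracheotomy|"],
   "scenario_ref": null},
  {"state_id": 6, "label": "Gastrostomy",
   "snomed_exprs": ["54956002|Gastrostomy|"],
   "scenario_ref": null},
  {"state_id": 7, "label": "Pharyngo-cutaneous fistula",
   "snomed_exprs": ["232413009|Pharyngocutaneous fistula|"],
   "scenario_ref": null},
  {"state_id": 8, "label": "Hospital re-admission for febrile neutropenia",
   "snomed_exprs": ["409089005|Febrile neutropenia|"],
   "scenario_ref": null},
  {"state_id": 9, "label": "Esopharyngeal stenosis",
   "snomed_exprs": ["232372008|Nasopharyngeal stenosis|"],
   "scenario_ref": null},
  {"state_id": 10, "label": "Osteo-radio-necrosis",
   "snomed_exprs": ["109333005|Osteoradionecrosis|"],
   "scenario_ref": null},
  {"state_id": 11, "label": "Post-operative hemorrhages",
   "snomed_exprs": ["110265006|Postoperative hemorrhage|"],
   "scenario_ref": null},
  {"state_id": 12, "label": "Remission after TORS/TLM",
   "snomed_exprs": ["277022003|Remission|", "10724008|Microsurgery|", "118438002|Trans-oral approach|"],
   "scenario_ref": null},
  {"state_id": 13, "label": "Remission after TORS/TLM + adjuvant",
   "snomed_exprs": ["277022003|Remission|", "10724008|Microsurgery|", "118438002|Trans-oral approach|", "169400008|Chemo-radiotherapy: IV|"],
   "scenario_ref": null},
  {"state_id": 14, "label": "Local recurrence (intervention needed)",
   "snomed_exprs": ["25173007|Recurrent tumor|", "255470001|Local|", "64695001|Repeat elective|"],
   "scenario_ref": null},
  {"state_id": 15, "label": "Local recurrence (RT or CRT needed)",
   "snomed_exprs": ["25173007|Recurrent tumor|", "255470001|Local|", "169400008|Chemo-radiotherapy: IV|"],
   "scenario_ref": null},
  {"state_id": 16, "label": "Regional recurrence",
   "snomed_exprs": ["25173007|Recurrent tumor|", "410674003|Regional|"],
   "scenario_ref": null},
  {"state_id": 17, "label": "Distant recurrence",
   "snomed_exprs": ["25173007|Recurrent tumor|", "261007001|Distant|"],
   "scenario_ref": null},
  {"state_id": 18, "label": "Palliative care",
   "snomed_exprs": ["103735009|Palliative care|"],
   "scenario_ref": null}
]
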