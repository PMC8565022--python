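state_id,scenario,mean,ci_low,ci_high
1,TLM/TORS intervention (first month),0.95,0.94,0.97
2,Re-intervention,0.94,0.91,0.97
3,RT after intervention,0.89,0.85,0.93
4,CRT after intervention,0.89,0.89,0.93
5,Tracheotomy long duration,0.85,0.80,0.91
6,Gastrostomy,0.89,0.85,0.94
7,Pharyngo-cutaneous fistula,0.89,0.85,0.94
8,Hospital re-admission for febrile neutropenia,0.96,0.94,0.98
9,Esopharyngeal stenosis,0.85,0.80,0.90
10,Osteo-radio-necrosis,0.85,0.81,0.90
11,Post-operative hemorrhages,NA,NA,NA
12,Remission after TORS/TLM,0.96,0.94,0.98
13,Remission after TORS/TLM + adjuvant,0.95,0.93,0.98
14,Local recurrence (intervention needed),0.82,0.77,0.87
15,Local recurrence (RT or CRT needed),0.88,0.84,0.91
16,Regional recurrence,0.94,0.91,0.97
17,Distant recurrence,0.57,0.50,0.64
18,Palliative care,0.42,0.34,0.50
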