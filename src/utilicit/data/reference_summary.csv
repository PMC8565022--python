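state_id,scenario,method,n,mean,sd,max,min,median,q1,q3
1,TLM/TORS intervention (first month),SG,47,0.902,0.203,1.000,0.245,1.000,0.968,1.000
2,Re-intervention,SG,47,0.872,0.249,1.000,0.075,1.000,0.919,1.000
3,RT after intervention,SG,47,0.850,0.275,1.000,0.040,1.000,0.880,1.000
4,CRT after intervention,SG,47,0.794,0.317,1.000,0.030,1.000,0.548,1.000
5,Tracheotomy long duration,SG,47,0.852,0.271,1.000,0.020,1.000,0.895,1.000
6,Gastrostomy,SG,47,0.916,0.209,1.000,0.095,1.000,0.990,1.000
7,Pharyngo-cutaneous fistula,SG,47,0.932,0.194,1.000,0.025,1.000,1.000,1.000
8,Hospital re-admission for febrile neutropenia,SG,47,0.954,0.140,1.000,0.330,1.000,1.000,1.000
9,Esopharyngeal stenosis,SG,47,0.826,0.284,1.000,0.000,0.975,0.833,1.000
10,Osteo-radio-necrosis,SG,47,0.791,0.302,1.000,0.005,0.915,0.758,1.000
11,Post-operative hemorrhages,SG,47,0.910,0.203,1.000,0.120,1.000,0.970,1.000
12,Remission after TORS/TLM,SG,47,0.980,0.099,1.000,0.340,1.000,1.000,1.000
13,Remission after TORS/TLM + adjuvant,SG,47,0.957,0.151,1.000,0.125,1.000,1.000,1.000
14,Local recurrence (intervention needed),SG,47,0.755,0.316,1.000,0.005,0.900,0.525,1.000
15,Local recurrence (RT or CRT needed),SG,47,0.771,0.302,1.000,0.005,0.935,0.598,1.000
16,Regional recurrence,SG,47,0.859,0.283,1.000,0.005,1.000,0.878,1.000
17,Distant recurrence,SG,47,0.307,0.350,1.000,0.000,0.100,0.015,0.513
18,Palliative care,SG,47,0.213,0.336,1.000,0.000,0.010,0.005,0.320
1,TLM/TORS intervention (first month),RS,47,0.546,0.200,1.000,0.100,0.510,0.395,0.725
2,Re-intervention,RS,47,0.441,0.192,0.790,0.070,0.400,0.290,0.568
3,RT after intervention,RS,47,0.448,0.193,0.840,0.050,0.400,0.300,0.630
4,CRT after intervention,RS,47,0.334,0.172,0.650,0.030,0.300,0.200,0.500
5,Tracheotomy long duration,RS,47,0.406,0.189,0.800,0.080,0.400,0.255,0.500
6,Gastrostomy,RS,47,0.501,0.214,0.900,0.070,0.550,0.350,0.665
7,Pharyngo-cutaneous fistula,RS,47,0.496,0.205,0.850,0.100,0.500,0.345,0.680
8,Hospital re-admission for febrile neutropenia,RS,47,0.449,0.211,0.840,0.080,0.460,0.275,0.615
9,Esopharyngeal stenosis,RS,47,0.322,0.180,0.790,0.000,0.300,0.185,0.420
10,Osteo-radio-necrosis,RS,47,0.274,0.164,0.620,0.050,0.250,0.125,0.400
11,Post-operative hemorrhages,RS,47,0.542,0.204,0.950,0.120,0.500,0.395,0.680
12,Remission after TORS/TLM,RS,47,0.763,0.177,1.000,0.290,0.800,0.695,0.900
13,Remission after TORS/TLM + adjuvant,RS,47,0.620,0.174,0.920,0.200,0.650,0.500,0.700
14,Local recurrence (intervention needed),RS,47,0.250,0.149,0.650,0.000,0.240,0.150,0.350
15,Local recurrence (RT or CRT needed),RS,47,0.264,0.134,0.620,0.000,0.250,0.160,0.355
16,Regional recurrence,RS,47,0.378,0.188,0.790,0.030,0.350,0.250,0.500
17,Distant recurrence,RS,47,0.108,0.109,0.500,0.000,0.100,0.040,0.130
18,Palliative care,RS,47,0.072,0.086,0.400,0.000,0.050,0.015,0.090
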