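{
  "n": 47,
  "sex": {"female": 33, "male": 14},
  "education": {"secondary school": 7, "high school": 4, "university": 36},
  "family_situation": {
    "has_dependant_child": 7,
    "has_adult_non_self-sufficient_dependant": 2,
    "none_of_the_above": 38
  },
  "profession": {
    "healthcare professional": 33,
    "administrative": 6,
    "commercial activities": 4,
    "unemployed": 4
  },
  "marital_status": {"married": 22, "single": 19, "other": 6},
  "age": {"mean": 40.8, "sd": 14.79, "min": 21, "max": 68},
  "country": "Switzerland"
}
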