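[
  {"compound": "1", "formula": "C32H38O10", "adduct": "Na", "calcd": 605.2363, "observed": 605.2356,
   "fragments": []},
  {"compound": "2", "formula": "C31H36O10", "adduct": "Na", "calcd": 591.2206, "observed": 591.2202,
   "fragments": [{"mz": 505.1826, "nominal_loss": 86}]},
  {"compound": "3", "formula": "C32H38O9", "adduct": "Na", "calcd": 589.2414, "observed": 589.2412,
   "fragments": [{"mz": 489.1882, "nominal_loss": 100}, {"mz": 445.1983, "nominal_loss": 144}]},
  {"compound": "4", "formula": "C32H42O9", "adduct": "Na", "calcd": 593.2727, "observed": 593.2714,
   "fragments": [{"mz": 475.2071, "nominal_loss": 118}]},
  {"compound": "5", "formula": "C30H36O12", "adduct": "Na", "calcd": 611.2104, "observed": 611.2108,
   "fragments": [{"mz": 551.1882, "nominal_loss": 60}]},
  {"compound": "6", "formula": "C32H40O14", "adduct": "Na", "calcd": 671.2316, "observed": 671.2309,
   "fragments": [{"mz": 611.2089, "nominal_loss": 60}, {"mz": 567.2194, "nominal_loss": 104}]},
  {"compound": "7", "formula": "C30H46O9", "adduct": "Na", "calcd": 573.3040, "observed": 573.3041,
   "fragments": [{"mz": 513.2820, "nominal_loss": 60}, {"mz": 469.2921, "nominal_loss": 104}, {"mz": 453.2606, "nominal_loss": 120}]},
  {"compound": "8", "formula": "C28H34O10", "adduct": "Na", "calcd": 553.2050, "observed": 553.2038,
   "fragments": [{"mz": 493.1825, "nominal_loss": 60}, {"mz": 449.1931, "nominal_loss": 104}]},
  {"compound": "9", "formula": "C30H36O13", "adduct": "Na", "calcd": 627.2054, "observed": 627.2045,
   "fragments": [{"mz": 567.1841, "nominal_loss": 60}]}
]
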