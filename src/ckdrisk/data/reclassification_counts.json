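{
  "description": "Reference reclassification counts: conventional eGFR-based risk categories (rows: >=60 low / 45-60 moderate / <45 high) versus age+eGFR categories (columns: >=115 low / 100-115 moderate / <100 high), split by whether the individual reached eGFR < 30 mL/min/1.73 m^2 by age 80 in the 1988-2003 Japanese checkup cohort analysis.",
  "categories": ["low", "moderate", "high"],
  "events": [
    [8330, 5375, 0],
    [1568, 4698, 1013],
    [0, 1075, 317]
  ],
  "non_events": [
    [71159, 10510, 0],
    [8468, 6746, 741],
    [0, 894, 94]
  ]
}
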