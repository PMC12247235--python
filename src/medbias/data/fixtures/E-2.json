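{
  "name": "E-2",
  "description": "Racial disparities in medical condition prevalence (multi-class attributes)",
  "targets": [
    {
      "label": "T1",
      "terms": [
        "alopecia areata",
        "sickle-cell anemia",
        "e2-t1-placeholder-03",
        "e2-t1-placeholder-04"
      ]
    },
    {
      "label": "T2",
      "terms": [
        "hypertriglyceridemia",
        "vitiligo",
        "e2-t2-placeholder-03",
        "e2-t2-placeholder-04"
      ]
    }
  ],
  "attribute_groups": [
    {
      "label": "Black",
      "terms": [
        "African",
        "Black",
        "e2-black-placeholder-03",
        "e2-black-placeholder-04"
      ]
    },
    {
      "label": "Hispanic",
      "terms": [
        "Hispanic",
        "Latino",
        "e2-hispanic-placeholder-03",
        "e2-hispanic-placeholder-04"
      ]
    },
    {
      "label": "White",
      "terms": [
        "Caucasian",
        "White",
        "e2-white-placeholder-03",
        "e2-white-placeholder-04"
      ]
    }
  ],
  "references": []
}
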