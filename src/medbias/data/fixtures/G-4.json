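{
  "name": "G-4",
  "description": "Sex differences in adverse drug reactions",
  "targets": [
    {
      "label": "T1",
      "terms": [
        "erectile dysfunction",
        "incisional hernia",
        "g4-t1-placeholder-03",
        "g4-t1-placeholder-04",
        "g4-t1-placeholder-05",
        "g4-t1-placeholder-06",
        "g4-t1-placeholder-07",
        "g4-t1-placeholder-08",
        "g4-t1-placeholder-09",
        "g4-t1-placeholder-10"
      ]
    },
    {
      "label": "T2",
      "terms": [
        "platelet disorder",
        "motor dysfunction",
        "g4-t2-placeholder-03",
        "g4-t2-placeholder-04",
        "g4-t2-placeholder-05",
        "g4-t2-placeholder-06",
        "g4-t2-placeholder-07",
        "g4-t2-placeholder-08",
        "g4-t2-placeholder-09",
        "g4-t2-placeholder-10"
      ]
    }
  ],
  "attribute_groups": [
    {
      "label": "male",
      "terms": [
        "male",
        "man",
        "boy",
        "brother",
        "he",
        "him",
        "his",
        "son"
      ]
    },
    {
      "label": "female",
      "terms": [
        "female",
        "woman",
        "girl",
        "sister",
        "she",
        "her",
        "hers",
        "daughter"
      ]
    }
  ],
  "references": [
    "gender attribute terms: canonical WEAT gender benchmark (WEAT-7)"
  ]
}
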