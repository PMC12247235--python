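{
  "name": "G-3",
  "description": "Medical conditions with no strong sex disparity (ratio at most 1.25:1)",
  "targets": [
    {
      "label": "T1",
      "terms": [
        "Hodgkin lymphoma",
        "meningitis",
        "g3-t1-placeholder-03",
        "g3-t1-placeholder-04",
        "g3-t1-placeholder-05"
      ]
    },
    {
      "label": "T2",
      "terms": [
        "cellulitis",
        "hemorrhoids",
        "g3-t2-placeholder-03",
        "g3-t2-placeholder-04",
        "g3-t2-placeholder-05"
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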