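{
  "name": "G-1",
  "description": "Sex disparities in medical conditions with a sex ratio of at least 99:1",
  "targets": [
    {
      "label": "T1",
      "terms": [
        "prostate cancer",
        "testicular cancer",
        "g1-t1-placeholder-03",
        "g1-t1-placeholder-04",
        "g1-t1-placeholder-05",
        "g1-t1-placeholder-06"
      ]
    },
    {
      "label": "T2",
      "terms": [
        "ovarian cancer",
        "breast cancer",
        "g1-t2-placeholder-03",
        "g1-t2-placeholder-04",
        "g1-t2-placeholder-05",
        "g1-t2-placeholder-06"
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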