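{
  "name": "G-2",
  "description": "Sex disparities in medical conditions with a sex ratio of at least 3:1",
  "targets": [
    {
      "label": "T1",
      "terms": [
        "prostate cancer",
        "testicular cancer",
        "color blindness",
        "g2-t1-placeholder-04",
        "g2-t1-placeholder-05",
        "g2-t1-placeholder-06",
        "g2-t1-placeholder-07",
        "g2-t1-placeholder-08",
        "g2-t1-placeholder-09",
        "g2-t1-placeholder-10",
        "g2-t1-placeholder-11"
      ]
    },
    {
      "label": "T2",
      "terms": [
        "ovarian cancer",
        "breast cancer",
        "osteoporosis",
        "g2-t2-placeholder-04",
        "g2-t2-placeholder-05",
        "g2-t2-placeholder-06",
        "g2-t2-placeholder-07",
        "g2-t2-placeholder-08",
        "g2-t2-placeholder-09",
        "g2-t2-placeholder-10",
        "g2-t2-placeholder-11"
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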