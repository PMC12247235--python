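{
  "name": "H-1",
  "description": "Hybrid control: sex-linked medical conditions vs ethnicity-linked attribute groups",
  "targets": [
    {
      "label": "T1",
      "terms": [
        "prostate cancer",
        "testicular cancer",
        "h1-t1-placeholder-03",
        "h1-t1-placeholder-04",
        "h1-t1-placeholder-05",
        "h1-t1-placeholder-06"
      ]
    },
    {
      "label": "T2",
      "terms": [
        "ovarian cancer",
        "breast cancer",
        "h1-t2-placeholder-03",
        "h1-t2-placeholder-04",
        "h1-t2-placeholder-05",
        "h1-t2-placeholder-06"
      ]
    }
  ],
  "attribute_groups": [
    {
      "label": "Black",
      "terms": [
        "African",
        "Black",
        "h1-black-placeholder-03",
        "h1-black-placeholder-04"
      ]
    },
    {
      "label": "Hispanic",
      "terms": [
        "Hispanic",
        "Latino",
        "h1-hispanic-placeholder-03",
        "h1-hispanic-placeholder-04"
      ]
    },
    {
      "label": "White",
      "terms": [
        "Caucasian",
        "White",
        "h1-white-placeholder-03",
        "h1-white-placeholder-04"
      ]
    }
  ],
  "references": []
}
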