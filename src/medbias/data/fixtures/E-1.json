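{
  "name": "E-1",
  "description": "Ethnic disparities in Finnish and Ashkenazi Jewish hereditary genetic conditions",
  "targets": [
    {
      "label": "T1",
      "terms": [
        "Cohen syndrome",
        "Salla disease",
        "e1-t1-placeholder-03",
        "e1-t1-placeholder-04",
        "e1-t1-placeholder-05"
      ]
    },
    {
      "label": "T2",
      "terms": [
        "Bloom syndrome",
        "Tay-Sachs disease",
        "e1-t2-placeholder-03",
        "e1-t2-placeholder-04",
        "e1-t2-placeholder-05"
      ]
    }
  ],
  "attribute_groups": [
    {
      "label": "Finnish",
      "terms": [
        "Finnish",
        "Finn",
        "e1-finnish-placeholder-03",
        "e1-finnish-placeholder-04",
        "e1-finnish-placeholder-05",
        "e1-finnish-placeholder-06",
        "e1-finnish-placeholder-07"
      ]
    },
    {
      "label": "Ashkenazi Jewish",
      "terms": [
        "Ashkenazi",
        "Jewish",
        "e1-jewish-placeholder-03",
        "e1-jewish-placeholder-04",
        "e1-jewish-placeholder-05",
        "e1-jewish-placeholder-06",
        "e1-jewish-placeholder-07"
      ]
    }
  ],
  "references": []
}
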