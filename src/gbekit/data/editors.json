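{
  "editors": [
    {
      "name": "gTBEv3",
      "conversion": {
        "source_base": "T",
        "product_bases": [
          "C",
          "G",
          "A"
        ],
        "predominant": [
          "C",
          "G"
        ],
        "minor": [
          "A"
        ]
      },
      "window": {
        "editable": [
          2,
          11
        ],
        "optimal": [
          3,
          7
        ],
        "peak": 5
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "gTBEv4",
      "conversion": {
        "source_base": "T",
        "product_bases": [
          "C",
          "G",
          "A"
        ],
        "predominant": [
          "C",
          "G"
        ],
        "minor": [
          "A"
        ]
      },
      "window": {
        "editable": [
          7,
          13
        ],
        "optimal": [
          7,
          13
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "gTBEv5",
      "conversion": {
        "source_base": "T",
        "product_bases": [
          "C",
          "G",
          "A"
        ],
        "predominant": [
          "C",
          "G"
        ],
        "minor": [
          "A"
        ]
      },
      "window": {
        "editable": [
          5,
          9
        ],
        "optimal": [
          5,
          9
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "TSBE3",
      "conversion": {
        "source_base": "T",
        "product_bases": [
          "C",
          "G",
          "A"
        ],
        "predominant": [
          "C",
          "G"
        ],
        "minor": [
          "A"
        ]
      },
      "window": {
        "editable": [
          4,
          9
        ],
        "optimal": [
          4,
          9
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "DAF-TBE",
      "conversion": {
        "source_base": "T",
        "product_bases": [
          "C",
          "G",
          "A"
        ],
        "predominant": [
          "C",
          "G"
        ],
        "minor": [
          "A"
        ]
      },
      "window": {
        "editable": [
          2,
          6
        ],
        "optimal": [
          2,
          6
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "DAF-TBE2",
      "conversion": {
        "source_base": "T",
        "product_bases": [
          "C",
          "G",
          "A"
        ],
        "predominant": [
          "C",
          "G"
        ],
        "minor": [
          "A"
        ]
      },
      "window": {
        "editable": [
          9,
          13
        ],
        "optimal": [
          9,
          13
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "gCBEv2",
      "conversion": {
        "source_base": "C",
        "product_bases": [
          "G",
          "T",
          "A"
        ],
        "predominant": [
          "G"
        ],
        "minor": [
          "A"
        ]
      },
      "window": {
        "editable": [
          2,
          9
        ],
        "optimal": [
          2,
          6
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "gCBEv3",
      "conversion": {
        "source_base": "C",
        "product_bases": [
          "G",
          "T",
          "A"
        ],
        "predominant": [
          "G"
        ],
        "minor": [
          "A"
        ]
      },
      "window": {
        "editable": [
          2,
          11
        ],
        "optimal": [
          2,
          11
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "CGBE1",
      "conversion": {
        "source_base": "C",
        "product_bases": [
          "G",
          "T",
          "A"
        ],
        "predominant": [
          "G"
        ],
        "minor": [
          "A"
        ]
      },
      "window": {
        "editable": [
          4,
          10
        ],
        "optimal": [
          5,
          7
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "CGBE-CDG",
      "conversion": {
        "source_base": "C",
        "product_bases": [
          "G",
          "T",
          "A"
        ],
        "predominant": [
          "G"
        ],
        "minor": [
          "A"
        ]
      },
      "window": {
        "editable": [
          2,
          9
        ],
        "optimal": [
          2,
          9
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "DAF-CBE",
      "conversion": {
        "source_base": "C",
        "product_bases": [
          "G",
          "T",
          "A"
        ],
        "predominant": [
          "G"
        ],
        "minor": [
          "A"
        ]
      },
      "window": {
        "editable": [
          2,
          9
        ],
        "optimal": [
          2,
          9
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "DAF-CBE2",
      "conversion": {
        "source_base": "C",
        "product_bases": [
          "G",
          "T",
          "A"
        ],
        "predominant": [
          "G"
        ],
        "minor": [
          "A"
        ]
      },
      "window": {
        "editable": [
          9,
          12
        ],
        "optimal": [
          9,
          12
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "ABE",
      "conversion": {
        "source_base": "A",
        "product_bases": [
          "G"
        ],
        "predominant": [
          "G"
        ],
        "minor": []
      },
      "window": {
        "editable": [
          3,
          9
        ],
        "optimal": [
          4,
          8
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "CBE",
      "conversion": {
        "source_base": "C",
        "product_bases": [
          "T"
        ],
        "predominant": [
          "T"
        ],
        "minor": []
      },
      "window": {
        "editable": [
          3,
          9
        ],
        "optimal": [
          4,
          8
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    },
    {
      "name": "gGBE",
      "conversion": {
        "source_base": "G",
        "product_bases": [
          "C",
          "T"
        ],
        "predominant": [
          "C",
          "T"
        ],
        "minor": []
      },
      "window": {
        "editable": [
          4,
          8
        ],
        "optimal": [
          4,
          8
        ],
        "peak": null
      },
      "pam": "NGG",
      "nickase": "nCas9(D10A)"
    }
  ]
}
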