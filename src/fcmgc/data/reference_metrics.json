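{
  "description": "Published confusion matrices (rows = predicted, columns = actual, order high/medium/low) and reported metric cells from the original 560-patient gastric-cancer study's held-out evaluation (168 records: 56 high, 64 medium, 48 low). Baseline classifiers were run by the original authors; only their printed matrices are re-scored here. Two published cells are inconsistent with their own printed matrices and are omitted from 'printed': the Naive Bayes medium-class precision (printed 77.77; row [8, 56, 4] gives 82.35) and, for the MLP-ANN, the overall accuracy and low-class recall (printed 90.47 and 93.75, i.e. 152/168 and 45/48, but the printed matrix's low column sums to 56 so its cells total 176 rather than 168).",
  "classifiers": {
    "decision_tree": {
      "matrix": [
        [
          30,
          10,
          1
        ],
        [
          16,
          52,
          0
        ],
        [
          10,
          2,
          47
        ]
      ],
      "printed": {
        "accuracy": 76.78,
        "recall": {
          "high": 53.57,
          "medium": 81.25,
          "low": 97.91
        },
        "precision": {
          "high": 73.17,
          "medium": 76.47,
          "low": 79.66
        }
      }
    },
    "naive_bayes": {
      "matrix": [
        [
          40,
          8,
          5
        ],
        [
          8,
          56,
          4
        ],
        [
          8,
          0,
          39
        ]
      ],
      "printed": {
        "accuracy": 80.35,
        "recall": {
          "high": 71.42,
          "medium": 87.5,
          "low": 81.25
        },
        "precision": {
          "high": 75.47,
          "low": 82.97
        }
      }
    },
    "svm_rbf": {
      "matrix": [
        [
          46,
          2,
          4
        ],
        [
          0,
          60,
          4
        ],
        [
          10,
          2,
          40
        ]
      ],
      "printed": {
        "accuracy": 86.9,
        "recall": {
          "high": 82.14,
          "medium": 93.75,
          "low": 83.3
        },
        "precision": {
          "high": 88.46,
          "medium": 93.75,
          "low": 76.92
        }
      }
    },
    "mlp_ann": {
      "matrix": [
        [
          49,
          2,
          7
        ],
        [
          4,
          58,
          4
        ],
        [
          3,
          4,
          45
        ]
      ],
      "printed": {
        "recall": {
          "high": 87.5,
          "medium": 90.62
        },
        "precision": {
          "high": 84.48,
          "medium": 87.87,
          "low": 86.53
        }
      }
    },
    "nhl_fcm": {
      "matrix": [
        [
          55,
          1,
          1
        ],
        [
          1,
          60,
          1
        ],
        [
          0,
          3,
          46
        ]
      ],
      "printed": {
        "accuracy": 95.83,
        "recall": {
          "high": 98.21,
          "medium": 93.75,
          "low": 95.83
        },
        "precision": {
          "high": 96.49,
          "medium": 96.77,
          "low": 93.87
        }
      }
    }
  },
  "parameter_grid": [
    {
      "eta": 0.01,
      "gamma": 0.97,
      "matrix": [
        [
          50,
          4,
          7
        ],
        [
          4,
          59,
          1
        ],
        [
          2,
          1,
          40
        ]
      ],
      "accuracy": 88.69
    },
    {
      "eta": 0.03,
      "gamma": 0.95,
      "matrix": [
        [
          45,
          6,
          1
        ],
        [
          5,
          58,
          0
        ],
        [
          6,
          0,
          47
        ]
      ],
      "accuracy": 89.28
    },
    {
      "eta": 0.045,
      "gamma": 0.98,
      "matrix": [
        [
          55,
          1,
          1
        ],
        [
          1,
          60,
          1
        ],
        [
          0,
          3,
          46
        ]
      ],
      "accuracy": 95.83
    },
    {
      "eta": 0.05,
      "gamma": 0.96,
      "matrix": [
        [
          54,
          6,
          0
        ],
        [
          1,
          56,
          0
        ],
        [
          1,
          2,
          48
        ]
      ],
      "accuracy": 94.04
    },
    {
      "eta": 0.055,
      "gamma": 0.96,
      "matrix": [
        [
          53,
          2,
          5
        ],
        [
          2,
          58,
          0
        ],
        [
          1,
          4,
          43
        ]
      ],
      "accuracy": 91.6
    }
  ]
}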