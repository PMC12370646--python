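{
  "description": "Published per-class and aggregate evaluation metrics of the final gradient-boosted item-score models on a 225-participant clinical cohort (180 training participants evaluated by LOOCV, 45 held-out test participants). Per-class blocks list precision, recall, F1 and support as printed (null = undefined/NA); aggregate blocks list weighted F1, ACC+-0 (%), ACC+-1 (%), quadratically-weighted kappa and macro F1. Used as the input of the reconstruction oracle that validates this package's metric conventions.",
  "items": {
    "3.9": {
      "name": "arising from chair",
      "classes": ["0", "1", "2/3/4"],
      "LOOCV": {
        "precision": [0.855, 0.587, 0.429],
        "recall": [0.803, 0.661, 0.429],
        "f1": [0.828, 0.622, 0.429],
        "support": [117, 56, 7],
        "weighted_f1": 0.748,
        "acc_exact": 74.4,
        "acc_within1": 99.4,
        "kappa_w": 0.52,
        "macro_f1": 0.626
      },
      "TEST": {
        "precision": [0.769, 0.789, null],
        "recall": [0.87, 0.714, 0.0],
        "f1": [0.816, 0.75, null],
        "support": [23, 21, 1],
        "weighted_f1": 0.767,
        "acc_exact": 77.8,
        "acc_within1": 100.0,
        "kappa_w": 0.573,
        "macro_f1": 0.783
      }
    },
    "3.10": {
      "name": "gait",
      "classes": ["0", "1", "2/3"],
      "LOOCV": {
        "precision": [0.5, 0.694, 0.916],
        "recall": [0.462, 0.843, 0.784],
        "f1": [0.48, 0.761, 0.844],
        "support": [13, 70, 97],
        "weighted_f1": 0.786,
        "acc_exact": 78.3,
        "acc_within1": 98.9,
        "kappa_w": 0.64,
        "macro_f1": 0.695
      },
      "TEST": {
        "precision": [0.75, 0.462, 0.821],
        "recall": [0.75, 0.5, 0.793],
        "f1": [0.75, 0.48, 0.807],
        "support": [4, 12, 29],
        "weighted_f1": 0.715,
        "acc_exact": 71.1,
        "acc_within1": 100.0,
        "kappa_w": 0.539,
        "macro_f1": 0.679
      }
    },
    "3.11": {
      "name": "freezing of gait",
      "classes": ["0", "1", "2/3/4"],
      "LOOCV": {
        "precision": [0.932, 0.25, 0.538],
        "recall": [0.849, 0.333, 0.75],
        "f1": [0.889, 0.286, 0.627],
        "support": [146, 6, 28],
        "weighted_f1": 0.828,
        "acc_exact": 81.7,
        "acc_within1": 87.2,
        "kappa_w": 0.53,
        "macro_f1": 0.6
      },
      "TEST": {
        "precision": [0.882, null, 0.636],
        "recall": [0.938, 0.0, 0.875],
        "f1": [0.909, null, 0.737],
        "support": [32, 5, 8],
        "weighted_f1": 0.777,
        "acc_exact": 82.2,
        "acc_within1": 93.3,
        "kappa_w": 0.664,
        "macro_f1": 0.823
      }
    },
    "3.12": {
      "name": "postural stability",
      "classes": ["0", "1", "2", "3", "4"],
      "LOOCV": {
        "precision": [0.667, 0.614, 0.2, 0.578, 0.308],
        "recall": [0.712, 0.474, 0.3, 0.578, 0.444],
        "f1": [0.689, 0.535, 0.24, 0.578, 0.364],
        "support": [59, 57, 10, 45, 9],
        "weighted_f1": 0.571,
        "acc_exact": 56.7,
        "acc_within1": 80.6,
        "kappa_w": 0.51,
        "macro_f1": 0.481
      },
      "TEST": {
        "precision": [0.562, 0.273, 0.0, 0.462, 0.0],
        "recall": [0.6, 0.3, 0.0, 0.353, 0.0],
        "f1": [0.581, 0.286, null, 0.4, null],
        "support": [15, 10, 2, 17, 1],
        "weighted_f1": 0.408,
        "acc_exact": 40.0,
        "acc_within1": 66.7,
        "kappa_w": 0.278,
        "macro_f1": 0.422
      }
    },
    "3.13": {
      "name": "posture",
      "classes": ["0", "1", "2", "3/4"],
      "LOOCV": {
        "precision": [0.66, 0.726, 0.375, 0.48],
        "recall": [0.714, 0.562, 0.455, 0.667],
        "f1": [0.686, 0.634, 0.411, 0.558],
        "support": [49, 80, 33, 18],
        "weighted_f1": 0.6,
        "acc_exact": 59.4,
        "acc_within1": 88.3,
        "kappa_w": 0.5,
        "macro_f1": 0.572
      },
      "TEST": {
        "precision": [0.5, 0.526, 0.4, 0.2],
        "recall": [0.571, 0.526, 0.25, 0.25],
        "f1": [0.533, 0.526, 0.308, 0.222],
        "support": [14, 19, 8, 4],
        "weighted_f1": 0.463,
        "acc_exact": 46.7,
        "acc_within1": 84.4,
        "kappa_w": 0.308,
        "macro_f1": 0.397
      }
    }
  }
}
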