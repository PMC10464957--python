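"""Reference error matrices: post-cleanup confusion matrices of the
maximum-likelihood and neural-net classifications of two Icelandic lake
spawning-ground surveys, re-entered by hand as worked examples for the
accuracy module. Rows: unclassified + 6 predicted classes; columns: the 6
true (ground-truth ROI) classes. Expected metrics are the published
2-decimal values.

Note: the spawning-redds/anthropogenic cell of the second lake's neural-net
matrix is 56 — the value consistent with that table's own row and column
totals and every derived metric.
"""

import numpy as np

LAKE1_CLASSES = ["spawning redds", "vegetation", "underwater rocks",
                 "deep water", "shoreline", "surface rocks"]
LAKE2_CLASSES = ["spawning redds", "vegetation", "underwater rocks",
                 "aquatic vegetation", "anthropogenic feature", "sediment"]

LAKE1_MLC = np.array([
    [0, 1, 0, 0, 0, 0],
    [919, 0, 26, 9, 0, 0],
    [0, 867, 39, 0, 0, 70],
    [15, 92, 924, 26, 0, 116],
    [74, 0, 24, 966, 0, 0],
    [2, 20, 0, 0, 1011, 21],
    [0, 27, 0, 0, 6, 907],
])

LAKE1_NN = np.array([
    [0, 0, 0, 0, 0, 0],
    [931, 2, 23, 82, 9, 0],
    [0, 708, 29, 7, 0, 25],
    [17, 213, 909, 2, 0, 174],
    [62, 0, 16, 910, 0, 0],
    [0, 32, 0, 0, 1006, 21],
    [0, 52, 36, 0, 2, 894],
])

LAKE2_MLC = np.array([
    [0, 1, 0, 0, 0, 0],
    [962, 0, 0, 100, 43, 0],
    [0, 925, 30, 0, 0, 132],
    [0, 5, 920, 0, 0, 0],
    [49, 0, 0, 973, 0, 0],
    [0, 78, 0, 0, 1001, 0],
    [0, 4, 273, 0, 0, 937],
])

LAKE2_NN = np.array([
    [0, 0, 0, 0, 0, 0],
    [1009, 0, 0, 114, 56, 0],
    [0, 929, 160, 0, 0, 241],
    [0, 0, 943, 0, 0, 42],
    [2, 0, 0, 619, 0, 85],
    [0, 84, 3, 0, 988, 0],
    [0, 0, 117, 340, 0, 701],
])

# (matrix, class names, expected values at 2-decimal rounding)
REFERENCE_CASES = {
    "lake1_mlc": {
        "matrix": LAKE1_MLC,
        "classes": LAKE1_CLASSES,
        "oa_pct": 90.78,
        "kappa": 0.89,
        "pa_pct": [90.99, 86.10, 91.21, 96.50, 99.41, 81.42],
        "ua_pct": [96.33, 88.83, 78.77, 90.79, 95.92, 96.49],
    },
    "lake1_nn": {
        "matrix": LAKE1_NN,
        "classes": LAKE1_CLASSES,
        "oa_pct": 86.95,
        "kappa": 0.84,
        "pa_pct": [92.18, 70.31, 89.73, 90.91, 98.92, 80.25],
        "ua_pct": [88.92, 92.07, 69.13, 92.11, 95.00, 90.85],
    },
    "lake2_mlc": {
        "matrix": LAKE2_MLC,
        "classes": LAKE2_CLASSES,
        "oa_pct": 88.89,
        "kappa": 0.87,
        "pa_pct": [95.15, 91.31, 75.22, 90.68, 95.88, 87.65],
        "ua_pct": [87.06, 85.10, 99.46, 95.21, 92.77, 77.18],
    },
    "lake2_nn": {
        "matrix": LAKE2_NN,
        "classes": LAKE2_CLASSES,
        "oa_pct": 80.66,
        "kappa": 0.77,
        "pa_pct": [99.80, 91.71, 77.11, 57.69, 94.64, 65.58],
        "ua_pct": [85.58, 69.85, 95.74, 87.68, 91.91, 60.54],
    },
}


def scheme_for(names):
    from reddmap import ClassScheme
    palette = [(220, 30, 30), (40, 160, 40), (90, 200, 210),
               (20, 40, 140), (240, 230, 80), (160, 80, 200)]
    return ClassScheme([(i + 1, n, palette[i]) for i, n in enumerate(names)])


def confusion_for(case):
    from reddmap import ConfusionMatrix
    d = REFERENCE_CASES[case]
    return ConfusionMatrix(d["matrix"], scheme_for(d["classes"]))
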