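"""Published benchmark accuracy-assessment matrices for the four-class
steppe habitat-mapping campaign (6-date UAV RGB time series, n = 8743).

Rows are true classes C0 (steppe), C1 (shrubs), C2 (forest-steppe),
C3 (bare/fallow land); columns are the predicted classes in the same order.
One matrix per descriptor family plus the combined and feature-selected
models; the dictionary below also records each model's per-pixel feature
dimensionality D.  These serve as fixed inputs for validating the metric
engine against independently reported aggregates.
"""

from __future__ import annotations

import numpy as np

from .model_eval import ConfusionMatrix

REFERENCE_MATRICES: dict[str, ConfusionMatrix] = {
    "spectral": ConfusionMatrix(np.array([
        [8319, 82, 51, 4],
        [11, 100, 12, 0],
        [64, 13, 57, 0],
        [26, 0, 2, 2],
    ])),
    "texture": ConfusionMatrix(np.array([
        [7953, 54, 449, 0],
        [12, 93, 17, 1],
        [1, 10, 118, 5],
        [7, 0, 5, 18],
    ])),
    "morphological": ConfusionMatrix(np.array([
        [8243, 78, 135, 0],
        [23, 100, 0, 0],
        [121, 9, 3, 1],
        [28, 1, 0, 1],
    ])),
    "combined": ConfusionMatrix(np.array([
        [8410, 8, 38, 0],
        [8, 107, 7, 1],
        [2, 4, 124, 4],
        [7, 0, 3, 20],
    ])),
    "selected": ConfusionMatrix(np.array([
        [8216, 160, 0, 80],
        [5, 108, 9, 1],
        [0, 8, 125, 1],
        [10, 1, 2, 17],
    ])),
}

#: Feature dimensionality D of each benchmark model (6 dates, per-date
#: families of 9 spectral / 54 texture / 11 morphological features).
REFERENCE_DIMENSIONALITY = {
    "spectral": 6 * 9,
    "texture": 6 * 54,
    "morphological": 6 * 11,
    "combined": 6 * 74,
    "selected": 15,
}

#: Aggregates reported alongside the matrices (overall accuracy in percent,
#: Cohen's kappa, and the 95% CI half-width of kappa).
REFERENCE_AGGREGATES = {
    "spectral": {"oa": 96.97, "kappa": 0.55, "kappa_ci95": 0.046},
    "texture": {"oa": 93.58, "kappa": 0.45, "kappa_ci95": 0.037},
    "morphological": {"oa": 95.47, "kappa": 0.34, "kappa_ci95": 0.048},
    "combined": {"oa": 99.06, "kappa": 0.86, "kappa_ci95": 0.029},
    "selected": {"oa": 96.83, "kappa": 0.64, "kappa_ci95": 0.038},
}

#: Per-class and average rows reported with the matrices, per model:
#: PA (producer's accuracy), UA (user's accuracy), ACC, F, each a list over
#: classes C0..C3 followed by the class average.
REFERENCE_PER_CLASS = {
    "spectral": {
        "PA": [0.98, 0.81, 0.43, 0.07], "UA": [0.99, 0.51, 0.47, 0.33],
        "ACC": [0.97, 0.99, 0.98, 1.00], "F": [0.99, 0.63, 0.45, 0.11],
        "avg": {"PA": 0.57, "UA": 0.58, "ACC": 0.98, "F": 0.54},
    },
    "texture": {
        "PA": [0.94, 0.76, 0.88, 0.60], "UA": [1.00, 0.59, 0.20, 0.75],
        "ACC": [0.94, 0.99, 0.94, 1.00], "F": [0.97, 0.66, 0.33, 0.67],
        "avg": {"PA": 0.79, "UA": 0.64, "ACC": 0.97, "F": 0.66},
    },
    "morphological": {
        "PA": [0.97, 0.81, 0.02, 0.03], "UA": [0.98, 0.53, 0.02, 0.50],
        "ACC": [0.96, 0.99, 0.97, 1.00], "F": [0.98, 0.64, 0.02, 0.06],
        "avg": {"PA": 0.46, "UA": 0.51, "ACC": 0.98, "F": 0.43},
    },
    "combined": {
        "PA": [0.99, 0.87, 0.93, 0.67], "UA": [1.00, 0.90, 0.72, 0.80],
        "ACC": [0.99, 1.00, 0.99, 1.00], "F": [1.00, 0.88, 0.81, 0.73],
        "avg": {"PA": 0.86, "UA": 0.85, "ACC": 1.00, "F": 0.85},
    },
    "selected": {
        "PA": [0.97, 0.88, 0.93, 0.57], "UA": [1.00, 0.39, 0.92, 0.17],
        "ACC": [0.97, 0.98, 1.00, 0.99], "F": [0.98, 0.54, 0.93, 0.26],
        "avg": {"PA": 0.84, "UA": 0.62, "ACC": 0.98, "F": 0.68},
    },
}
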