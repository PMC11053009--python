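"""Published benchmark classifier metrics used as worked-example inputs.

These are the reported per-dataset evaluation tables for five classifiers
on the two public cardiac benchmarks (the ambulatory arrhythmia corpus and
the clinical heart-disease table). They serve as *inputs* to the averaging
and difference-ratio arithmetic and the entropy scoring — the package does
not claim to reproduce them from raw data, which is external.
"""

from __future__ import annotations

import pandas as pd

METRIC_NAMES = ["AUC", "ACC", "F1", "Prec", "MCC", "FPR", "Se", "Sp", "G-mean"]
CLASSIFIERS = ["nn", "knn", "svm", "rf", "nb"]

# per-classifier rows: AUC, ACC, F1, Prec, MCC, FPR, Se, Sp, G-mean
ARRHYTHMIA_METRICS = pd.DataFrame(
    [
        [1.000, 0.998, 0.995, 0.996, 0.994, 0.0009, 0.994, 0.999, 0.995],
        [0.998, 0.994, 0.984, 0.987, 0.980, 0.0027, 0.980, 0.997, 0.983],
        [0.999, 0.998, 0.994, 0.994, 0.990, 0.0010, 0.994, 0.998, 0.994],
        [1.000, 0.999, 0.997, 0.998, 0.990, 0.0020, 0.996, 0.999, 0.997],
        [0.997, 0.980, 0.945, 0.930, 0.933, 0.0700, 0.961, 0.983, 0.945],
    ],
    index=CLASSIFIERS,
    columns=METRIC_NAMES,
)

HEART_DISEASE_METRICS = pd.DataFrame(
    [
        [0.874, 0.806, 0.806, 0.806, 0.611, 0.193, 0.804, 0.806, 0.649],
        [0.713, 0.690, 0.690, 0.691, 0.381, 0.339, 0.720, 0.660, 0.690],
        [0.798, 0.731, 0.730, 0.737, 0.468, 0.333, 0.799, 0.666, 0.733],
        [0.858, 0.783, 0.783, 0.783, 0.565, 0.220, 0.786, 0.799, 0.783],
        [0.885, 0.803, 0.806, 0.804, 0.527, 0.215, 0.822, 0.784, 0.803],
    ],
    index=CLASSIFIERS,
    columns=METRIC_NAMES,
)

# per-record beat-detection counts (record id -> N, CB, NMB) for the
# worked-example detection-score arithmetic
BEAT_COUNT_EXAMPLES = {
    "106": (2026, 2024, 2),
    "233": (3078, 3076, 2),
    "total": (100694, 100679, 15),
}
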