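"""Published MIT-BIH benchmark tables for the cumulant-model method.

Plain-data constants from the original MIT-BIH arrhythmia evaluation of
this method: per-class beat counts with the 60/40 train/test split, and the
one-vs-rest confusion counts of the three compared methods (cumulant-model
parameters, raw-signal-model parameters, full cumulant samples).  They
serve as worked-example inputs for the evaluation arithmetic — the metrics
recomputed from these counts must reproduce the published sensitivity and
specificity figures.

Confusion rows are kept exactly as published (the per-row arithmetic is
self-consistent even where row totals differ between tables).
"""

# class -> (total beats, training beats, test beats); 60/40 stratified split
CLASS_SPLIT_COUNTS = {
    "N":    (2000, 1200, 800),
    "PVC":  (2938, 1763, 1175),
    "APC":  (722, 433, 289),
    "RBBB": (2251, 1351, 900),
    "LBBB": (1456, 874, 582),
}

# class -> (total, TP, TN, FP, FN) on the 3746-beat test set
CUMULANT_MODEL_CONFUSION = {  # method 1: cumulant model parameters
    "N":    (800, 800, 2941, 5, 0),
    "PVC":  (289, 276, 3445, 12, 13),
    "APC":  (1175, 1155, 2556, 15, 20),
    "RBBB": (900, 895, 2839, 7, 5),
    "LBBB": (582, 570, 3153, 11, 12),
}

SIGNAL_MODEL_CONFUSION = {  # method 2: raw-signal model parameters
    "N":    (800, 799, 2936, 10, 1),
    "PVC":  (289, 272, 3444, 13, 17),
    "APC":  (1175, 1161, 2562, 9, 14),
    "RBBB": (900, 896, 2838, 8, 4),
    "LBBB": (582, 576, 3162, 2, 6),
}

FUSED_METHOD_CONFUSION = {  # method 3: fused cumulant-model classifier
    "N":    (800, 800, 2943, 3, 0),
    "PVC":  (289, 272, 3450, 7, 17),
    "APC":  (1175, 1166, 2559, 12, 9),
    "RBBB": (900, 896, 2835, 11, 4),
    "LBBB": (582, 574, 3159, 5, 8),
}

# published pooled (micro-averaged) percentages for the three methods
PUBLISHED_AVERAGES = {
    "cumulant_model": {"Se": 98.66, "Sp": 99.67},
    "signal_model": {"Se": 98.89, "Sp": 99.72},
    "fused_method": {"Se": 98.98, "Sp": 99.75},
}
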