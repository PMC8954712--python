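"""Frozen published benchmark values for the DYRK1A inhibitor classifiers.

``PERFORMANCE_ROWS`` holds every row of the published imbalanced and
SMOTE+Tomek-balanced model tables: confusion counts plus the printed
AUC/CA/MCC/SE/SP/BA.  AUC is not recomputable from counts and is carried for
context only.

``ERRATA`` pins the cells whose printed value is arithmetically inconsistent
with the row's own confusion counts under either balanced-accuracy rounding
convention (see the report module); the regression test asserts exact
reproduction everywhere else and asserts that the inconsistent set is
exactly this one.

``FRAGMENT_ROWS`` holds the published privileged-substructure statistics:
per-bit potent/non-potent occurrence counts with printed information gain
and class frequencies, over the 117-compound modeling set (89 P / 28 N).
``FRAGMENT_ERRATA`` marks the one bit whose printed potent-class frequency
(1.292) cannot be produced by the frequency formula from its own counts
(18 potent, 0 non-potent forces 117/89 = 1.315).
"""

# (table, split, model, auc, ca, mcc, tp, tn, fp, fn, se, sp, ba)
# mcc None = printed "-" (undefined: a zero confusion margin)
PERFORMANCE_ROWS = [
    # --- imbalanced models, pooled 5-fold CV on the 88-compound training set
    ("imbalanced", "train", "PubChemFP-SVM", 0.933, 0.909, 0.717, 67, 13, 6, 2, 0.971, 0.684, 0.828),
    ("imbalanced", "train", "SubFP-LR", 0.914, 0.864, 0.583, 64, 12, 7, 5, 0.928, 0.632, 0.780),
    ("imbalanced", "train", "PubChemFP-NB", 0.908, 0.807, 0.508, 57, 14, 5, 12, 0.826, 0.737, 0.782),
    ("imbalanced", "train", "PubChemFP-RF", 0.908, 0.920, 0.753, 68, 13, 6, 1, 0.986, 0.684, 0.835),
    ("imbalanced", "train", "SubFP-ANN", 0.908, 0.841, 0.530, 62, 12, 7, 7, 0.899, 0.632, 0.766),
    ("imbalanced", "train", "PubChemFP-LR", 0.904, 0.920, 0.755, 67, 14, 5, 2, 0.971, 0.737, 0.854),
    ("imbalanced", "train", "MACCSFP-RF", 0.900, 0.898, 0.678, 67, 12, 7, 2, 0.971, 0.632, 0.802),
    ("imbalanced", "train", "SubFP-Tree", 0.896, 0.875, 0.638, 63, 14, 5, 6, 0.913, 0.737, 0.825),
    ("imbalanced", "train", "EStateFP-ANN", 0.893, 0.852, 0.556, 63, 12, 7, 6, 0.913, 0.632, 0.773),
    ("imbalanced", "train", "PubChemFP-ANN", 0.893, 0.909, 0.743, 64, 16, 3, 5, 0.928, 0.842, 0.885),
    # --- imbalanced models, 29-compound test set
    ("imbalanced", "test", "PubChemFP-SVM", 0.911, 0.862, 0.705, 17, 8, 1, 3, 0.850, 0.889, 0.870),
    ("imbalanced", "test", "SubFP-LR", 0.903, 0.793, 0.493, 18, 5, 4, 2, 0.900, 0.556, 0.728),
    ("imbalanced", "test", "PubChemFP-NB", 0.881, 0.828, 0.647, 16, 8, 1, 4, 0.800, 0.889, 0.845),
    ("imbalanced", "test", "PubChemFP-RF", 0.917, 0.897, 0.761, 20, 6, 3, 0, 1.000, 0.667, 0.834),
    ("imbalanced", "test", "SubFP-ANN", 0.881, 0.793, 0.517, 17, 6, 3, 3, 0.850, 0.667, 0.759),
    ("imbalanced", "test", "PubChemFP-LR", 0.944, 0.862, 0.705, 17, 8, 1, 3, 0.850, 0.889, 0.870),
    ("imbalanced", "test", "MACCSFP-RF", 0.922, 0.862, 0.680, 20, 5, 4, 0, 1.000, 0.556, 0.778),
    ("imbalanced", "test", "SubFP-Tree", 0.825, 0.862, 0.517, 17, 6, 3, 3, 0.850, 0.667, 0.759),
    ("imbalanced", "test", "EStateFP-ANN", 0.858, 0.793, 0.517, 17, 6, 3, 3, 0.850, 0.667, 0.759),
    ("imbalanced", "test", "PubChemFP-ANN", 0.911, 0.862, 0.705, 17, 8, 1, 3, 0.850, 0.889, 0.870),
    # --- imbalanced models, 15-compound external validation set
    ("imbalanced", "validation", "PubChemFP-SVM", 0.660, 0.667, 0.213, 8, 2, 3, 2, 0.800, 0.400, 0.600),
    ("imbalanced", "validation", "SubFP-LR", 0.780, 0.667, 0.139, 9, 1, 4, 1, 0.900, 0.200, 0.550),
    ("imbalanced", "validation", "PubChemFP-NB", 0.660, 0.667, 0.378, 6, 4, 1, 4, 0.600, 0.400, 0.500),
    ("imbalanced", "validation", "PubChemFP-RF", 0.430, 0.600, -0.189, 9, 0, 5, 1, 0.600, 0.000, 0.300),
    ("imbalanced", "validation", "SubFP-ANN", 0.760, 0.733, 0.354, 9, 2, 3, 1, 0.900, 0.400, 0.650),
    ("imbalanced", "validation", "PubChemFP-LR", 0.760, 0.667, 0.139, 9, 1, 4, 1, 0.600, 0.100, 0.350),
    ("imbalanced", "validation", "MACCSFP-RF", 0.820, 0.667, None, 10, 0, 5, 0, 1.000, 0.000, 0.500),
    ("imbalanced", "validation", "SubFP-Tree", 0.600, 0.667, 0.213, 8, 2, 3, 2, 0.800, 0.400, 0.600),
    ("imbalanced", "validation", "EStateFP-ANN", 0.820, 0.667, 0.213, 8, 2, 3, 2, 0.800, 0.400, 0.600),
    ("imbalanced", "validation", "PubChemFP-ANN", 0.660, 0.733, 0.354, 9, 2, 3, 1, 0.900, 0.400, 0.650),
    # --- balanced models, pooled 5-fold CV on the SMOTE+Tomek training set
    ("balanced", "train", "PubChemFP-LR", 0.993, 0.948, 0.896, 63, 64, 3, 4, 0.940, 0.955, 0.948),
    ("balanced", "train", "PubChemFP-SVM", 0.990, 0.940, 0.881, 64, 62, 5, 3, 0.955, 0.925, 0.940),
    ("balanced", "train", "PubChemFP-ANN", 0.989, 0.955, 0.910, 64, 64, 3, 3, 0.955, 0.955, 0.955),
    ("balanced", "train", "MACCSFP-RF", 0.984, 0.954, 0.908, 62, 62, 3, 3, 0.954, 0.954, 0.954),
    ("balanced", "train", "PubChemFP-kNN", 0.983, 0.948, 0.896, 62, 65, 2, 5, 0.925, 0.970, 0.948),
    ("balanced", "train", "PubChemFP-RF", 0.979, 0.948, 0.896, 65, 62, 5, 2, 0.970, 0.925, 0.948),
    ("balanced", "train", "MACCSFP-LR", 0.974, 0.954, 0.908, 62, 62, 3, 3, 0.954, 0.954, 0.954),
    ("balanced", "train", "MACCSFP-kNN", 0.972, 0.954, 0.908, 61, 63, 2, 4, 0.938, 0.969, 0.954),
    ("balanced", "train", "SubFP-RF", 0.971, 0.888, 0.777, 61, 58, 9, 6, 0.910, 0.866, 0.888),
    ("balanced", "train", "SubFP-LR", 0.971, 0.881, 0.761, 59, 59, 8, 8, 0.881, 0.881, 0.881),
    # --- balanced models, test set (kept imbalanced)
    ("balanced", "test", "PubChemFP-LR", 0.808, 0.863, 0.577, 19, 5, 4, 1, 0.950, 0.556, 0.753),
    ("balanced", "test", "PubChemFP-SVM", 0.883, 0.828, 0.680, 20, 5, 4, 0, 1.000, 0.556, 0.778),
    ("balanced", "test", "PubChemFP-ANN", 0.836, 0.828, 0.493, 18, 5, 4, 2, 0.900, 0.556, 0.728),
    ("balanced", "test", "MACCSFP-RF", 0.933, 0.862, 0.667, 19, 6, 3, 1, 0.950, 0.667, 0.808),
    ("balanced", "test", "PubChemFP-kNN", 0.881, 0.862, 0.680, 20, 5, 4, 0, 1.000, 0.556, 0.778),
    ("balanced", "test", "PubChemFP-RF", 0.895, 0.862, 0.697, 20, 7, 3, 1, 0.952, 0.700, 0.826),
    ("balanced", "test", "MACCSFP-LR", 0.922, 0.862, 0.667, 19, 6, 3, 1, 0.950, 0.667, 0.808),
    ("balanced", "test", "MACCSFP-kNN", 0.811, 0.862, 0.680, 20, 5, 4, 0, 1.000, 0.556, 0.778),
    ("balanced", "test", "SubFP-RF", 0.872, 0.862, 0.680, 20, 5, 4, 0, 1.000, 0.556, 0.778),
    ("balanced", "test", "SubFP-LR", 0.806, 0.759, 0.393, 18, 4, 5, 2, 0.900, 0.444, 0.672),
    # --- balanced models, external validation set
    ("balanced", "validation", "PubChemFP-LR", 0.500, 0.600, 0.100, 7, 2, 3, 3, 0.700, 0.400, 0.550),
    ("balanced", "validation", "PubChemFP-SVM", 0.400, 0.600, 0.100, 7, 2, 3, 3, 0.700, 0.400, 0.550),
    ("balanced", "validation", "PubChemFP-ANN", 0.560, 0.533, 0.000, 6, 2, 3, 4, 0.600, 0.400, 0.500),
    ("balanced", "validation", "MACCSFP-RF", 0.640, 0.667, 0.139, 9, 1, 4, 1, 0.900, 0.200, 0.550),
    ("balanced", "validation", "PubChemFP-kNN", 0.330, 0.600, -0.189, 9, 0, 5, 1, 0.900, 0.000, 0.450),
    ("balanced", "validation", "PubChemFP-RF", 0.300, 0.600, -0.189, 9, 0, 5, 1, 0.900, 0.000, 0.450),
    ("balanced", "validation", "MACCSFP-LR", 0.760, 0.733, 0.378, 10, 1, 4, 0, 1.000, 0.200, 0.600),
    ("balanced", "validation", "MACCSFP-kNN", 0.590, 0.533, -0.277, 8, 0, 5, 2, 0.800, 0.000, 0.400),
    ("balanced", "validation", "SubFP-RF", 0.760, 0.773, 0.378, 10, 1, 4, 0, 1.000, 0.200, 0.600),
    ("balanced", "validation", "SubFP-LR", 0.520, 0.600, -0.189, 9, 0, 5, 1, 0.900, 0.000, 0.450),
]

# (table, split, model) -> metric cells that do NOT reproduce from the counts.
# The balanced-test RF row additionally sums to 31 on a 29-compound split.
ERRATA = {
    ("imbalanced", "test", "SubFP-Tree"): {"CA"},
    ("imbalanced", "validation", "PubChemFP-NB"): {"SP", "BA"},
    ("imbalanced", "validation", "PubChemFP-RF"): {"SE", "BA"},
    ("imbalanced", "validation", "PubChemFP-LR"): {"SE", "SP", "BA"},
    ("balanced", "test", "PubChemFP-LR"): {"CA"},
    ("balanced", "test", "PubChemFP-SVM"): {"CA"},
    ("balanced", "test", "PubChemFP-ANN"): {"CA"},
    ("balanced", "test", "PubChemFP-RF"): {"CA"},
    ("balanced", "validation", "SubFP-RF"): {"CA"},
}

# (bit, n_fragment_P, n_fragment_N, printed IG, printed freq_P, printed freq_N)
# over the modeling set: 89 potent, 28 non-potent, 117 total
FRAGMENT_ROWS = [
    ("PubchemFP187", 23, 0, 0.088, 1.315, 0.0),
    ("PubchemFP188", 23, 0, 0.088, 1.315, 0.0),
    ("PubchemFP260", 18, 0, 0.067, 1.292, 0.0),
    ("PubchemFP646", 17, 0, 0.063, 1.315, 0.0),
    ("PubchemFP645", 29, 2, 0.053, 1.230, 0.270),
    ("PubchemFP499", 32, 2, 0.064, 1.237, 0.246),
    ("PubchemFP547", 32, 2, 0.064, 1.237, 0.246),
    ("PubchemFP569", 36, 3, 0.060, 1.213, 0.321),
    ("PubchemFP611", 36, 3, 0.060, 1.213, 0.321),
    ("PubchemFP629", 41, 4, 0.062, 1.198, 0.371),
    ("PubchemFP658", 41, 4, 0.062, 1.198, 0.371),
    ("PubchemFP691", 49, 2, 0.144, 1.263, 0.164),
    ("PubchemFP702", 49, 2, 0.144, 1.263, 0.164),
    ("PubchemFP703", 48, 2, 0.139, 1.262, 0.167),
    ("PubchemFP720", 41, 2, 0.103, 1.253, 0.194),
    ("PubchemFP783", 41, 2, 0.103, 1.253, 0.194),
]

FRAGMENT_ERRATA = {"PubchemFP260": {"freq_P"}}

N_POTENT, N_NON_POTENT = 89, 28
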