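"""Published model-selection scores for *Tettigettalna* calling songs.

Seven-model information-criterion scores (and the Akaike weights
reported alongside them) for the six calling-song variables of the
published comparative study this package's analysis is shaped after.
They serve as worked-example inputs: recomputing the weights from the
scores exercises the AICc/weight bookkeeping against independently
reported values.

Model order: EB, BM, OU, BMS(calling site), OUMV(calling site),
OUMV(NDVI), BMS(NDVI).
"""

MODEL_ORDER = ("EB", "BM", "OU", "BMS_site", "OUMV_site",
               "OUMV_ndvi", "BMS_ndvi")

#: trait -> (information-criterion scores, reported Akaike weights)
PUBLISHED_MODEL_SCORES = {
    "CD": ([42.24, 38.20, 42.24, 49.59, 48.86, 42.71, 42.89],
           [0.09, 0.68, 0.09, 0.00, 0.00, 0.07, 0.07]),
    "NE": ([61.21, 57.17, 61.21, 60.73, 66.15, 61.24, 61.16],
           [0.08, 0.58, 0.08, 0.10, 0.01, 0.08, 0.08]),
    "ER": ([57.71, 53.50, 57.54, 52.66, 59.88, 60.60, 53.04],
           [0.03, 0.24, 0.03, 0.37, 0.01, 0.01, 0.31]),
    "ED": ([56.16, 52.11, 56.14, 52.65, 61.20, 58.45, 50.92],
           [0.03, 0.26, 0.03, 0.20, 0.00, 0.01, 0.47]),
    "ID": ([62.75, 58.46, 62.46, 58.61, 63.82, 65.24, 58.64],
           [0.04, 0.31, 0.04, 0.29, 0.02, 0.01, 0.29]),
    "DF": ([-12.97, -11.32, -7.27, 6.08, 12.62, 16.01, 7.63],
           [0.67, 0.29, 0.04, 0.00, 0.00, 0.00, 0.00]),
}

#: trait -> the best-supported model reported for it
PUBLISHED_BEST_MODEL = {
    "CD": "BM", "NE": "BM", "ER": "BMS_site", "ED": "BMS_ndvi",
    "ID": "BM", "DF": "EB",
}
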