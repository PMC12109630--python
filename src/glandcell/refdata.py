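"""Published reference results of the original GlandNet development study.

These tables were reported for the model's private 110-biopsy cohort and
cannot be recomputed here (the underlying patient data are not
shareable).  They serve two purposes: internal-consistency regression
checks (the metric identities must reproduce the printed values from the
printed ingredients) and dataset-count arithmetic checks.

All table values are percentages rounded to one decimal, as printed;
counts are nuclei unless stated otherwise.
"""

from __future__ import annotations

# Per-biopsy statistics of the 128-px patch model over three random test splits
# (row "avg" is the printed per-row mean).
PATCH128_TABLE = {
    1: dict(accuracy=87.6, sensitivity=91.1, specificity=84.6, ppv=83.3, npv=91.8, f1=87.0),
    2: dict(accuracy=88.7, sensitivity=70.3, specificity=95.1, ppv=83.1, npv=90.3, f1=76.2),
    3: dict(accuracy=90.3, sensitivity=15.5, specificity=98.3, ppv=49.9, npv=91.6, f1=23.6),
    "avg": dict(accuracy=88.8, sensitivity=58.9, specificity=92.6, ppv=72.1, npv=91.2, f1=62.3),
}

# Final-round results on the three consensus-best test biopsies.
BEST3_TABLE = {
    1: dict(accuracy=94.9, sensitivity=93.1, specificity=96.2, ppv=95.1, npv=94.7, f1=94.1),
    2: dict(accuracy=92.6, sensitivity=95.3, specificity=85.6, ppv=94.5, npv=87.5, f1=94.9),
    3: dict(accuracy=94.8, sensitivity=98.6, specificity=81.8, ppv=94.9, npv=94.4, f1=96.7),
    "avg": dict(accuracy=94.1, sensitivity=95.7, specificity=87.8, ppv=94.8, npv=92.2, f1=95.2),
}

# Final-round results on the three consensus-worst test biopsies.
WORST3_TABLE = {
    1: dict(accuracy=91.1, sensitivity=87.1, specificity=93.9, ppv=91.0, npv=91.1, f1=89.0),
    2: dict(accuracy=89.4, sensitivity=88.4, specificity=91.5, ppv=95.7, npv=78.8, f1=91.9),
    3: dict(accuracy=92.1, sensitivity=83.7, specificity=96.7, ppv=93.1, npv=91.7, f1=88.1),
    "avg": dict(accuracy=90.9, sensitivity=86.4, specificity=94.0, ppv=93.3, npv=87.2, f1=89.7),
}

# Printed averages of the derived error rates on the best-three biopsies.
BEST3_AVG_FPR = 12.2  # = 100 - average specificity
BEST3_AVG_FNR = 4.3   # = 100 - average sensitivity

# Validation-cohort false-negative-rate drops from round 1 to round 2 of the
# semi-supervised procedure (best-ranked and worst-ranked example biopsies).
VALIDATION_FNR_DROPS = {
    "best": (13.04, 5.76),
    "worst": (21.22, 7.57),
    "best_1": (14.64, 7.76),
    "best_3": (15.54, 8.18),
}

# Cohort bookkeeping: biopsies and nuclei (total, in-gland) per cohort.
COHORT_COUNTS = {
    "train": dict(biopsies=66, nuclei=646_426, gland=213_702),
    "val": dict(biopsies=22, nuclei=210_982, gland=60_310),
    "test": dict(biopsies=22, nuclei=407_364, gland=175_867),
}
TOTAL_BIOPSIES = 110
TOTAL_NUCLEI = 1_264_772
TOTAL_GLAND = 449_879

# The six consensus-selected test biopsies, fully hand-annotated.
SIX_BIOPSY_CELLS = 77_952
BEST3_GLAND_CELLS = 20_735
WORST3_STROMA_CELLS = 57_217
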