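"""Published summary statistics for the 85-genotype Lens diversity panel.

These are the printed population-level values from the hydroponic
phosphorus screen that this package re-implements analytically: per-trait
genotype-mean summaries under sufficient (SP, 300 uM) and low (LP, 3 uM)
phosphorus, and the heritability magnitudes used to calibrate the
synthetic-cohort defaults.  They are inputs to worked examples and to the
simulator calibration, not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

# Per-trait genotype-mean summaries: (max_SP, max_LP, min_SP, min_LP,
# mean_SP, mean_LP, CV%_SP, CV%_LP).
_SUMMARY_ROWS = {
    #        maxSP     maxLP    minSP   minLP   meanSP  meanLP  cvSP  cvLP
    "PRL": (50.00, 46.83, 19.50, 17.33, 35.72, 33.61, 9.11, 5.86),
    "TRL": (1211.40, 1380.41, 43.42, 80.44, 366.79, 418.34, 10.68, 8.61),
    "TSA": (171.87, 133.05, 9.45, 9.08, 59.02, 48.57, 10.26, 9.62),
    "ARD": (0.47, 0.46, 0.34, 0.33, 0.39, 0.38, 7.17, 6.97),
    "TRV": (1.80, 1.35, 0.10, 0.08, 0.52, 0.47, 11.14, 13.72),
    "TRT": (873.67, 640.33, 55.00, 42.40, 309.70, 235.14, 10.10, 13.14),
    "RF": (5630.67, 1830.33, 31.67, 44.33, 725.67, 445.80, 13.71, 10.41),
    "SDW": (260.00, 163.33, 78.89, 55.56, 148.65, 89.76, 12.60, 13.61),
    "RDW": (173.33, 88.89, 56.67, 43.33, 95.94, 61.20, 11.28, 8.67),
    "TDW": (424.44, 235.56, 151.11, 103.33, 244.59, 149.84, 11.35, 10.26),
    "RSR": (0.99, 1.14, 0.43, 0.40, 0.66, 0.71, 9.86, 10.73),
    "PUPE": (768.01, 266.49, 115.65, 19.50, 275.65, 84.80, 11.03, 14.20),
}

#: Genotype-mean trait summaries for the published panel.
PANEL_SUMMARY = pd.DataFrame.from_dict(
    _SUMMARY_ROWS, orient="index",
    columns=["max_SP", "max_LP", "min_SP", "min_LP",
             "mean_SP", "mean_LP", "cv_SP", "cv_LP"],
).rename_axis("trait")

#: Published percent change of the LP mean relative to the SP mean, 2 dp,
#: for the traits whose printed value is exactly reproducible from the
#: printed means (the published TSA and PUPE changes differ from
#: recomputation by 0.01 because the means themselves are rounded).
PUBLISHED_PERCENT_CHANGE = {
    "PRL": -5.91, "TRL": 14.05, "ARD": -2.56, "TRT": -24.07,
    "RF": -38.57, "SDW": -39.62, "RDW": -36.21, "TDW": -38.74, "RSR": 7.58,
}

#: Published broad-sense heritability per trait (single-condition SP, LP and
#: combined across P levels).  Used only to calibrate synthetic defaults.
PUBLISHED_HERITABILITY = pd.DataFrame.from_dict(
    {
        "PRL": (0.83, 0.75, 0.77), "TRL": (0.87, 0.81, 0.68),
        "TSA": (0.78, 0.77, 0.63), "ARD": (0.27, 0.56, 0.51),
        "TRV": (0.68, 0.86, 0.58), "TRT": (0.77, 0.75, 0.60),
        "RF": (0.82, 0.79, 0.87), "SDW": (0.64, 0.70, 0.62),
        "RDW": (0.75, 0.76, 0.55), "TDW": (0.78, 0.81, 0.59),
        "RSR": (0.71, 0.73, 0.38), "PUPE": (0.77, 0.83, 0.66),
    },
    orient="index", columns=["H_SP", "H_LP", "H_combined"],
).rename_axis("trait")

#: Ratio of interaction to genotypic variance in the published combined
#: analysis (genotype x P-level component over genotype component).
PUBLISHED_GE_RATIO = {
    "PRL": 80.69 / 185.89, "TRL": 155823.95 / 373387.29,
    "TSA": 2169.04 / 5911.29, "ARD": 0.0018 / 0.0020,
    "TRV": 0.22 / 0.51, "TRT": 67016.26 / 94974.36,
    "RF": 1100946.56 / 2552335.63, "SDW": 3743.80 / 4001.09,
    "RDW": 1113.83 / 1312.65, "TDW": 8221.86 / 9057.42,
    "RSR": 0.04 / 0.049, "PUPE": 10567.17 / 12490.84,
}

#: Published population-mean total dry weight under each arm (mg/plant),
#: the xC / xT of the stress-tolerance indices.
PANEL_MEAN_TDW = {"SP": 244.59, "LP": 149.84}
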