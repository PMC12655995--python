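"""Default per-trait parameters for simulating a cacao germplasm trial.

Grand means and genotypic/phenotypic variance components representative of a
large Amazonian fine-flavor cacao collection (113 accessions, clonally
propagated, two pooled evaluation seasons).  These drive the synthetic trial
generator: genotypic variance GV controls accession-to-accession spread and
environmental variance EV = PV - GV controls replicate noise.

Tuples are (mean, GV, PV) in the descriptor's own units (squared units for
the variances).
"""

from __future__ import annotations

# acronym: (grand mean, genotypic variance, phenotypic variance)
TRAIT_PARAMS: dict[str, tuple[float, float, float]] = {
    "LL": (27.90, 0.60, 1.51),
    "LW": (9.72, 0.17, 0.40),
    "PtL": (1.84, 0.01, 0.07),
    "PdL": (1.63, 0.05, 0.09),
    "SpL": (7.92, 0.96, 1.27),
    "SW": (2.63, 0.22, 0.28),
    "PL": (3.90, 0.16, 0.23),
    "PW": (2.11, 0.04, 0.08),
    "LgW": (2.71, 0.10, 0.19),
    "FL": (3.99, 1.67, 2.06),
    "StL": (6.76, 0.36, 0.50),
    "SL": (3.35, 0.01, 0.65),
    "OL": (1.71, 0.04, 0.09),
    "OW": (1.23, 0.03, 0.05),
    "SH": (0.36, 0.01, 0.01),
    "FM": (767.30, 53286.70, 68984.54),
    "FrL": (19.54, 7.29, 10.56),
    "FW": (9.85, 0.67, 1.05),
    "PrT": (2.06, 0.13, 0.19),
    "GD": (1.34, 0.08, 0.10),
    "PM": (545.16, 34718.83, 47675.19),
    "NL": (4.89, 0.02, 0.02),
    "TSS": (17.35, 1.51, 1.51),
    "NSL": (7.86, 0.67, 2.60),
    "FSMF": (147.29, 985.50, 1809.02),
    "NSF": (40.39, 24.52, 57.81),
    "SI": (1.28, 0.03, 0.11),
    "PI": (20.57, 1.60, 64.09),
    "NIS": (36.36, 18.69, 61.61),
    "NES": (4.03, 1.32, 8.40),
    "SeL": (26.12, 2.35, 5.14),
    "SD": (13.88, 0.86, 2.16),
    "ST": (9.09, 0.28, 1.82),
}

# Strong genotypic cross-correlations typical of cacao fruit/seed biometrics
# (fruit mass tracks pericarp mass and width; seed counts track each other).
DEFAULT_TRAIT_CORRELATIONS: dict[tuple[str, str], float] = {
    ("FM", "PM"): 0.95,
    ("FW", "PM"): 0.80,
    ("FM", "FW"): 0.78,
    ("NSL", "NSF"): 0.87,
    ("NSL", "NIS"): 0.89,
    ("NSF", "NIS"): 0.93,
}
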