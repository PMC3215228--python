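"""Published reference summary statistics for the healthy adult meniscus.

These are the calibration constants of the synthetic-cohort generator and
the phantom presets: per-sex means and standard deviations of every size and
position measure of the medial and lateral meniscus, plus the within-sex
Pearson correlations among the size measures, body height, body weight and
tibial plateau area.  They describe an asymptomatic reference sample of
right knees (40 men, 62 women, drawn from the OAI "non-exposed" reference
cohort) measured on coronal MRI at 1.5 mm slice thickness and 0.37 mm
in-plane resolution, with no radiographic knee OA and no MRI signs of
meniscus lesions.

Units: areas mm², volume mm³, thickness/width/extrusion/overlap mm,
coverage and uncovered fractions %, body height m, body weight kg.
Signed conventions: extrusion positive beyond the plateau rim; overlap
distance negative when the meniscal inner rim lies internal to the plateau
rim (hence the negative means below).
"""

from __future__ import annotations

#: Group sizes of the reference sample.
N_SUBJECTS = {"M": 40, "F": 62}

#: Acquisition geometry (mm): in-plane 0.37, coronal slice thickness 1.5.
ACQUISITION_SPACING = (0.37, 1.5, 0.37)

#: Anthropometrics: mean/SD of height (m) and weight (kg); age range (years).
BODY = {
    "M": {"height": (1.74, 0.07), "weight": (79.2, 8.2), "age_range": (45, 79)},
    "F": {"height": (1.64, 0.06), "weight": (62.3, 8.4), "age_range": (46, 69)},
}

#: Within-sex correlation of body height and weight (men, women).
HEIGHT_WEIGHT_R = (0.35, 0.58)

# (mean, SD) per measure; key order matches the published report layout.
_MEDIAL_MEN = {
    "ACdAB": (1169.0, 122.0), "V": (2407.0, 520.0), "TA": (620.0, 93.0),
    "FA": (714.0, 117.0), "EA": (440.0, 75.4), "TOT_A": (1774.0, 276.0),
    "TOTA_over_ACdAB": (1.52, 0.161), "Th_Me": (2.80, 0.292),
    "Th_Max": (7.71, 1.15), "Wid_Me": (9.93, 1.06), "Wid_Max": (18.8, 2.08),
    "TA_Uncovp": (10.0, 4.42), "Ex_Me": (1.24, 1.18), "Ex_Max": (8.05, 1.57),
    "ACdAB_Covp": (49.6, 5.72), "OvD_Me": (-12.0, 1.31), "OvD_Max": (-4.66, 1.44),
}
_MEDIAL_WOMEN = {
    "ACdAB": (952.0, 85.7), "V": (1853.0, 321.0), "TA": (518.0, 65.9),
    "FA": (597.0, 73.7), "EA": (365.0, 56.2), "TOT_A": (1480.0, 178.0),
    "TOTA_over_ACdAB": (1.56, 0.143), "Th_Me": (2.55, 0.245),
    "Th_Max": (7.15, 0.893), "Wid_Me": (9.11, 0.875), "Wid_Max": (16.9, 1.61),
    "TA_Uncovp": (12.2, 4.05), "Ex_Me": (1.83, 1.06), "Ex_Max": (7.55, 1.75),
    "ACdAB_Covp": (49.8, 5.37), "OvD_Me": (-10.7, 1.28), "OvD_Max": (-4.04, 1.15),
}
_LATERAL_MEN = {
    "ACdAB": (1101.0, 121.0), "V": (2441.0, 487.0), "TA": (651.0, 86.6),
    "FA": (746.0, 116.0), "EA": (451.0, 69.7), "TOT_A": (1848.0, 260.0),
    "TOTA_over_ACdAB": (1.68, 0.201), "Th_Me": (2.67, 0.260),
    "Th_Max": (7.23, 0.980), "Wid_Me": (10.1, 1.28), "Wid_Max": (14.2, 2.14),
    "TA_Uncovp": (6.36, 3.68), "Ex_Me": (-2.49, 1.26), "Ex_Max": (8.21, 1.95),
    "ACdAB_Covp": (57.8, 6.77), "OvD_Me": (-16.8, 2.08), "OvD_Max": (-10.1, 1.99),
}
_LATERAL_WOMEN = {
    "ACdAB": (864.0, 87.2), "V": (1824.0, 296.0), "TA": (503.0, 60.7),
    "FA": (581.0, 76.8), "EA": (379.0, 51.4), "TOT_A": (1463.0, 174.0),
    "TOTA_over_ACdAB": (1.70, 0.134), "Th_Me": (2.51, 0.237),
    "Th_Max": (6.75, 0.976), "Wid_Me": (8.60, 0.780), "Wid_Max": (12.5, 1.55),
    "TA_Uncovp": (5.70, 3.19), "Ex_Me": (-2.21, 0.990), "Ex_Max": (7.62, 1.54),
    "ACdAB_Covp": (58.3, 5.01), "OvD_Me": (-14.6, 1.30), "OvD_Max": (-8.41, 1.31),
}

# Published two-tailed p for the sex difference ("<0.001" kept as a string)
# and the published percent difference (men vs women, women-referenced).
_MEDIAL_P = {
    "ACdAB": "<0.001", "V": "<0.001", "TA": "<0.001", "FA": "<0.001",
    "EA": "<0.001", "TOT_A": "<0.001", "TOTA_over_ACdAB": "0.221",
    "Th_Me": "<0.001", "Th_Max": "0.008", "Wid_Me": "<0.001",
    "Wid_Max": "<0.001", "TA_Uncovp": "0.012", "Ex_Me": "0.011",
    "Ex_Max": "0.149", "ACdAB_Covp": "0.874", "OvD_Me": "<0.001",
    "OvD_Max": "0.021",
}
_MEDIAL_DIFF = {
    "ACdAB": 22.7, "V": 29.9, "TA": 19.6, "FA": 19.8, "EA": 20.5,
    "TOT_A": 19.9, "TOTA_over_ACdAB": -2.45, "Th_Me": 10.1, "Th_Max": 7.84,
    "Wid_Me": 8.99, "Wid_Max": 11.1, "TA_Uncovp": -18.2, "Ex_Me": -32.4,
    "Ex_Max": 6.65, "ACdAB_Covp": -0.36, "OvD_Me": 12.6, "OvD_Max": 15.2,
}
_LATERAL_P = {
    "ACdAB": "<0.001", "V": "<0.001", "TA": "<0.001", "FA": "<0.001",
    "EA": "<0.001", "TOT_A": "<0.001", "TOTA_over_ACdAB": "0.720",
    "Th_Me": "0.003", "Th_Max": "0.019", "Wid_Me": "<0.001",
    "Wid_Max": "<0.001", "TA_Uncovp": "0.342", "Ex_Me": "0.215",
    "Ex_Max": "0.101", "ACdAB_Covp": "0.668", "OvD_Me": "<0.001",
    "OvD_Max": "<0.001",
}
_LATERAL_DIFF = {
    "ACdAB": 27.5, "V": 33.9, "TA": 29.5, "FA": 28.4, "EA": 18.8,
    "TOT_A": 26.3, "TOTA_over_ACdAB": -0.72, "Th_Me": 6.23, "Th_Max": 7.11,
    "Wid_Me": 16.9, "Wid_Max": 13.0, "TA_Uncovp": 11.7, "Ex_Me": 12.9,
    "Ex_Max": 7.65, "ACdAB_Covp": -0.88, "OvD_Me": 15.6, "OvD_Max": 20.1,
}

# Within-sex Pearson correlations (r_men, r_women).  "ACdAB" is the
# ipsi-compartmental plateau area; unlisted pairs were not reported.
_MEDIAL_CORR = {
    ("V", "TOT_A"): (0.97, 0.96), ("V", "Th_Me"): (0.81, 0.82),
    ("V", "Wid_Me"): (0.78, 0.76), ("V", "height"): (0.27, 0.17),
    ("V", "weight"): (0.18, -0.05), ("V", "ACdAB"): (0.64, 0.60),
    ("TOT_A", "Th_Me"): (0.65, 0.66), ("TOT_A", "Wid_Me"): (0.75, 0.68),
    ("TOT_A", "height"): (0.27, 0.22), ("TOT_A", "weight"): (0.16, -0.03),
    ("TOT_A", "ACdAB"): (0.72, 0.67), ("Th_Me", "Wid_Me"): (0.59, 0.55),
    ("Th_Me", "height"): (0.20, 0.07), ("Th_Me", "weight"): (0.18, -0.04),
    ("Th_Me", "ACdAB"): (0.35, 0.34), ("Wid_Me", "height"): (0.07, 0.07),
    ("Wid_Me", "weight"): (0.03, -0.10), ("Wid_Me", "ACdAB"): (0.35, 0.37),
    ("height", "weight"): HEIGHT_WEIGHT_R,
    ("ACdAB", "height"): (0.61, 0.55), ("ACdAB", "weight"): (0.31, 0.19),
}
_LATERAL_CORR = {
    ("V", "TOT_A"): (0.98, 0.95), ("V", "Th_Me"): (0.85, 0.73),
    ("V", "Wid_Me"): (0.57, 0.61), ("V", "height"): (0.17, 0.51),
    ("V", "weight"): (-0.01, 0.24), ("V", "ACdAB"): (0.64, 0.68),
    ("TOT_A", "Th_Me"): (0.74, 0.50), ("TOT_A", "Wid_Me"): (0.64, 0.64),
    ("TOT_A", "height"): (0.19, 0.53), ("TOT_A", "weight"): (0.02, 0.22),
    ("TOT_A", "ACdAB"): (0.62, 0.75), ("Th_Me", "Wid_Me"): (0.29, 0.26),
    ("Th_Me", "height"): (0.09, 0.27), ("Th_Me", "weight"): (-0.04, 0.21),
    ("Th_Me", "ACdAB"): (0.55, 0.31), ("Wid_Me", "height"): (0.06, 0.21),
    ("Wid_Me", "weight"): (0.06, -0.07), ("Wid_Me", "ACdAB"): (0.01, 0.14),
    ("height", "weight"): HEIGHT_WEIGHT_R,
    ("ACdAB", "height"): (0.53, 0.57), ("ACdAB", "weight"): (0.10, 0.32),
}

REFERENCE = {
    "medial": {
        "M": _MEDIAL_MEN, "F": _MEDIAL_WOMEN,
        "p": _MEDIAL_P, "diff_pct": _MEDIAL_DIFF, "corr": _MEDIAL_CORR,
    },
    "lateral": {
        "M": _LATERAL_MEN, "F": _LATERAL_WOMEN,
        "p": _LATERAL_P, "diff_pct": _LATERAL_DIFF, "corr": _LATERAL_CORR,
    },
}

#: Measures reported with p < 0.001 for the sex difference.
def strongly_different_measures(compartment: str) -> list[str]:
    return [m for m, p in REFERENCE[compartment]["p"].items() if p == "<0.001"]
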