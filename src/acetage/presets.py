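"""Documented-study calibration data for the synthetic generator.

The generator is calibrated against the published summary statistics of
two documented skeletal collections: a Portuguese cemetery collection and
a North American donated collection.  Stored here are, per sex and
population: the mean chronological age at every stage of the seven
acetabular variables (the generator's attainment anchors), the per-stage
sample sizes, the decade-bin age counts of each collection (the
generator's age-structure weights), the documented reference/test split
sizes, and the documented per-pairing counts of no-estimation outcomes.
These are printed summary tables, not individual-level data; no real
individual is represented.
"""

from __future__ import annotations

# (variable, stage) -> (n, mean age, SD); SD None where not reported (n = 1
# or not printed).  Keys are the seven acetabular variables v1..v7.

PT_MALE_STAGE_STATS = {
    "v1": [(5, 17.40, 2.51), (131, 48.04, 19.16), (131, 60.61, 16.25), (27, 74.74, 9.20)],
    "v2": [(4, 21.50, 3.87), (20, 24.20, 9.20), (33, 32.64, 12.11), (39, 50.67, 16.13),
           (130, 60.19, 13.85), (52, 70.67, 11.40), (16, 75.94, 7.15)],
    "v3": [(10, 17.00, 1.56), (17, 24.88, 5.80), (51, 37.84, 12.01), (120, 57.13, 12.44),
           (61, 71.02, 11.54), (35, 75.09, 9.42)],
    "v4": [(17, 24.71, 6.25), (79, 39.09, 14.79), (119, 59.49, 13.36), (45, 71.40, 12.93),
           (34, 74.65, 9.56)],
    "v5": [(174, 45.15, 16.80), (102, 69.58, 12.21), (18, 76.94, 8.63)],
    "v6": [(26, 22.58, 7.51), (47, 42.85, 15.59), (177, 59.16, 15.43), (44, 74.20, 10.05)],
    "v7": [(21, 21.29, 3.89), (34, 40.91, 15.36), (142, 53.56, 15.53), (27, 67.67, 12.89),
           (70, 72.40, 11.75)],
}

PT_FEMALE_STAGE_STATS = {
    "v1": [(4, 17.50, 3.00), (157, 54.89, 21.82), (115, 69.09, 14.76), (41, 79.51, 9.28)],
    "v2": [(1, 15.00, None), (16, 23.38, 6.98), (17, 23.88, 9.17), (51, 52.61, 18.92),
           (158, 69.05, 14.00), (63, 74.11, 12.72), (11, 75.91, 12.47)],
    "v3": [(4, 17.50, 1.73), (14, 25.07, 6.71), (42, 33.00, 14.20), (128, 63.49, 13.69),
           (85, 75.02, 9.90), (44, 81.39, 7.38)],
    "v4": [(29, 26.76, 11.06), (69, 46.59, 19.07), (130, 70.62, 11.58), (52, 73.50, 12.84),
           (37, 78.35, 10.72)],
    "v5": [(134, 46.54, 20.03), (158, 73.56, 11.09), (25, 81.28, 8.60)],
    "v6": [(33, 24.61, 7.67), (21, 34.76, 12.42), (168, 65.14, 15.05), (95, 77.97, 8.27)],
    "v7": [(14, 20.07, 4.16), (38, 32.21, 12.74), (90, 57.28, 14.99), (53, 70.09, 9.47),
           (122, 78.01, 9.46)],
}

NA_MALE_STAGE_STATS = {
    "v1": [(6, 28.86, 6.27), (250, 55.90, 15.68), (157, 65.68, 12.98), (43, 74.00, 12.09)],
    "v2": [(0, None, None), (4, 25.50, 5.00), (11, 37.18, 15.10), (49, 44.73, 12.18),
           (226, 60.09, 13.78), (134, 67.05, 13.92), (32, 74.16, 11.90)],
    "v3": [(0, None, None), (4, 30.25, 5.74), (30, 36.73, 9.17), (191, 53.55, 11.98),
           (126, 68.59, 12.49), (105, 71.90, 12.43)],
    "v4": [(3, 28.67, 8.08), (52, 41.92, 11.33), (196, 58.01, 14.27), (114, 66.04, 12.94),
           (91, 71.19, 13.26)],
    "v5": [(217, 51.24, 13.83), (196, 67.85, 12.65), (43, 74.98, 12.41)],
    "v6": [(11, 33.55, 7.79), (59, 48.54, 14.95), (259, 59.22, 14.60), (127, 71.43, 11.49)],
    "v7": [(7, 39.43, 7.74), (35, 44.43, 11.31), (170, 53.35, 14.74), (44, 62.30, 13.61),
           (200, 70.00, 12.03)],
}

NA_FEMALE_STAGE_STATS = {
    "v1": [(0, None, None), (172, 60.29, 14.36), (146, 67.86, 12.43), (52, 72.60, 14.93)],
    "v2": [(0, None, None), (0, None, None), (1, 33.00, None), (25, 47.04, 11.91),
           (200, 64.78, 13.24), (116, 69.07, 14.14), (28, 66.96, 13.11)],
    "v3": [(0, None, None), (0, None, None), (9, 37.44, 5.43), (159, 59.64, 12.15),
           (129, 69.39, 12.69), (73, 72.34, 14.46)],
    "v4": [(4, 49.75, 16.66), (31, 48.84, 12.76), (171, 64.73, 13.70), (87, 67.36, 13.44),
           (77, 70.26, 12.67)],
    "v5": [(111, 55.29, 12.66), (211, 68.78, 12.93), (48, 70.90, 13.96)],
    "v6": [(7, 44.00, 13.61), (19, 54.63, 12.02), (189, 60.48, 13.62), (155, 72.74, 11.44)],
    "v7": [(6, 36.17, 8.33), (15, 46.67, 12.02), (109, 56.85, 11.23), (44, 68.89, 11.37),
           (196, 70.95, 12.53)],
}

STAGE_STATS = {
    ("PT", "M"): PT_MALE_STAGE_STATS,
    ("PT", "F"): PT_FEMALE_STAGE_STATS,
    ("NA", "M"): NA_MALE_STAGE_STATS,
    ("NA", "F"): NA_FEMALE_STAGE_STATS,
}


def stage_mean_anchors(population: str, sex: str) -> dict[str, list[float]]:
    """Per-variable stage-mean-age anchors for the generator."""
    return {
        var: [mean for (_n, mean, _sd) in rows]
        for var, rows in STAGE_STATS[(population, sex)].items()
    }


def stage_counts(population: str, sex: str) -> dict[str, list[int]]:
    """Per-variable per-stage sample sizes of the documented collections."""
    return {
        var: [n for (n, _mean, _sd) in rows]
        for var, rows in STAGE_STATS[(population, sex)].items()
    }


# Decade-bin age counts of the analyzed individuals, by population and sex.
# Bins: <20, 20-29, ..., 80-89, >=90.
AGE_BIN_EDGES: list[tuple[int, int]] = [
    (15, 19), (20, 29), (30, 39), (40, 49), (50, 59),
    (60, 69), (70, 79), (80, 89), (90, 104),
]

AGE_BIN_COUNTS = {
    ("PT", "M"): [12, 24, 24, 48, 57, 48, 40, 41, 0],
    ("PT", "F"): [13, 25, 14, 18, 47, 45, 85, 60, 10],
    ("NA", "M"): [1, 9, 40, 74, 84, 101, 89, 51, 7],
    ("NA", "F"): [0, 2, 14, 38, 75, 98, 78, 48, 17],
}

# Documented reference/test split sizes per population and sex.
REFERENCE_SIZES = {("PT", "M"): 184, ("PT", "F"): 201,
                   ("NA", "M"): 300, ("NA", "F"): 220}
TEST_SIZES = {("PT", "M"): 110, ("PT", "F"): 116,
              ("NA", "M"): 156, ("NA", "F"): 150}

# Documented no-estimation counts per (test sample, reference sample)
# pairing, as (test_population, test_sex, reference_population): count.
# Matched pairings first, crossed pairings second.
DOCUMENTED_NO_ESTIMATION_COUNTS = {
    ("PT", "F", "PT"): 0,
    ("PT", "M", "PT"): 1,
    ("NA", "F", "NA"): 1,
    ("NA", "M", "NA"): 2,
    ("PT", "F", "NA"): 14,
    ("PT", "M", "NA"): 6,
    ("NA", "F", "PT"): 4,
    ("NA", "M", "PT"): 3,
}
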