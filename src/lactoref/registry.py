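"""Packaged parameter tables: the 34-analyte plasma panel and the 11-farm herd table.

The analyte table carries, per analyte and lactation phase, the number of
samples retained in the reference population and the mean/SD of the healthy
distribution, plus the unit string and whether the analyte is ln-transformed
before normality-gated statistics.  These values parameterize the synthetic
herd generator and the report formats; they are not recomputed at run time.
"""

from __future__ import annotations

# Phase labels in physiological order, with their days-from-calving windows
# (closed integer intervals; negative = before calving).
PHASE_ORDER: tuple[str, ...] = ("dry", "postpartum", "early_lactation", "late_lactation")

PHASE_WINDOWS: dict[str, tuple[int, int]] = {
    "dry": (-30, -10),
    "postpartum": (3, 7),
    "early_lactation": (28, 45),
    "late_lactation": (160, 305),
}

# The dry phase additionally requires 30-50 days from dry-phase onset when known.
DRY_ONSET_WINDOW: tuple[int, int] = (30, 50)

# Retinol display conversion: µmol/L × 28.645 = µg/100 mL.
RETINOL_UG_PER_100ML_FACTOR = 28.645

# Analytes whose distributions fail the ±1.5 skew/kurtosis normality gate and
# are ln-transformed before ANOVA/pairwise testing.
LOG_TRANSFORMED = frozenset({"BHB", "Zn", "AOPP"})

# name, unit, n per phase (dry, postpartum, early, late),
# (mean, sd) per phase in the same order, model R².
# The Zn unit string is stored verbatim from the source table ("mmol/L") even
# though µmol/L is the physiologically plausible unit; no correction is applied.
ANALYTE_TABLE: list[tuple] = [
    ("PCV", "L/L", (75, 78, 59, 65),
     ((0.34, 0.03), (0.34, 0.02), (0.30, 0.02), (0.33, 0.03)), 0.29),
    ("Glucose", "mmol/L", (74, 81, 60, 64),
     ((4.22, 0.23), (3.87, 0.34), (4.15, 0.26), (4.35, 0.28)), 0.29),
    ("Fructosamine", "mmol/L", (75, 80, 62, 65),
     ((288.0, 22.3), (273.0, 27.2), (278.0, 28.8), (298.0, 28.2)), 0.11),
    ("NEFA", "mmol/L", (75, 80, 63, 64),
     ((0.18, 0.11), (0.67, 0.33), (0.33, 0.19), (0.11, 0.04)), 0.55),
    ("BHB", "mmol/L", (75, 80, 63, 64),
     ((0.42, 0.10), (0.67, 0.21), (0.50, 0.19), (0.45, 0.17)), 0.26),
    ("Triglycerides", "mmol/L", (76, 75, 63, 65),
     ((0.22, 0.05), (0.10, 0.02), (0.10, 0.02), (0.10, 0.02)), 0.71),
    ("Urea", "mmol/L", (76, 81, 63, 65),
     ((4.22, 1.37), (4.36, 1.20), (4.98, 1.28), (5.22, 0.78)), 0.11),
    ("Creatinine", "µmol/L", (75, 80, 63, 64),
     ((97.5, 10.5), (91.0, 8.47), (84.3, 6.29), (84.8, 5.50)), 0.31),
    ("Ca", "mmol/L", (76, 78, 62, 65),
     ((2.57, 0.11), (2.40, 0.15), (2.55, 0.13), (2.56, 0.13)), 0.23),
    ("P", "mmol/L", (65, 81, 63, 65),
     ((2.02, 0.20), (1.62, 0.45), (1.63, 0.34), (1.86, 0.29)), 0.20),
    ("Mg", "mmol/L", (75, 81, 63, 65),
     ((0.99, 0.08), (0.91, 0.13), (1.09, 0.10), (1.06, 0.10)), 0.32),
    ("Na", "mmol/L", (76, 80, 63, 65),
     ((145.0, 4.25), (147.0, 3.56), (144.0, 4.14), (143.0, 3.91)), 0.15),
    ("K", "mmol/L", (75, 79, 62, 63),
     ((4.30, 0.35), (4.23, 0.38), (4.23, 0.48), (4.18, 0.30)), 0.01),
    ("Cl", "mmol/L", (76, 79, 63, 64),
     ((106.0, 3.52), (106.0, 2.94), (104.0, 3.15), (103.0, 2.68)), 0.19),
    ("Zn", "mmol/L", (76, 81, 63, 62),
     ((14.3, 2.54), (12.6, 3.69), (13.2, 2.71), (13.6, 3.74)), 0.04),
    ("Total bilirubin", "µmol/L", (73, 75, 61, 65),
     ((1.67, 0.75), (5.65, 2.79), (2.31, 1.00), (1.54, 0.51)), 0.54),
    ("AST", "U/L", (75, 72, 56, 58),
     ((83.8, 14.9), (109.0, 15.5), (95.2, 12.7), (105.0, 21.4)), 0.28),
    ("GGT", "U/L", (75, 71, 57, 57),
     ((24.3, 6.81), (20.5, 4.03), (25.4, 4.52), (31.6, 6.21)), 0.34),
    ("ALP", "U/L", (70, 78, 62, 65),
     ((48.5, 13.9), (49.2, 15.6), (42.8, 13.6), (49.7, 12.8)), 0.04),
    ("Myeloperoxidase", "U/L", (73, 77, 57, 64),
     ((438.0, 54.4), (504.0, 53.3), (461.0, 55.5), (458.0, 61.0)), 0.17),
    ("Total protein", "g/L", (76, 81, 63, 62),
     ((80.0, 5.23), (74.0, 4.82), (82.3, 4.35), (83.8, 3.84)), 0.41),
    ("Globulin", "g/L", (76, 80, 63, 65),
     ((43.4, 5.51), (38.6, 4.14), (44.6, 5.18), (45.7, 5.01)), 0.24),
    ("Haptoglobin", "g/L", (71, 81, 53, 55),
     ((0.17, 0.06), (0.84, 0.51), (0.18, 0.07), (0.13, 0.07)), 0.55),
    ("Ceruloplasmin", "µmol/L", (76, 81, 63, 62),
     ((2.22, 0.39), (2.93, 0.51), (2.46, 0.56), (2.39, 0.45)), 0.25),
    ("Albumin", "g/L", (75, 77, 63, 63),
     ((36.6, 1.60), (35.3, 2.17), (37.6, 2.21), (38.5, 1.75)), 0.27),
    ("Cholesterol", "mmol/L", (69, 80, 63, 61),
     ((3.05, 0.65), (2.06, 0.46), (4.66, 1.34), (6.13, 1.22)), 0.73),
    ("Retinol", "µmol/L", (73, 81, 57, 65),
     ((1.04, 0.20), (0.81, 0.27), (1.23, 0.22), (1.41, 0.28)), 0.46),
    ("Paraoxonase", "U/mL", (72, 81, 61, 65),
     ((87.1, 16.1), (73.2, 18.1), (101.6, 20.3), (95.0, 16.7)), 0.27),
    ("Tocopherol", "µmol/L", (73, 80, 61, 65),
     ((5.03, 2.03), (3.49, 1.13), (7.26, 2.63), (10.93, 3.80)), 0.56),
    ("Beta-carotene", "µmol/L", (70, 69, 59, 59),
     ((4.02, 1.94), (2.32, 0.98), (3.64, 1.60), (6.74, 2.84)), 0.41),
    ("FRAP", "mmol/L", (73, 78, 62, 65),
     ((126.0, 13.6), (150.0, 25.4), (149.0, 21.7), (149.0, 18.0)), 0.21),
    ("Thiol groups", "mmol/L", (75, 81, 62, 64),
     ((338.0, 59.1), (351.0, 73.3), (354.0, 61.8), (361.0, 64.9)), 0.02),
    ("ROMt", "mg H2O2/dL", (75, 77, 63, 65),
     ((13.5, 3.10), (16.6, 3.40), (13.5, 3.63), (12.9, 2.71)), 0.18),
    ("AOPP", "mmol/L", (76, 81, 62, 65),
     ((63.8, 23.3), (46.6, 18.7), (59.0, 22.5), (63.9, 19.0)), 0.11),
]

# 11 high-welfare herds: milking system (MP parlor / AU automatic unit), daily
# milking frequency, days open, lactating cows, 305-d energy-corrected milk
# (kg), welfare cluster scores (%), and cows enrolled per lactation phase.
FARM_TABLE: list[dict] = [
    {"farm_id": "1", "milking_system": "MP", "milking_frequency": 2.0,
     "days_open": 99, "lactating_cows": 184, "ecm_305": 11291,
     "env_score": 75, "feed_score": 88, "animal_score": 79,
     "enrolled": {"dry": 6, "postpartum": 6, "early_lactation": 7, "late_lactation": 8}},
    {"farm_id": "2", "milking_system": "MP", "milking_frequency": 2.0,
     "days_open": 109, "lactating_cows": 210, "ecm_305": 10349,
     "env_score": 75, "feed_score": 87, "animal_score": 74,
     "enrolled": {"dry": 6, "postpartum": 6, "early_lactation": 6, "late_lactation": 6}},
    {"farm_id": "3", "milking_system": "MP", "milking_frequency": 2.0,
     "days_open": 93, "lactating_cows": 394, "ecm_305": 12435,
     "env_score": 70, "feed_score": 83, "animal_score": 80,
     "enrolled": {"dry": 6, "postpartum": 4, "early_lactation": 8, "late_lactation": 8}},
    {"farm_id": "4", "milking_system": "MP", "milking_frequency": 2.0,
     "days_open": 104, "lactating_cows": 864, "ecm_305": 10841,
     "env_score": 80, "feed_score": 76, "animal_score": 74,
     "enrolled": {"dry": 21, "postpartum": 28, "early_lactation": 13, "late_lactation": 11}},
    {"farm_id": "5", "milking_system": "MP", "milking_frequency": 2.0,
     "days_open": 119, "lactating_cows": 280, "ecm_305": 11203,
     "env_score": 70, "feed_score": 87, "animal_score": 73,
     "enrolled": {"dry": 10, "postpartum": 10, "early_lactation": 10, "late_lactation": 8}},
    {"farm_id": "6", "milking_system": "AU", "milking_frequency": 2.9,
     "days_open": 120, "lactating_cows": 107, "ecm_305": 10055,
     "env_score": 77, "feed_score": 86, "animal_score": 67,
     "enrolled": {"dry": 6, "postpartum": 5, "early_lactation": 6, "late_lactation": 6}},
    {"farm_id": "7", "milking_system": "MP", "milking_frequency": 2.0,
     "days_open": 139, "lactating_cows": 311, "ecm_305": 10007,
     "env_score": 75, "feed_score": 82, "animal_score": 71,
     "enrolled": {"dry": 7, "postpartum": 6, "early_lactation": 6, "late_lactation": 8}},
    {"farm_id": "8", "milking_system": "MP", "milking_frequency": 2.0,
     "days_open": 118, "lactating_cows": 304, "ecm_305": 10098,
     "env_score": 66, "feed_score": 83, "animal_score": 76,
     "enrolled": {"dry": 6, "postpartum": 6, "early_lactation": 2, "late_lactation": 6}},
    {"farm_id": "9", "milking_system": "MP", "milking_frequency": 2.0,
     "days_open": 129, "lactating_cows": 175, "ecm_305": 10025,
     "env_score": 67, "feed_score": 89, "animal_score": 70,
     "enrolled": {"dry": 10, "postpartum": 7, "early_lactation": 6, "late_lactation": 8}},
    {"farm_id": "10", "milking_system": "MP", "milking_frequency": 2.0,
     "days_open": 112, "lactating_cows": 378, "ecm_305": 10147,
     "env_score": 70, "feed_score": 76, "animal_score": 72,
     "enrolled": {"dry": 6, "postpartum": 7, "early_lactation": 6, "late_lactation": 6}},
    {"farm_id": "11", "milking_system": "MP", "milking_frequency": 2.0,
     "days_open": 128, "lactating_cows": 338, "ecm_305": 9695,
     "env_score": 66, "feed_score": 84, "animal_score": 70,
     "enrolled": {"dry": 8, "postpartum": 18, "early_lactation": 14, "late_lactation": 7}},
]

# Subclinical-disorder exclusion tallies per phase (animals retrospectively
# excluded from the enrolled cohort by the screening rules).
SCD_EXCLUDED_PER_PHASE: dict[str, int] = {
    "dry": 16, "postpartum": 22, "early_lactation": 21, "late_lactation": 17,
}
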