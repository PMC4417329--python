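"""Published population tabulations used for internal-consistency checks.

These are the printed marginal tables of a two-period (1995 vs 2010)
population-wide dispensing analysis for a Scottish health-board region
of ~310,000 adults: patient counts by drug-count band, by BNF chapter,
by number of chapters, and by number of potentially serious drug-drug
interactions, together with the printed crude percentages, directly
age-sex standardised percentages (2010 standardised to the 1995
structure) and standardised relative risks. The underlying patient-level
data are not publicly available; these marginals serve as fixed inputs
for arithmetic-consistency tests (percentages and ratios recomputed from
the printed counts must round back to the printed values) and give the
synthetic-data generator its calibration targets.

Counts are patients; percentages are as printed (1 decimal place, or
2 for small chapter rates).
"""

N_1995 = 301_019
N_2010 = 311_881

# drug-count bands: (n_1995, pct_1995, n_2010, pct_2010, std_pct_2010, srr)
DRUG_BANDS = {
    "0":     (148_828, 49.4, 128_155, 41.1, 42.8, 0.87),
    "1-4":   (117_829, 39.1, 114_540, 36.7, 36.4, 0.93),
    "5-9":   (29_311, 9.7, 50_972, 16.3, 15.3, 1.57),
    "10-14": (4_481, 1.5, 14_662, 4.7, 4.4, 2.92),
    "15+":   (570, 0.2, 3_552, 1.1, 1.1, 5.58),
}

# dispensing from each BNF chapter: same column layout
CHAPTER_ROWS = {
    1: (37_813, 12.6, 56_536, 18.1, 17.1, 1.36),
    2: (50_593, 16.8, 85_140, 27.3, 25.2, 1.49),
    3: (18_368, 6.1, 24_760, 7.9, 7.7, 1.26),
    4: (55_920, 18.6, 81_902, 26.3, 25.4, 1.37),
    5: (48_610, 16.1, 46_934, 15.0, 14.8, 0.92),
    6: (26_469, 8.8, 44_695, 14.3, 13.5, 1.53),
    7: (11_695, 3.9, 23_126, 7.4, 7.4, 1.91),
    8: (1_686, 0.6, 3_062, 1.0, 0.9, 1.64),
    9: (8_634, 2.9, 15_217, 4.9, 4.7, 1.62),
    10: (26_166, 8.7, 26_185, 8.4, 8.0, 0.92),
    11: (8_166, 2.7, 11_726, 3.8, 3.5, 1.30),
    12: (8_633, 2.9, 12_459, 4.0, 3.8, 1.34),
    13: (23_345, 7.8, 31_644, 10.1, 9.9, 1.28),
}

# number of distinct chapters dispensed from
N_CHAPTER_BANDS = {
    "0": (148_828, 49.4, 128_155, 41.1, 42.8, 0.87),
    "1": (65_584, 21.8, 64_625, 20.7, 20.7, 0.95),
    "2": (40_561, 13.5, 45_439, 14.6, 14.2, 1.05),
    "3": (22_548, 7.5, 30_129, 9.7, 9.2, 1.23),
    "4": (12_581, 4.2, 19_646, 6.3, 5.9, 1.42),
    "5+": (10_917, 3.6, 23_887, 7.7, 7.1, 1.97),
}

# potentially serious DDIs: any, and by number of interactions
DDI_ANY = (17_448, 5.8, 40_689, 13.0, 12.1, 2.08)
DDI_BAND_ROWS = {
    "0": (283_571, 94.2, 271_192, 86.9, 87.9, 0.91),
    "1": (13_051, 4.3, 23_907, 7.7, 7.1, 2.41),
    "2": (3_151, 1.0, 9_324, 3.0, 2.8, 5.54),
    "3": (814, 0.3, 3_776, 1.2, 1.1, 7.03),
    "4+": (432, 0.1, 3_682, 1.2, 1.1, 13.8),
}

# 2010 cohort strata used by the multilevel models (patients per level)
MODEL_2010_AGE_N = {
    "20-29": 51_197, "30-39": 47_857, "40-49": 60_077, "50-59": 52_751,
    "60-69": 47_080, "70-79": 32_986, "80+": 19_933,
}
MODEL_2010_SEX_N = {"M": 151_202, "F": 160_679}
MODEL_2010_RESIDENCE_N = {"own_home": 308_660, "care_home": 3_221}

# DDI model cohort (dispensed >= 2 classes); the published own-home count
# is corrected for an obvious misprint (13,615 -> 137,615; the strata
# must sum to the 140,613 denominator)
DDI_MODEL_N = 140_613
DDI_MODEL_AGE_N = {
    "20-29": 9_976, "30-39": 12_294, "40-49": 18_805, "50-59": 23_565,
    "60-69": 30_756, "70-79": 27_240, "80+": 17_977,
}
DDI_MODEL_SEX_N = {"M": 58_466, "F": 82_147}
DDI_MODEL_RESIDENCE_N = {"own_home": 137_615, "care_home": 2_998}
DDI_MODEL_DRUG_BAND_N = {"2-4": 71_427, "5-9": 50_972, "10-14": 14_662, "15+": 3_552}

# empty-model intraclass correlations reported for the two outcomes
ICC_POLY10 = 0.009
ICC_ANY_DDI = 0.031
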