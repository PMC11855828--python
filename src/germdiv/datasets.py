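"""Bundled reference data for an EMS-mutagenized "M82" processing-tomato M2 panel.

These constants hold the published summary tables of a germplasm evaluation of
33 processing-tomato accessions derived from "M82" by EMS mutagenesis:
qualitative trait-level frequencies with their Shannon-Wiener indices,
descriptive statistics of 15 quantitative traits, per-sample SNP substitution
counts, genome-region tallies of the SNP annotation, the loadings /
eigenvalues of the first six principal components of the trait correlation
matrix, and the per-accession component scores with composite score and rank.

The raw accession-level field data behind these summaries are not public; the
:mod:`germdiv.synthetic` module generates accession-level data matching these
summary statistics so every stage of the analysis can be exercised end to end.
"""

from __future__ import annotations

import pandas as pd

from .trait_model import TraitDescriptor

# ---------------------------------------------------------------------------
# Qualitative trait coding (descriptor dictionary)
# ---------------------------------------------------------------------------

#: Level codes for the qualitative descriptors, following the national
#: description norms for tomato germplasm resources.
QUALITATIVE_CODING: list[TraitDescriptor] = [
    TraitDescriptor("hypocotyl color", "qualitative", levels={1: "green", 2: "purple"}),
    TraitDescriptor("growth habit", "qualitative",
                    levels={1: "infinite growth", 2: "finite growth"}),
    TraitDescriptor("plant type", "qualitative",
                    levels={1: "vine type", 2: "half-vine type", 3: "upright"}),
    TraitDescriptor("stem leaf pubescence", "qualitative",
                    levels={0: "no", 1: "short thin", 2: "short dense",
                            3: "long thin", 4: "long dense"}),
    TraitDescriptor("leaf type", "qualitative",
                    levels={1: "common leaf type", 2: "potato leaf type",
                            3: "compound broad leaf type", 4: "complex fine leaf type"}),
    TraitDescriptor("leaf shape", "qualitative",
                    levels={1: "pinnate complex leaves",
                            2: "bipinnate complex leaves"}),
    TraitDescriptor("leaf attitude", "qualitative",
                    levels={1: "upright", 2: "horizontal", 3: "drooping"}),
    TraitDescriptor("leaf color", "qualitative",
                    levels={1: "yellow-green", 2: "light green",
                            3: "green", 4: "dark green"}),
    TraitDescriptor("leaf vein color", "qualitative",
                    levels={1: "colorless", 2: "green"}),
    TraitDescriptor("leaf lobing depth", "qualitative",
                    levels={0: "no", 1: "shallow", 2: "medium", 3: "deep"}),
    TraitDescriptor("inflorescence type", "qualitative",
                    levels={1: "single flowers", 2: "single inflorescence",
                            3: "double flowers", 4: "multiple inflorescences"}),
    TraitDescriptor("flower clustering", "qualitative", levels={0: "no", 1: "yes"}),
    TraitDescriptor("style length", "qualitative",
                    levels={1: "shorter than stamen",
                            2: "nearly equal length to stamen",
                            3: "longer than stamen"}),
    TraitDescriptor("flower color", "qualitative",
                    levels={1: "light yellow", 2: "yellow", 3: "orange yellow"}),
    TraitDescriptor("pedicel abscission layer", "qualitative",
                    levels={0: "no", 1: "yes"}),
    TraitDescriptor("fruit ridging", "qualitative",
                    levels={0: "no", 1: "light", 2: "medium", 3: "heavy"}),
    TraitDescriptor("fruit apex shape", "qualitative",
                    levels={1: "deep concave", 2: "micro concave", 3: "round flat",
                            4: "micro convex", 5: "convex tip"}),
    TraitDescriptor("fruit shoulder shape", "qualitative",
                    levels={0: "no", 1: "flat", 2: "microconcave", 3: "deep concave"}),
    TraitDescriptor("fruit shape", "qualitative",
                    levels={1: "flat", 2: "oblate", 3: "circle", 4: "high circle",
                            5: "long circle", 6: "oval", 7: "peach circle",
                            8: "pear-shaped", 9: "long pear-shaped"}),
]

# ---------------------------------------------------------------------------
# Qualitative trait-level frequencies and reported Shannon-Wiener H'
# ---------------------------------------------------------------------------

#: Reported relative frequencies (per level code) of the scored qualitative
#: traits in the M2 panel, plus the reported Shannon-Wiener index of each row.
#: A few printed rows do not sum exactly to 1; they are kept as reported.
QUALITATIVE_FREQUENCIES: dict[str, dict] = {
    "hypocotyl color": {"freqs": {1: 0.9949, 2: 0.0051}, "h_prime": 0.03},
    "growth habit": {"freqs": {1: 0.7077, 2: 0.2923}, "h_prime": 0.60},
    "plant type": {"freqs": {1: 0.0359, 2: 0.3333, 3: 0.6308}, "h_prime": 0.78},
    "stem leaf pubescence": {
        "freqs": {1: 0.0718, 2: 0.1641, 3: 0.5949, 4: 0.1692}, "h_prime": 1.10},
    "leaf type": {
        "freqs": {1: 0.2308, 2: 0.4974, 3: 0.1795, 4: 0.0923}, "h_prime": 1.21},
    "leaf shape": {"freqs": {1: 0.7179, 2: 0.2821}, "h_prime": 0.59},
    "leaf attitude": {"freqs": {1: 0.2103, 2: 0.2718, 3: 0.5179}, "h_prime": 1.02},
    "leaf vein color": {"freqs": {1: 0.0051, 2: 0.9949}, "h_prime": 0.03},
    "leaf lobing depth": {
        "freqs": {1: 0.7949, 2: 0.1949, 3: 0.0103}, "h_prime": 0.55},
    "inflorescence type": {
        "freqs": {1: 0.0308, 2: 0.6974, 3: 0.2462, 4: 0.0256}, "h_prime": 0.80},
    "style length": {"freqs": {1: 0.7077, 2: 0.0410, 3: 0.0513}, "h_prime": 0.53},
    "pedicel abscission layer": {"freqs": {0: 0.0205, 1: 0.9795}, "h_prime": 0.10},
    "fruit ridging": {
        "freqs": {1: 0.1801, 2: 0.5346, 3: 0.1717, 4: 0.1136}, "h_prime": 1.19},
    "fruit apex shape": {
        "freqs": {1: 0.1717, 2: 0.3241, 3: 0.2687, 4: 0.1330, 5: 0.0997,
                  6: 0.0028}, "h_prime": 1.54},
    "fruit shoulder shape": {
        "freqs": {1: 0.0028, 2: 0.5180, 3: 0.4100, 4: 0.0693}, "h_prime": 0.91},
    "fruit shape": {
        "freqs": {0: 0.0637, 1: 0.0637, 2: 0.0720, 3: 0.4349, 4: 0.2548,
                  5: 0.0139, 6: 0.0942, 7: 0.0028}, "h_prime": 1.55},
}

# ---------------------------------------------------------------------------
# Quantitative trait descriptive statistics
# ---------------------------------------------------------------------------

_QUANT_COLUMNS = ["mean", "sd", "min", "max", "cv", "h_prime"]

#: Reported descriptive statistics of the 15 quantitative traits across the
#: 33 accessions: mean, standard deviation, min, max, coefficient of
#: variation (%), and Shannon-Wiener index of the 10-grade binned values.
QUANTITATIVE_SUMMARY = pd.DataFrame(
    [
        ["soluble protein (mg/g)", 2.21, 0.68, 0.57, 3.41, 30.93, 2.02],
        ["soluble sugar (mg/g)", 92.98, 26.80, 36.24, 147.98, 28.82, 1.92],
        ["vitamin C (mg/100g)", 31.42, 6.18, 17.56, 49.38, 19.66, 1.60],
        ["nitrate (mg/g)", 0.31, 0.06, 0.21, 0.42, 18.38, 2.02],
        ["organic acid (%)", 0.01, 0.00, 0.01, 0.01, 18.02, 1.93],
        ["plant height (cm)", 37.89, 10.31, 23.88, 76.00, 27.22, 1.71],
        ["stem diameter (mm)", 10.91, 3.48, 7.41, 28.36, 31.93, 1.25],
        ["internode length (mm)", 27.39, 9.95, 11.65, 63.06, 36.33, 1.82],
        ["leaf length (cm)", 21.00, 3.26, 14.94, 27.80, 15.51, 2.07],
        ["leaf width (cm)", 23.66, 5.47, 13.74, 38.75, 23.13, 1.93],
        ["fruit transverse diameter (mm)", 38.88, 3.32, 29.18, 45.78, 8.55, 1.65],
        ["fruit longitudinal diameter (mm)", 38.94, 3.29, 28.60, 45.88, 8.45, 1.90],
        ["leaf area (cm2)", 357.96, 133.33, 143.75, 754.08, 37.25, 1.94],
        ["yield per plant (kg)", 0.90, 0.22, 0.34, 1.40, 24.40, 1.96],
        ["yield (t/667m2)", 4.389, 1.073, 1.667, 6.804, 24.45, 1.97],
    ],
    columns=["trait"] + _QUANT_COLUMNS,
).set_index("trait")

#: Quantitative trait names in canonical (principal-component table) order.
QUANTITATIVE_TRAITS: list[str] = list(QUANTITATIVE_SUMMARY.index)

# ---------------------------------------------------------------------------
# Principal components of the trait correlation matrix
# ---------------------------------------------------------------------------

#: Reported unit-eigenvector loadings of the first six principal components
#: (rows = traits in QUANTITATIVE_TRAITS order, columns = PC1..PC6).
PCA_LOADINGS = pd.DataFrame(
    [
        [-0.0085, 0.0943, 0.1174, 0.8095, 0.0906, -0.1380],
        [-0.1351, 0.3200, 0.3838, 0.1635, 0.0884, 0.1600],
        [0.1438, 0.3502, 0.1660, -0.1132, -0.2844, -0.3028],
        [0.0969, 0.1986, -0.2670, -0.3223, 0.5981, 0.1765],
        [-0.0970, 0.3252, 0.2156, 0.1473, 0.3574, 0.4958],
        [0.3041, 0.0314, 0.3970, -0.0832, 0.1810, -0.1781],
        [0.2565, 0.1733, 0.4416, -0.2030, -0.0784, -0.1668],
        [0.1746, -0.2243, -0.2474, 0.3076, 0.3199, -0.3507],
        [0.3890, -0.2134, 0.1839, 0.0132, 0.0326, 0.0682],
        [0.3368, -0.3236, 0.1066, 0.0211, 0.1177, 0.2177],
        [0.0777, 0.2952, -0.1025, -0.0853, 0.4015, -0.5219],
        [0.2834, 0.3258, -0.2676, 0.1001, -0.1687, 0.1497],
        [0.3735, -0.2843, 0.1329, 0.0323, 0.0894, 0.1553],
        [0.3623, 0.2406, -0.2601, 0.0948, -0.1776, 0.1283],
        [0.3628, 0.2393, -0.2592, 0.0939, -0.1797, 0.1295],
    ],
    index=QUANTITATIVE_TRAITS,
    columns=[f"PC{k}" for k in range(1, 7)],
)

#: Reported eigenvalues of the retained components.
PCA_EIGENVALUES = [4.5959, 2.6975, 2.0800, 1.2784, 1.1997, 1.0405]

#: Reported per-component variance contributions (percent of total variance).
PCA_CONTRIBUTIONS = [30.6396, 17.9835, 13.8667, 8.5227, 7.9979, 6.9367]

#: Reported cumulative variance (percent) after each retained component.
PCA_CUMULATIVE = [30.6396, 48.6232, 62.4899, 71.0126, 79.0106, 85.9473]

# ---------------------------------------------------------------------------
# Component scores, composite score and ranking per accession
# ---------------------------------------------------------------------------

#: Reported component scores Y1..Y6, composite score Z and rank of the 33
#: accessions (index = accession id).
COMPONENT_SCORES = pd.DataFrame(
    [
        ["1", -4.1276, -3.1328, 0.9697, -0.9460, -0.2613, -0.7985, -2.153080588, 33],
        ["2", -0.5189, -0.1488, -0.1237, 0.0585, 0.5098, -0.8406, -0.250679506, 21],
        ["4", -3.5646, 2.4312, 0.1686, -0.5215, 0.2229, 0.2375, -0.746654022, 29],
        ["10", -0.6913, 1.5360, -0.7669, -1.0034, 0.2275, 0.8296, -0.060157100, 17],
        ["11", 0.1920, -1.2960, 1.0441, 0.0232, 0.4714, 0.8205, 0.078116564, 13],
        ["17", -1.3992, 0.1854, 2.4221, 1.0352, 1.8863, 1.4457, 0.325632936, 9],
        ["19", 1.4227, 1.9766, -1.9854, -0.8859, 0.4334, 0.4097, 0.585989260, 5],
        ["21", 1.6679, 0.0883, -1.6885, 2.2524, 0.6845, -2.3038, 0.441760608, 7],
        ["42", -1.3106, 2.7436, -0.7717, 0.2159, 0.4492, 1.2593, 0.147188246, 12],
        ["43", -1.7510, -2.1808, 0.4705, -0.9792, -0.2801, 0.0446, -1.124181177, 32],
        ["46", -1.1475, 1.8350, -0.5937, 1.6082, -1.9671, -0.9829, -0.223816498, 18],
        ["63", -1.3001, 1.1611, -1.1036, -2.3667, 0.5849, 0.1050, -0.570367436, 28],
        ["72", -0.4578, 0.0246, 0.1098, 0.4105, -0.6461, -1.1796, -0.254961555, 23],
        ["76", 3.8114, 4.0838, 4.7951, -1.9720, -1.3328, -1.0524, 2.582355156, 1],
        ["84", -0.6938, -0.8998, 1.2316, -0.7712, -0.1704, -0.9343, -0.404638508, 24],
        ["97", 4.7153, -2.2508, 1.5808, 0.5188, 1.9576, -0.5056, 1.657867015, 3],
        ["102", 3.0236, -1.0974, 0.2238, 1.3934, -1.7504, -1.0101, 0.778144450, 4],
        ["103", 1.1924, -0.9202, -2.2686, -0.6524, 1.6790, 0.3450, -0.014082201, 14],
        ["104", 0.7744, 0.3587, 0.4491, 0.9438, -0.0807, 0.8979, 0.582127412, 6],
        ["107", 0.3030, -0.7355, -0.3155, 0.4699, 0.5861, -0.4002, -0.027943760, 15],
        ["108", 0.1120, -0.0916, 0.9201, 0.5422, 1.0094, 0.8043, 0.381819711, 8],
        ["109", -2.4298, 0.5402, -0.9880, 0.4839, -1.0478, -1.1611, -1.055809554, 30],
        ["111", -1.0160, -0.3405, 0.4858, 0.7376, 0.2658, 0.2870, -0.234024271, 19],
        ["113", -0.6333, 1.5486, -1.8312, 0.0201, -0.8155, 0.2305, -0.252475452, 22],
        ["115", -2.4588, -1.5251, 0.9184, 0.4725, -0.6702, -0.7038, -1.119795192, 31],
        ["127", -2.2782, 0.7928, -0.0469, 0.6239, 0.7429, 0.5647, -0.477269899, 26],
        ["130", 3.2974, -0.9876, -3.1388, -1.7432, 0.0330, -0.5627, 0.247239802, 11],
        ["131", 1.8687, -2.4816, -0.2027, -2.8707, -0.9750, 0.1544, -0.248704195, 20],
        ["137", 4.4798, 1.7242, -0.6570, 1.1328, 0.2921, 0.9229, 2.065784387, 2],
        ["140", 1.2790, -2.3221, -0.3305, 0.9546, -3.3476, 3.2751, -0.035766054, 16],
        ["146", -1.4883, 0.8114, -0.3427, 0.0169, -0.4856, -0.3959, -0.491547832, 27],
        ["147", 0.1231, -0.5427, 1.2617, 0.3290, 0.9207, 0.6783, 0.306938125, 10],
        ["M82", -0.9959, -0.8883, 0.1040, 0.4688, 0.8738, -0.4805, -0.435099898, 25],
    ],
    columns=["accession_id", "Y1", "Y2", "Y3", "Y4", "Y5", "Y6", "z", "rank"],
).set_index("accession_id")

# ---------------------------------------------------------------------------
# Per-sample SNP substitution statistics
# ---------------------------------------------------------------------------

#: Reported per-sample SNP counts: total SNPs, transitions, transversions,
#: Ts/Tv ratio, heterozygous and homozygous (non-reference) site counts.
SNP_SAMPLE_STATS = pd.DataFrame(
    [
        ["a1", 34179, 21069, 13111, 1.61, 8660, 119407],
        ["a10", 32473, 19361, 13115, 1.48, 8203, 120260],
        ["a103", 32130, 19130, 13004, 1.47, 8190, 119811],
        ["a104", 30799, 18316, 12487, 1.47, 7569, 120600],
        ["a107", 31364, 18624, 12743, 1.46, 7810, 120189],
        ["a108", 31144, 18501, 12644, 1.46, 7314, 120623],
        ["a109", 37582, 23954, 13628, 1.76, 10039, 117627],
        ["a11", 31920, 18957, 12966, 1.46, 8501, 120158],
        ["a111", 38000, 24125, 13878, 1.74, 10877, 117446],
        ["a113", 31285, 18546, 12739, 1.46, 7968, 120293],
        ["a114", 31302, 18714, 12590, 1.49, 7625, 120634],
        ["a115", 34321, 21315, 13008, 1.64, 7972, 119332],
        ["a127", 34264, 20937, 13328, 1.57, 9381, 118944],
        ["a130", 36470, 22437, 14035, 1.60, 9414, 118639],
        ["a131", 35320, 22109, 13214, 1.67, 8676, 119527],
        ["a137", 33729, 20814, 12917, 1.61, 7776, 120175],
        ["a140", 31602, 18718, 12885, 1.45, 7662, 120094],
        ["a146", 39720, 24614, 15108, 1.63, 11963, 115902],
        ["a147", 33145, 19988, 13159, 1.52, 8643, 119604],
        ["a17", 31346, 18593, 12756, 1.46, 8399, 119834],
        ["a19", 32493, 19378, 13116, 1.48, 7732, 120468],
        ["a2", 31746, 18841, 12907, 1.46, 8999, 119381],
        ["a21", 39247, 25254, 13994, 1.80, 11357, 117239],
        ["a4", 31205, 18576, 12633, 1.47, 8458, 119604],
        ["a42", 37534, 23828, 13708, 1.74, 10546, 117464],
        ["a43", 30579, 18244, 12336, 1.48, 8229, 119869],
        ["a63", 31526, 18763, 12763, 1.47, 8065, 120127],
        ["a72", 33738, 20454, 13286, 1.54, 8948, 119420],
        ["a84", 32573, 19637, 12940, 1.52, 9789, 118435],
        ["a97", 32103, 19277, 12829, 1.50, 8039, 120136],
        ["a98", 34814, 20927, 13889, 1.51, 8538, 119693],
        ["m82", 31113, 18536, 12578, 1.47, 8436, 120126],
    ],
    columns=["sample", "snp_number", "transition", "transversion",
             "ts_tv", "het", "hom"],
).set_index("sample")

# ---------------------------------------------------------------------------
# Population SNP genome-region annotation tallies
# ---------------------------------------------------------------------------

#: Reported genome-region / coding-effect tallies of the population SNP set.
REGION_COUNTS: dict[str, int] = {
    "upstream": 119731,
    "exon:stopgain": 16447,
    "exon:stoploss": 2540,
    "exon:synonymous": 250068,
    "exon:nonsynonymous": 50309,
    "intronic": 2490078,
    "splicing": 63113,
    "intergenic": 42600902,
    "UTR5": 16020,
    "UTR3": 201073,
    "UTR5;UTR3": 708,
    "ncRNA": 0,
    "downstream": 2259742,
    "upstream/downstream": 7164,
}

#: Reported total number of SNP sites in the population annotation. The
#: printed per-category counts sum to a slightly different figure; percentage
#: computations on this table therefore use this stated denominator.
REGION_TOTAL_SITES = 46_070_107
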