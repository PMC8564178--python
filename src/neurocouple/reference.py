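"""Reference summary statistics of the emulated three-group WMH cohort.

These tables describe the cohort design the synthetic generator targets:
86 non-dementia adults with white-matter hyperintensities, split by total
Fazekas score into mild (1-2, n=32), moderate (3-4, n=24) and severe (5-6,
n=30) groups.  Counts are (yes, no) or (male, female) per group; continuous
variables are (mean, SD) per group in the order mild, moderate, severe.

They serve two purposes: as worked-example inputs for the demographics
tests (the chi-square / ANOVA statistics can be recomputed directly from
them), and as calibration targets for :mod:`neurocouple.synthetic`.
"""

from __future__ import annotations

import numpy as np

GROUP_ORDER = ("mild", "moderate", "severe")

GROUP_SIZES = {"mild": 32, "moderate": 24, "severe": 30}

#: groups x categories count tables (rows follow GROUP_ORDER)
CATEGORICAL_COUNTS: dict[str, np.ndarray] = {
    "gender_male_female": np.array([[16, 16], [13, 11], [18, 12]]),
    "hypertension_yes_no": np.array([[6, 26], [17, 7], [21, 9]]),
    "diabetes_yes_no": np.array([[3, 29], [4, 20], [8, 22]]),
    "smoking_yes_no": np.array([[5, 27], [7, 17], [10, 20]]),
    "drinking_yes_no": np.array([[8, 24], [3, 21], [3, 27]]),
}

#: per-group (mean, sd) for continuous variables
CONTINUOUS_SUMMARIES: dict[str, list[tuple[float, float]]] = {
    "age_years": [(63.69, 5.47), (64.33, 6.65), (66.43, 5.07)],
    "education_years": [(10.78, 3.13), (11.08, 3.69), (9.10, 3.89)],
    "gray_matter_volume_ml": [(614.96, 38.54), (615.65, 31.16), (626.83, 57.33)],
    "framewise_displacement": [(0.18, 0.16), (0.18, 0.10), (0.17, 0.08)],
    # domain z-scores (standardized across the whole cohort)
    "global_cognition_z": [(0.28, 0.69), (0.32, 0.79), (-0.56, 1.19)],
    "processing_speed_z": [(0.18, 0.88), (0.26, 0.89), (-0.39, 1.11)],
    "executive_function_z": [(0.33, 0.76), (0.20, 0.95), (-0.52, 1.08)],
    "episodic_memory_z": [(0.34, 0.88), (0.12, 1.00), (-0.46, 0.98)],
    "language_z": [(0.25, 0.85), (0.09, 1.12), (-0.33, 0.99)],
}

#: mean within-subject global CBF-FCS coupling per group (Pearson r across
#: gray-matter voxels) -- the generator's coupling targets
COUPLING_BY_GROUP = {"mild": 0.225, "moderate": 0.209, "severe": 0.156}

#: per-group prevalence of binary risk factors, derived from the count tables
RISK_PREVALENCES = {
    name.rsplit("_", 2)[0]: {
        g: counts[i, 0] / counts[i].sum() for i, g in enumerate(GROUP_ORDER)
    }
    for name, counts in CATEGORICAL_COUNTS.items()
    if name != "gender_male_female"
}

MALE_PREVALENCE = {
    g: CATEGORICAL_COUNTS["gender_male_female"][i, 0]
    / CATEGORICAL_COUNTS["gender_male_female"][i].sum()
    for i, g in enumerate(GROUP_ORDER)
}

#: raw cognitive test scores (mean, sd) per group the generator draws from.
#: mmse: global cognition (points); tmt_a / tmt_b: trail-making A/B times in
#: seconds (larger = worse); avlt_delay: delayed recall (words); vft: verbal
#: fluency (words).  Chosen so the severe group is worst in every domain and
#: between-group separations match the domain z-score summaries above.
COGNITION_RAW_PARAMS: dict[str, list[tuple[float, float]]] = {
    "mmse": [(28.2, 1.5), (28.3, 1.7), (26.5, 2.4)],
    "tmt_a": [(55.0, 18.0), (53.0, 19.0), (68.0, 25.0)],
    "tmt_b": [(125.0, 40.0), (130.0, 45.0), (165.0, 55.0)],
    "avlt_delay": [(6.5, 2.2), (6.0, 2.5), (4.8, 2.4)],
    "vft": [(16.5, 3.5), (16.0, 4.2), (14.5, 3.8)],
}

#: which raw test feeds which cognitive domain
DOMAIN_TESTS = {
    "global_cognition": "mmse",
    "processing_speed": "tmt_a",
    "executive_function": "tmt_b",
    "episodic_memory": "avlt_delay",
    "language": "vft",
}
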