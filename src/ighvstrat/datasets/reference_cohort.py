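"""Published summary counts of the 129-patient SLE stratification cohort.

The patient-level data behind the published stratification (ImmuNexUT
B-cell subsets) are available only on request, so this module carries the
cohort's *printed group-level counts*: how many patients in the high- and
low-usage groups (80 and 49 patients) showed each clinical feature. They
serve as inputs for recomputing the within-group percentages of the
published comparison tables and as reference points in the test suite.

Each entry maps a variable to ``{"HIGH": (k, n), "LOW": (k, n)}`` where k
is the affected count and n the non-missing within-group denominator
(most variables use the full group size; the autoantibody panel and C4
were missing for a few patients, hence the smaller n).
"""

GROUP_SIZES = {"HIGH": 80, "LOW": 49}

CATEGORICAL_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    # SLEDAI-2K descriptors
    "arthritis": {"HIGH": (22, 80), "LOW": (4, 49)},
    "urinary_casts": {"HIGH": (12, 80), "LOW": (0, 49)},
    "haematuria": {"HIGH": (17, 80), "LOW": (1, 49)},
    "proteinuria": {"HIGH": (17, 80), "LOW": (4, 49)},
    "pyuria": {"HIGH": (5, 80), "LOW": (0, 49)},
    "rash": {"HIGH": (23, 80), "LOW": (5, 49)},
    "alopecia": {"HIGH": (14, 80), "LOW": (6, 49)},
    "mucosal_ulcers": {"HIGH": (6, 80), "LOW": (1, 49)},
    "pleurisy": {"HIGH": (4, 80), "LOW": (0, 49)},
    "pericarditis": {"HIGH": (2, 80), "LOW": (0, 49)},
    "low_complement": {"HIGH": (49, 80), "LOW": (15, 49)},
    "increased_dna_binding": {"HIGH": (39, 80), "LOW": (11, 49)},
    "fever": {"HIGH": (15, 80), "LOW": (2, 49)},
    "thrombocytopenia": {"HIGH": (6, 80), "LOW": (1, 49)},
    "leukopenia": {"HIGH": (8, 80), "LOW": (3, 49)},
    # clinical-features table
    "male_sex": {"HIGH": (8, 80), "LOW": (2, 49)},
    "lupus_nephritis_history": {"HIGH": (50, 80), "LOW": (28, 49)},
    "anti_sm": {"HIGH": (23, 76), "LOW": (4, 48)},
    "tacrolimus": {"HIGH": (15, 80), "LOW": (11, 49)},
    "mmf": {"HIGH": (17, 80), "LOW": (11, 49)},
    "hcq": {"HIGH": (34, 80), "LOW": (24, 49)},
    "lldas": {"HIGH": (28, 80), "LOW": (34, 49)},
}

#: Published median IGHV4-34 usage per subset (percent of clonotypes),
#: for the two subsets the report quotes.
SUBSET_MEDIAN_USAGE_PCT = {"NAIVE": 7.4, "USM": 6.6}
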