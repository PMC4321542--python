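"""Published cotton-study library counts bundled as worked-example inputs.

Raw read counts from the published three-library cotton seedling
small-RNA categorization table (control / drought / salt; unique and
redundant reads per category and reference-match row) and a few
Results-prose counts.  These are inputs for the arithmetic worked
examples: every percentage and mean the package reports for them is
recomputed from these counts at run time.
"""

from __future__ import annotations

LIBRARIES = ("control", "drought", "salt")

#: total unique / redundant clean reads per library
TOTALS = {
    "control": {"unique": 5_725_308, "redundant": 16_109_390},
    "drought": {"unique": 7_650_789, "redundant": 18_808_997},
    "salt": {"unique": 6_377_678, "redundant": 16_938_676},
}

#: per-row counts: row -> library -> (unique, redundant)
CATEGORY_COUNTS = {
    "matched_est_gss": {
        "control": (246_723, 2_740_263),
        "drought": (279_212, 2_714_775),
        "salt": (248_892, 2_800_217),
    },
    "matched_genome": {
        "control": (1_775_856, 8_740_467),
        "drought": (2_314_399, 9_198_501),
        "salt": (1_965_288, 8_764_559),
    },
    "matched_any": {
        "control": (1_847_787, 9_229_827),
        "drought": (2_398_328, 9_719_543),
        "salt": (2_040_086, 9_281_862),
    },
    "miRNA": {
        "control": (29_145, 4_265_679),
        "drought": (31_229, 3_761_665),
        "salt": (31_343, 4_114_428),
    },
    "rRNA": {
        "control": (87_185, 1_230_970),
        "drought": (95_647, 1_117_486),
        "salt": (80_630, 1_038_386),
    },
    "snRNA": {
        "control": (1_250, 2_041),
        "drought": (1_532, 2_619),
        "salt": (1_353, 2_338),
    },
    "snoRNA": {
        "control": (486, 749),
        "drought": (611, 1_148),
        "salt": (530, 746),
    },
    "tRNA": {
        "control": (8_586, 182_011),
        "drought": (10_198, 201_042),
        "salt": (7_410, 151_590),
    },
    "unannotated": {
        "control": (5_598_655, 10_427_939),
        "drought": (7_511_572, 13_725_037),
        "salt": (6_256_412, 11_631_188),
    },
}

#: miRNAs detected with precursors, and how many were seen in all three
#: conditions (Results prose).
N_MIRNAS_TOTAL = 337
N_MIRNAS_SHARED_ALL = 292

#: known-miRNA families detected, families differential at p <= 0.05,
#: and families significant under the combined |log2 FC| >= 1 rule.
N_FAMILIES_TOTAL = 709
N_FAMILIES_P05 = 565
N_FAMILIES_SIG = 443


def counts(row: str, kind: str) -> list[int]:
    """Per-library counts for one table row; kind is unique|redundant."""
    k = 0 if kind == "unique" else 1
    return [CATEGORY_COUNTS[row][lib][k] for lib in LIBRARIES]


def totals(kind: str) -> list[int]:
    return [TOTALS[lib][kind] for lib in LIBRARIES]
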