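"""Published summary statistics of the reference cohort.

The full-scale study population behind this methodology — mental-health
users of a large integrated US health system, fiscal year 2024 — is not
publicly deposited.  What is public are its summary tables: the cost
distribution by age stratum and sex, the 24 mental-health diagnostic
category sizes, and the code-scope counts (889 ICD-10-CM codes across the
24 CCSR mental-health categories, 109 of which were excluded as not
directly mental-health-related, leaving 780 in scope).

These constants serve two purposes: they parameterise the synthetic
generator's emulation targets, and they let consistency arithmetic (stratum
counts summing to the cohort total, the female share, the retained-code
count) be recomputed from inputs rather than asserted.
"""

from __future__ import annotations

# (label, n_patients, mean cost $, median cost $, SD $)
AGE_STRATA: tuple[tuple[str, int, float, float, float], ...] = (
    ("age_lt35", 291_334, 6485.0, 2540.0, 18_630.0),
    ("age_35_44", 422_541, 7680.0, 2538.0, 22_998.0),
    ("age_45_54", 339_340, 7243.0, 2456.0, 21_866.0),
    ("age_55_64", 391_784, 8278.0, 2385.0, 25_605.0),
    ("age_65_74", 346_912, 7807.0, 2165.0, 24_809.0),
    ("age_ge75", 296_263, 4571.0, 1858.0, 13_648.0),
)

SEX_COUNTS: dict[str, int] = {"male": 1_721_171, "female": 367_003}

TOTAL_PATIENTS: int = 2_088_174
TOTAL_MEAN_COST: float = 7135.0
TOTAL_MEDIAN_COST: float = 2321.0
TOTAL_SD_COST: float = 22_050.0

N_MH_CATEGORIES: int = 24
N_MAPPED_CODES: int = 889
N_EXCLUDED_CODES: int = 109


def age_stratum_total() -> int:
    """Sum of the published age-stratum patient counts."""
    return sum(n for _, n, *_ in AGE_STRATA)


def female_share_percent() -> float:
    """Female share of the published cohort, in percent."""
    total = sum(SEX_COUNTS.values())
    return 100.0 * SEX_COUNTS["female"] / total


def retained_code_count() -> int:
    """Codes in scope after exclusions."""
    return N_MAPPED_CODES - N_EXCLUDED_CODES
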