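"""Published German ABO allele-group frequency estimates and known ambiguities.

Population-wide posterior-mean frequency estimates for 82 ABO alleles and
allele groups in the German population, obtained from a large-scale
exon 6/7 amplicon-sequencing survey, together with the published subgroup
and blood-group aggregates and the catalogue of phasing-ambiguity cases
observed in that population.  Identifiers ending in ``*`` are allele groups
collapsing alleles indistinguishable over exons 6 and 7.

Values are percentages as published (three decimals).  They serve as the
default frequency source for relative-likelihood scoring and as realistic
defaults for the synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass

# allele / allele-group level posterior means (percent)
GERMAN_GROUP_FREQUENCIES_PCT: dict[str, float] = {
    # A1
    "A1.01.01*": 20.286, "A1.01.02": 0.023, "A1.02.01": 0.101, "A1.02.03": 0.228,
    # A2
    "A2.01.01*": 6.588, "A2.02.01": 0.004, "A2.06.01": 0.204, "A2.12.01*": 0.043,
    "A2.17.01": 0.005, "A2.19.01": 0.012, "A2.20.01": 0.013,
    # A3
    "A3.02.01": 0.454, "A3.05.01": 0.004, "A3.07.01": 0.004,
    # Ael
    "Ael.01.01": 0.003, "Ael.03.01": 0.002, "Ael.05.01": 0.013, "Ael.06.01": 0.005,
    # Aw
    "Aw.01.01": 0.004, "Aw.04.01": 0.004, "Aw.05.01": 0.003, "Aw.06.01": 0.005,
    "Aw.07.01": 0.351, "Aw.10.01": 0.005, "Aw.11.01": 0.003, "Aw.19.01": 0.013,
    "Aw.25.01": 0.005,
    # Ax
    "Ax.01.01": 0.101, "Ax.01.02": 0.961, "Ax.02.01": 0.006, "Ax.02.02": 0.015,
    "Ax.12.01": 0.010, "Ax.13.01": 0.004, "Ax.14.01": 0.003,
    # B1
    "B1.01.01*": 8.420, "B1.01.02": 0.008, "B1.01.03": 0.007, "B1.01.05": 0.924,
    "B1.09.01": 0.010,
    # Ba
    "Ba.01.02": 0.035, "Ba.04.01": 0.044, "Ba.05.01": 0.010,
    # Bel
    "Bel.01.01": 0.010,
    # Bw
    "Bw.04.01": 0.010, "Bw.12.01": 0.010, "Bw.14.01": 0.057, "Bw.21.01": 0.010,
    "Bw.25.01": 0.017,
    # O1
    "O.01.01": 31.772, "O.01.04": 0.029, "O.01.05": 0.033, "O.01.06": 0.017,
    "O.01.07": 0.005, "O.01.08": 4.453, "O.01.09": 0.006, "O.01.10": 0.006,
    "O.01.11*": 0.014, "O.01.13": 0.246, "O.01.14": 0.033, "O.01.16": 0.004,
    # O2
    "O.02.01*": 18.479, "O.02.02*": 0.137, "O.02.04": 1.689, "O.02.05": 0.008,
    "O.02.06": 0.023, "O.02.07*": 0.008, "O.02.08": 0.011, "O.02.10": 0.004,
    "O.02.13": 0.091, "O.02.14": 0.008, "O.02.15*": 1.610, "O.02.16": 0.006,
    "O.02.19": 0.004,
    # O3 / O9 / rare O
    "O.03.01": 1.597,
    "O.09.01": 0.163, "O.09.02": 0.003, "O.09.03": 0.005,
    "O.48.01": 0.149, "O.49.01": 0.180, "O.50.01": 0.139, "O.52.01": 0.012,
    "O.53.01": 0.003,
}

# published subgroup-level posterior means (percent)
GERMAN_SUBGROUP_FREQUENCIES_PCT: dict[str, float] = {
    "A1": 20.638, "A2": 6.869, "A3": 0.462, "Ael": 0.023, "Aw": 0.391, "Ax": 1.099,
    "B1": 9.369, "Ba": 0.089, "Bel": 0.010, "Bw": 0.103,
    "O1": 36.619, "O2": 22.079, "O3": 1.597, "O9": 0.171,
    "O48": 0.149, "O49": 0.180, "O50": 0.139, "O52": 0.012, "O53": 0.003,
}

# published blood-group level posterior means (percent)
GERMAN_BLOOD_GROUP_FREQUENCIES_PCT: dict[str, float] = {
    "A": 29.482, "B": 9.570, "O": 60.948,
}


@dataclass(frozen=True)
class PublishedAmbiguity:
    """One published phasing-ambiguity case in the German population."""

    case: int
    pair_a: tuple[str, str]
    pair_b: tuple[str, str]
    published_relative_likelihood: float
    published_frequency_pct: float
    subgroup_relevant: bool


# the 24 phasing-ambiguity cases observed in the German survey, ordered by
# published case frequency (percent)
GERMAN_PHASING_AMBIGUITIES: tuple[PublishedAmbiguity, ...] = (
    PublishedAmbiguity(1, ("O.01.01", "O.02.01*"), ("O.01.11*", "O.02.02*"), 298326, 12.545, False),
    PublishedAmbiguity(2, ("A1.01.01*", "O.02.01*"), ("Ax.02.02", "O.02.02*"), 187949, 8.092, True),
    PublishedAmbiguity(3, ("A2.01.01*", "O.01.01"), ("A1.01.01*", "O.01.06"), 617, 4.511, True),
    PublishedAmbiguity(4, ("B1.01.01*", "O.02.01*"), ("Ax.02.01", "O.02.14"), 3313940, 3.250, True),
    PublishedAmbiguity(5, ("A1.01.01*", "A2.01.01*"), ("A1.02.01", "A2.06.01"), 6501, 2.868, False),
    PublishedAmbiguity(6, ("O.01.01", "O.02.15*"), ("O.01.14", "O.02.05"), 193859, 1.095, False),
    PublishedAmbiguity(7, ("O.01.01", "O.09.01"), ("O.01.05", "O.09.03"), 30220, 0.113, False),
    PublishedAmbiguity(8, ("A1.02.01", "O.01.01"), ("A1.01.01*", "O.01.05"), 5, 0.071, False),
    PublishedAmbiguity(9, ("A1.01.01*", "O.09.01"), ("A1.02.01", "O.09.03"), 6284, 0.068, False),
    PublishedAmbiguity(10, ("A2.01.01*", "O.01.05"), ("A1.02.01", "O.01.06"), 128, 0.027, True),
    PublishedAmbiguity(11, ("B1.01.01*", "O.02.02*"), ("A1.01.02", "O.02.14"), 6271, 0.026, True),
    PublishedAmbiguity(12, ("O.01.01", "O.02.06"), ("O.01.10", "O.02.02*"), 853, 0.016, False),
    PublishedAmbiguity(13, ("A1.01.02", "O.02.01*"), ("Ax.02.01", "O.02.02*"), 528, 0.010, True),
    PublishedAmbiguity(14, ("Ax.02.02", "O.01.01"), ("A1.01.01*", "O.01.11*"), 2, 0.007, True),
    PublishedAmbiguity(15, ("A1.02.01", "O.02.15*"), ("A2.20.01", "O.02.05"), 1515, 0.005, True),
    PublishedAmbiguity(16, ("O.01.10", "O.02.01*"), ("O.01.11*", "O.02.06"), 350, 0.003, False),
    PublishedAmbiguity(17, ("A1.01.01*", "Ax.02.01"), ("A1.01.02", "Ax.02.02"), 356, 0.002, False),
    PublishedAmbiguity(18, ("A1.01.01*", "Aw.25.01"), ("A1.02.01", "A3.02.01"), 2, 0.002, True),
    PublishedAmbiguity(19, ("A1.01.01*", "B1.01.02"), ("A1.01.02", "B1.01.05"), 8, 0.002, False),
    PublishedAmbiguity(20, ("Aw.25.01", "O.01.01"), ("A3.02.01", "O.01.05"), 10, 0.002, True),
    PublishedAmbiguity(21, ("A1.01.02", "A2.01.01*"), ("A1.02.03", "A2.06.01"), 3, 0.001, False),
    PublishedAmbiguity(22, ("A2.01.01*", "O.01.11*"), ("Ax.02.02", "O.01.06"), 389, 0.001, True),
    PublishedAmbiguity(23, ("A1.01.01*", "Aw.01.01"), ("A2.06.01", "A2.17.01"), 78, 0.001, True),
    PublishedAmbiguity(24, ("A2.01.01*", "O.09.03"), ("A2.06.01", "O.09.01"), 1, 0.001, False),
)


def german_theta() -> dict[str, float]:
    """Allele-group frequencies renormalized to a simplex (fractions)."""
    total = sum(GERMAN_GROUP_FREQUENCIES_PCT.values())
    return {k: v / total for k, v in GERMAN_GROUP_FREQUENCIES_PCT.items()}
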