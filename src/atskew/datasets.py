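"""Bundled reference datasets for desk-scale analyses.

The core dataset is the leading-strand singleton SNP spectrum from
ex-operonic intergenic sites of the Staphylococcus aureus ST239 clone
(TW20 reference chromosome, EMBL accession FN433596): 140 singleton SNPs
over the 12 substitution categories, together with the corresponding
published per-site mutation rates.  The site composition of the analyzed
class is recoverable from counts and rates via
:func:`atskew.equilibrium.infer_composition`, which makes the whole
equilibrium analysis reproducible without any genome download.
"""

from __future__ import annotations

import numpy as np

from .equilibrium import MutationCounts, infer_composition
from .genome import BASE_INDEX

#: Leading-strand ex-operonic singleton SNP counts for TW20 ("XY" = X -> Y).
TW20_LEADING_SINGLETON_PAIRS: dict[str, int] = {
    "AG": 31, "GA": 12, "CG": 0, "GC": 1, "GT": 22, "TA": 8,
    "TC": 21, "TG": 2, "AC": 3, "CA": 6, "AT": 11, "CT": 23,
}

#: Published per-site rates for the same spectrum ("XY" = X -> Y, per site X).
TW20_LEADING_RATE_PAIRS: dict[str, float] = {
    "AG": 6.59462e-04, "GA": 6.39046e-04, "CG": 0.0, "GC": 5.32538e-05,
    "GT": 1.17158e-03, "TA": 1.79965e-04, "TC": 4.72409e-04, "TG": 4.49913e-05,
    "AC": 6.38189e-05, "CA": 4.37222e-04, "AT": 2.34002e-04, "CT": 1.67602e-03,
}


def tw20_leading_singleton_counts() -> MutationCounts:
    """The 140-SNP leading-strand singleton spectrum as MutationCounts."""
    return MutationCounts.from_pairs(TW20_LEADING_SINGLETON_PAIRS)


def tw20_leading_rates() -> np.ndarray:
    """Published leading-strand per-site rates as a 4x4 (ACGT) matrix."""
    r = np.zeros((4, 4))
    for key, value in TW20_LEADING_RATE_PAIRS.items():
        r[BASE_INDEX[key[0]], BASE_INDEX[key[1]]] = value
    return r


def tw20_leading_composition() -> np.ndarray:
    """Ex-operonic leading-strand site counts N_i (ACGT), recovered at run
    time by inverting counts/rates (cross-checked across categories)."""
    return infer_composition(tw20_leading_singleton_counts(), tw20_leading_rates())


def tw20_leading_intergenic_freqs() -> np.ndarray:
    """Leading-strand ex-operonic base frequencies (ACGT), N_i / sum N."""
    N = tw20_leading_composition()
    return N / N.sum()


#: Genome-scale facts used in the false-positive expectation: ex-operonic
#: intergenic bases, chromosome length, and number of comparison genomes.
TW20_EX_OPERONIC_BASES = 125_042
TW20_CHROMOSOME_LENGTH = 3_043_210
TW20_N_GENOMES = 62
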