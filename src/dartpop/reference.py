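"""Published reference summaries of the 83-cultivar spring barley panel.

The package was written around a survey of 83 Polish spring barley
cultivars spanning 120 years of breeding, genotyped by DArTseq on
pooled 8-seedling samples (11,655 SNP loci after quality filtering).
The raw genotype deposit is not bundled; what is bundled here are the
published per-chromosome summary tables of that panel — chromosome
lengths on the Morex assembly, filtered locus counts, and SNP
substitution-type counts.  They serve two purposes:

* defaults for the synthetic-panel generator (chromosome geometry and
  realistic substitution-type proportions), and
* inputs for the self-consistency checks in ``scripts/acceptance.py``,
  which recompute derived quantities (Ts/Tv ratios, mean inter-locus
  spacing, genome-wide marker density) from these primary counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: the 12 ordered substitution classes; the first four are transitions
SNP_CHANGES: tuple[str, ...] = (
    "A>G", "G>A", "C>T", "T>C",          # transitions
    "A>C", "A>T", "G>C", "G>T",          # transversions (purine ref)
    "C>A", "C>G", "T>A", "T>G",          # transversions (pyrimidine ref)
)

TRANSITIONS: frozenset = frozenset(SNP_CHANGES[:4])

#: chromosome lengths (Mbp, Morex assembly) and filtered locus counts
CHROMOSOME_TABLE = pd.DataFrame(
    {
        "chromosome": ["1H", "2H", "3H", "4H", "5H", "6H", "7H", "Un"],
        "length_mbp": [558.54, 768.08, 699.71, 647.06, 670.03, 583.38,
                       657.22, np.nan],
        "n_loci": [1150, 1695, 1541, 1109, 1574, 1158, 1571, 1857],
    }
).set_index("chromosome")

#: SNP substitution-type counts per chromosome (rows = ordered change)
SNP_TYPE_COUNTS = pd.DataFrame(
    [
        # 1H   2H   3H   4H   5H   6H   7H   Un
        [186, 263, 235, 206, 278, 183, 245, 314],   # A>G
        [178, 254, 211, 168, 249, 193, 228, 271],   # G>A
        [184, 248, 252, 165, 240, 169, 243, 253],   # C>T
        [160, 222, 244, 145, 207, 151, 237, 238],   # T>C
        [33,   70,  75,  47,  70,  56,  70, 101],   # A>C
        [37,   44,  24,  34,  45,  33,  32,  43],   # A>T
        [101, 119, 107,  90, 116,  80, 125, 152],   # G>C
        [56,   95,  65,  45,  72,  52,  72,  68],   # G>T
        [45,   79,  67,  44,  72,  47,  91,  88],   # C>A
        [89,  170, 146,  86, 118, 103, 128, 187],   # C>G
        [28,   45,  39,  23,  48,  32,  36,  40],   # T>A
        [53,   86,  76,  56,  59,  59,  64, 102],   # T>G
    ],
    index=list(SNP_CHANGES),
    columns=["1H", "2H", "3H", "4H", "5H", "6H", "7H", "Un"],
)

#: genome-wide mean diversity statistics of the reference panel
PANEL_MEAN_UHO: float = 0.058
PANEL_MEAN_UHE: float = 0.197


def chromosome_lengths_bp() -> dict[str, int]:
    """Assembled chromosome lengths in bp (excludes unassigned)."""
    tab = CHROMOSOME_TABLE.dropna(subset=["length_mbp"])
    return {c: int(round(l * 1e6)) for c, l in tab["length_mbp"].items()}


def snp_change_probabilities() -> pd.Series:
    """Genome-wide relative frequency of each substitution class."""
    totals = SNP_TYPE_COUNTS.sum(axis=1)
    return totals / totals.sum()
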