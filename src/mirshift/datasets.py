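"""Bundled reference numbers from the RNase A / Lewis lung carcinoma profiling study.

Four pooled SOLiD small-RNA libraries were sequenced: tumour tissue of
saline-treated mice (L1), tumour tissue of RNase A-treated mice (L2),
serum of saline-treated mice (L3) and serum of RNase A-treated mice (L4).
This module carries the published per-library read-classification totals
and headline differential counts so that composition arithmetic and
overlap bookkeeping can be exercised without any download.
"""

from __future__ import annotations

import pandas as pd

LIBRARIES = ("L1", "L2", "L3", "L4")

#: Read-classification totals per library (reads mapped to hairpin miRNAs,
#: mRNAs, rRNAs, "filter" RNAs — tRNA/repeats/adapters — plus the mapped and
#: grand totals). "mapped" equals the sum of the four classes in every library.
LIBRARY_CLASS_COUNTS: pd.DataFrame = pd.DataFrame(
    {
        "miRNA": [965_017, 1_399_612, 835_664, 560_568],
        "mRNA": [31_407_252, 21_972_560, 20_476_883, 27_024_143],
        "rRNA": [9_348_471, 5_783_418, 2_623_843, 3_195_154],
        "filter": [6_511_041, 4_986_000, 8_200_681, 8_876_496],
        "mapped": [48_231_781, 34_141_590, 32_137_071, 39_656_361],
        "total": [71_675_921, 51_371_107, 42_561_316, 56_516_886],
    },
    index=list(LIBRARIES),
)

#: Headline per-compartment differential counts: direction -> number of
#: miRNAs whose level changed after ribonuclease treatment.
AFFECTED_COUNTS = {
    "tumour": {"up": 116, "down": 7},
    "serum": {"down": 137, "up": 2},
}

#: Detectable miRNA totals per compartment.
DETECTABLE_TOTALS = {"tumour": 615, "serum": 617}

#: Published overlap of the affected sets between compartments.
OVERLAP_COUNTS = {"common": 81, "tumour_only": 42, "serum_only": 58}

#: The nine candidates validated by stem-loop RT-qPCR.
VALIDATED_MIRNAS = (
    "mmu-miR-29b",
    "mmu-miR-21",
    "mmu-miR-10b",
    "mmu-miR-451a",
    "mmu-miR-17",
    "mmu-miR-18a",
    "mmu-miR-145",
    "mmu-miR-31",
    "mmu-let-7g",
)

#: Candidate reference genes screened for stability, and the pair retained
#: as having minimal M-value.
REFERENCE_GENE_CANDIDATES = ("gapdh", "ubc", "18S-rRNA", "rpl30", "hprt1", "ywhaz")
STABLE_REFERENCE_PAIR = ("hprt1", "rpl30")


def composition_fractions() -> pd.DataFrame:
    """Per-library class fractions of total reads, with an explicit
    ``unmapped`` remainder, for seeding simulated compositions.

    Rows sum to 1 exactly (unmapped is computed as the complement).
    """
    t = LIBRARY_CLASS_COUNTS
    frac = t[["miRNA", "mRNA", "rRNA", "filter"]].div(t["total"], axis=0)
    frac["unmapped"] = 1.0 - frac.sum(axis=1)
    return frac
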