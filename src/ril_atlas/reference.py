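"""Published *C. briggsae* cb4 map summary statistics.

These tables are inputs, not results: the per-chromosome cumulative map
lengths, marker counts, and recombination-domain geometry of the published
AF16/HK104 AI-RIL genetic map and cb4 assembly.  They serve two purposes:

* design arithmetic (e.g. the expected X-chromosome map length under the
  advanced-intercross design is 2/3 of the mean autosomal length);
* realistic defaults for the cross simulator, whose chromosomes mirror the
  cb4 domain organization.

Chromosome labels follow the assembly convention I..V plus X.
"""

from __future__ import annotations

import pandas as pd

CHROMOSOMES = ("I", "II", "III", "IV", "V", "X")
AUTOSOMES = ("I", "II", "III", "IV", "V")

#: Cumulative AI-RIL map length per linkage group (cM), all breakpoints
#: regarded as one meiosis.
CB4_MAP_LENGTH_CM = {
    "I": 171.7,
    "II": 164.5,
    "III": 148.6,
    "IV": 173.2,
    "V": 170.6,
    "X": 100.0,
}

#: Assembled sequence per chromosome (bp, gaps excluded).
CB4_SEQUENCE_BP = {
    "I": 15_451_279,
    "II": 16_622_654,
    "III": 14_574_751,
    "IV": 17_479_539,
    "V": 19_490_057,
    "X": 21_537_770,
}

#: SNP markers genotyped per chromosome (one further marker was mapped but
#: not used in the chromosome assemblies; 1,032 genotyped in total).
CB4_SNPS_PER_CHROMOSOME = {
    "I": 180,
    "II": 153,
    "III": 177,
    "IV": 213,
    "V": 177,
    "X": 131,
}

AIRIL_N_LINES = 167
AIRIL_N_MARKERS = 1032

#: Mean observed recombination breakpoints per line per chromosome.
BREAKPOINT_MEAN_PER_LINE = {
    "I": 1.63,
    "II": 1.57,
    "III": 1.44,
    "IV": 1.66,
    "V": 1.63,
    "X": 0.96,
}

# Recombination-domain geometry of the AI-RIL map: physical spans (Mbp) of
# the five domains per chromosome and the normalized genetic lengths (cM) of
# the three major domains (arms + center sum to 50 cM; tips carry 0 cM).
_DOMAIN_ROWS = [
    # chrom, tipA, armA, center, armB, tipB (Mbp), armA_cM, center_cM, armB_cM
    ("I", 0.37, 3.84, 6.68, 4.31, 0.24, 18.63, 7.06, 24.31),
    ("II", 0.09, 4.44, 7.11, 4.90, 0.09, 16.48, 9.61, 23.91),
    ("III", 0.36, 4.34, 6.11, 3.29, 0.49, 25.98, 8.89, 15.13),
    ("IV", 0.46, 5.27, 8.11, 3.31, 0.34, 18.10, 10.78, 21.12),
    ("V", 0.12, 6.05, 7.93, 5.11, 0.28, 15.38, 10.13, 24.49),
    ("X", 0.79, 7.70, 6.95, 5.93, 0.18, 19.57, 10.40, 20.03),
]

CB4_DOMAIN_GEOMETRY = pd.DataFrame(
    _DOMAIN_ROWS,
    columns=[
        "chromosome",
        "tipA_mbp",
        "armA_mbp",
        "center_mbp",
        "armB_mbp",
        "tipB_mbp",
        "armA_cm",
        "center_cm",
        "armB_cm",
    ],
)


def expected_x_map_length(autosome_lengths_cm=None) -> float:
    """Expected cumulative X map length under the AI-RIL design.

    The X is hemizygous in males during the outcrossing phase, so it spends
    two thirds of its transmissions in a recombining (XX) context relative
    to autosomes; the expected cumulative X map length is therefore 2/3 of
    the mean autosomal length.
    """
    if autosome_lengths_cm is None:
        autosome_lengths_cm = [CB4_MAP_LENGTH_CM[c] for c in AUTOSOMES]
    lengths = list(autosome_lengths_cm)
    return (2.0 / 3.0) * (sum(lengths) / len(lengths))
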