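"""Reference-genome constants for *Oryza sativa*.

Pseudomolecule lengths (bp) of the Os-Nipponbare-Reference-IRGSP-1.0
assembly, chromosomes 1-12; the total is 373,245,519 bp.  Used for
genome-fraction accounting when scan regions are reported against the rice
reference rather than a simulated genome.
"""

IRGSP_CHROM_LENGTHS: dict[str, int] = {
    "chr01": 43_270_923,
    "chr02": 35_937_250,
    "chr03": 36_413_819,
    "chr04": 35_502_694,
    "chr05": 29_958_434,
    "chr06": 31_248_787,
    "chr07": 29_697_621,
    "chr08": 28_443_022,
    "chr09": 23_012_720,
    "chr10": 23_207_287,
    "chr11": 29_021_106,
    "chr12": 27_531_856,
}

IRGSP_GENOME_BP: int = sum(IRGSP_CHROM_LENGTHS.values())
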