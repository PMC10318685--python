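"""Reference genome lengths.

GRCh37 autosome lengths are packaged as constants; a 22 x 10 Mb toy genome
is provided for simulation and tests where desk-scale runtimes matter.
"""

from __future__ import annotations

from .types import AUTOSOMES

# GRCh37 (hg19) autosome lengths in bp.
GRCH37_AUTOSOMES: dict[str, int] = {
    "1": 249250621,
    "2": 243199373,
    "3": 198022430,
    "4": 191154276,
    "5": 180915260,
    "6": 171115067,
    "7": 159138663,
    "8": 146364022,
    "9": 141213431,
    "10": 135534747,
    "11": 135006516,
    "12": 133851895,
    "13": 115169878,
    "14": 107349540,
    "15": 102531392,
    "16": 90354753,
    "17": 81195210,
    "18": 78077248,
    "19": 59128983,
    "20": 63025520,
    "21": 48129895,
    "22": 51304566,
}


def toy_genome(chrom_length: int = 10_000_000, n_chroms: int = 22) -> dict[str, int]:
    """Equal-length toy autosomes for simulation and tests."""
    return {c: chrom_length for c in AUTOSOMES[:n_chroms]}


def total_length(genome_lengths: dict[str, int]) -> int:
    return int(sum(genome_lengths.values()))
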