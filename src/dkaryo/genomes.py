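"""Bundled chromosome size tables.

Coordinates throughout the package are 0-based half-open on GRCh37/hg19
(autosomes + X + Y, no alternate contigs). Other builds are supported by
passing an explicit ``chrom_sizes`` mapping to :func:`dkaryo.genome_bins.build_bins`.
"""

from __future__ import annotations

#: GRCh37 / hg19 chromosome lengths in bp.
GRCH37_SIZES: dict[str, int] = {
    "1": 249_250_621,
    "2": 243_199_373,
    "3": 198_022_430,
    "4": 191_154_276,
    "5": 180_915_260,
    "6": 171_115_067,
    "7": 159_138_663,
    "8": 146_364_022,
    "9": 141_213_431,
    "10": 135_534_747,
    "11": 135_006_516,
    "12": 133_851_895,
    "13": 115_169_878,
    "14": 107_349_540,
    "15": 102_531_392,
    "16": 90_354_753,
    "17": 81_195_210,
    "18": 78_077_248,
    "19": 59_128_983,
    "20": 63_025_520,
    "21": 48_129_895,
    "22": 51_304_566,
    "X": 155_270_560,
    "Y": 59_373_566,
}

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
SEX_CHROMS: tuple[str, ...] = ("X", "Y")


def is_autosome(chrom: str) -> bool:
    return chrom in AUTOSOMES


def sort_key(chrom: str):
    """Karyotype ordering: 1..22, X, Y, then anything else lexicographically."""
    order = {c: i for i, c in enumerate(AUTOSOMES + SEX_CHROMS)}
    return (0, order[chrom]) if chrom in order else (1, chrom)
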