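"""Reference-genome constants.

Chromosome lengths are GRCh37/hg19, the build the panel's recurrent-CNV
coordinates are expressed in.
"""

from __future__ import annotations

# GRCh37 chromosome lengths in bp, in canonical order.
GRCH37_CHROM_LENGTHS: dict[str, int] = {
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

CHROMOSOMES: tuple[str, ...] = tuple(GRCH37_CHROM_LENGTHS)
AUTOSOMES: tuple[str, ...] = CHROMOSOMES[:22]

_CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}


def chrom_sort_key(chrom: str) -> int:
    """Canonical ordering 1..22, X, Y. Raises KeyError on unknown names."""
    return _CHROM_ORDER[normalize_chrom(chrom)]


def normalize_chrom(chrom: str) -> str:
    """Strip a 'chr' prefix and validate against the 24 canonical chromosomes."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c not in GRCH37_CHROM_LENGTHS:
        raise ValueError(f"unknown chromosome: {chrom!r}")
    return c


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) not in ("X", "Y")
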