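"""Built-in GRCh37 chromosome geometry.

Chromosome lengths and approximate centromere midpoints (cytoband-derived)
for chromosomes 1-22 and X. Y is excluded throughout: it carries no
informative heterozygous SNPs in a trio analysis and is skipped by
convention in autosomal statistics.
"""

from __future__ import annotations

CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X",)
AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23))

#: GRCh37 chromosome lengths in base pairs.
CHROM_LENGTHS: dict[str, int] = {
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
}

#: Centromere midpoint coordinates (GRCh37 cytoband midpoints), base pairs.
CENTROMERES: dict[str, int] = {
    "1": 125_000_000,
    "2": 93_300_000,
    "3": 91_000_000,
    "4": 50_400_000,
    "5": 48_400_000,
    "6": 61_000_000,
    "7": 59_900_000,
    "8": 45_600_000,
    "9": 49_000_000,
    "10": 40_200_000,
    "11": 53_700_000,
    "12": 35_800_000,
    "13": 17_900_000,
    "14": 17_600_000,
    "15": 19_000_000,
    "16": 36_600_000,
    "17": 24_000_000,
    "18": 17_200_000,
    "19": 26_500_000,
    "20": 27_500_000,
    "21": 13_200_000,
    "22": 14_700_000,
    "X": 60_600_000,
}


def normalize_chrom(label: str) -> str:
    """Strip an optional ``chr`` prefix and validate the label."""
    lab = str(label).strip()
    if lab.lower().startswith("chr"):
        lab = lab[3:]
    if lab not in CHROM_LENGTHS:
        raise ValueError(f"unsupported chromosome label: {label!r}")
    return lab


def load_centromeres_bed(path) -> dict[str, int]:
    """Read centromere midpoints from a BED file (chrom, start, end).

    Returns a mapping usable in place of :data:`CENTROMERES`.
    """
    table: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            chrom = normalize_chrom(chrom)
            table[chrom] = (int(start) + int(end)) // 2
    if not table:
        raise ValueError(f"no centromere records found in {path}")
    return table
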