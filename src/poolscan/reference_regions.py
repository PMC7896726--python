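"""Published region coordinates from the landlocked-vs-anadromous salmon scan.

Two reference tables from the pooled whole-genome comparison of landlocked
and anadromous Atlantic salmon populations, kept here as validation
fixtures for the interval machinery:

* ``SWEEP_REGIONS`` — the 28 selective sweeps called from windows holding
  >= 10 SNPs with dAF >= 0.6 (coordinates as printed; the shortest possible
  sweep under the scan's geometry is 200 kb).
* ``LOW_HET_ANADROMOUS_REGIONS`` — the 16 regions with consistently reduced
  normalized heterozygosity in anadromous populations confirmed in an
  independent SNP-array dataset, with their overlapping gene symbols
  (34 gene entries in total; unnamed genes appear as ``"unknown"``).

In both tables the printed region length equals ``end - start``.
"""

from __future__ import annotations

from .sync_io import Region

#: (chromosome, start, end, printed length in bp)
SWEEP_REGIONS: list[tuple[str, int, int, int]] = [
    ("1", 50_450_000, 50_700_000, 250_000),
    ("1", 81_550_000, 81_800_000, 250_000),
    ("3", 54_000_000, 54_250_000, 250_000),
    ("4", 51_750_000, 51_950_000, 200_000),
    ("4", 52_450_000, 52_850_000, 400_000),
    ("4", 63_300_000, 63_500_000, 200_000),
    ("5", 8_550_000, 8_800_000, 250_000),
    ("5", 41_350_000, 41_600_000, 250_000),
    ("6", 72_050_000, 72_300_000, 250_000),
    ("9", 18_500_000, 18_800_000, 300_000),
    ("9", 62_150_000, 62_400_000, 250_000),
    ("10", 66_100_000, 66_300_000, 200_000),
    ("10", 71_250_000, 71_450_000, 200_000),
    ("11", 700_000, 900_000, 200_000),
    ("11", 48_450_000, 48_850_000, 400_000),
    ("13", 65_950_000, 66_200_000, 250_000),
    ("15", 34_950_000, 35_200_000, 250_000),
    ("15", 41_000_000, 41_350_000, 350_000),
    ("18", 49_600_000, 50_100_000, 500_000),
    ("20", 75_350_000, 75_600_000, 250_000),
    ("21", 18_050_000, 18_300_000, 250_000),
    ("23", 9_950_000, 10_200_000, 250_000),
    ("24", 17_450_000, 17_800_000, 350_000),
    ("24", 18_400_000, 18_650_000, 250_000),
    ("24", 40_000_000, 40_250_000, 250_000),
    ("25", 37_700_000, 37_950_000, 250_000),
    ("28", 21_050_000, 21_300_000, 250_000),
    ("29", 29_250_000, 29_650_000, 400_000),
]

#: (chromosome, start, end, printed length in bp, overlapping gene symbols)
LOW_HET_ANADROMOUS_REGIONS: list[tuple[str, int, int, int, tuple[str, ...]]] = [
    ("2", 10_526_090, 10_576_406, 50_316, ("clcn1",)),
    ("2", 26_241_445, 26_298_376, 56_931, ("etv1", "dgkb")),
    ("2", 32_506_524, 32_558_150, 51_626, ("unknown", "macf1", "rft2")),
    ("3", 61_880_141, 61_931_499, 51_358, ()),
    ("4", 11_625_820, 11_676_588, 50_768, ("spcs3", "wdr17", "asb5")),
    ("5", 47_905_828, 47_964_764, 58_936, ("eif3e", "rspo2")),
    ("7", 44_096_893, 44_148_649, 51_756, ("ppfia2",)),
    ("8", 11_124_829, 11_176_404, 51_575, ("asb5", "spcs3", "wdr17")),
    ("8", 12_454_313, 12_553_935, 99_622, ()),
    ("8", 16_940_959, 17_026_461, 85_502,
     ("unknown", "g3bp2", "ppm1k", "uso1", "pkd2", "abcg2")),
    ("11", 13_759_622, 13_812_520, 52_898, ("cadn",)),
    ("11", 17_877_623, 17_927_732, 50_109, ("sbf2",)),
    ("14", 25_660_660, 25_712_400, 51_740, ("tgfbr1",)),
    ("17", 44_490_402, 44_541_187, 50_785, ("spic", "bcl2l13", "mybpc3")),
    ("17", 44_642_974, 44_693_695, 50_721, ("mch2", "igf1", "parpbp")),
    ("27", 161_241, 236_092, 74_851, ("psmd4", "unknown", "pip5k1a", "znf687")),
]


def sweep_region_list() -> list[Region]:
    """The published sweeps as Region objects (printed coordinates taken as
    half-open, consistent with length = end - start)."""
    return [Region(c, s, e, "sweep") for c, s, e, _ in SWEEP_REGIONS]


def low_het_region_list() -> list[Region]:
    return [Region(c, s, e, "low_in_A") for c, s, e, _, _ in LOW_HET_ANADROMOUS_REGIONS]
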