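"""Curated recurrent-CNV loci used by the default panel and knowledge base.

Coordinates are approximate GRCh37/hg19 spans of well-known microdeletion/
microduplication syndrome regions. They are a synthetic curation bundled for
simulation and testing — not an export of DGV, ISCA, DECIPHER or ClinGen.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SyndromeLocus:
    region_id: str
    chrom: str
    start: int
    end: int
    effect: str  # "DEL", "DUP" or "both"
    syndrome_name: str


#: Recurrent syndrome regions placed as core regions of the default panel.
SYNDROME_LOCI: tuple[SyndromeLocus, ...] = (
    SyndromeLocus("22q11_del", "22", 18_900_000, 21_500_000, "DEL", "22q11 deletion syndrome"),
    SyndromeLocus("22q11_dup", "22", 18_900_000, 21_500_000, "DUP", "22q11 duplication syndrome"),
    SyndromeLocus("wbs", "7", 72_700_000, 74_100_000, "DEL", "Williams-Beuren syndrome"),
    SyndromeLocus("7q11_dup", "7", 72_700_000, 74_100_000, "DUP", "7q11.23 duplication syndrome"),
    SyndromeLocus("16p13_11", "16", 15_500_000, 16_300_000, "both", "16p13.11 microdeletion/duplication syndrome"),
    SyndromeLocus("15q11_2", "15", 22_800_000, 23_100_000, "DEL", "15q11.2 microdeletion syndrome"),
    SyndromeLocus("1q21_tar", "1", 145_400_000, 145_900_000, "DEL", "1q21.1 TAR susceptibility locus"),
    SyndromeLocus("1q21_dup", "1", 146_500_000, 147_800_000, "DUP", "1q21.1 microduplication"),
    SyndromeLocus("cmt1a", "17", 14_100_000, 15_400_000, "DUP", "Charcot-Marie-Tooth syndrome type 1A"),
    SyndromeLocus("hnpp", "17", 14_100_000, 15_400_000, "DEL", "Hereditary neuropathy with liability to pressure palsies"),
    SyndromeLocus("22q11_distal", "22", 21_900_000, 23_700_000, "DEL", "22q11.2 distal deletion syndrome"),
    SyndromeLocus("3q29", "3", 195_700_000, 197_300_000, "DEL", "3q29 microdeletion syndrome"),
    SyndromeLocus("2p21", "2", 44_400_000, 45_000_000, "DEL", "2p21 microdeletion syndrome"),
    SyndromeLocus("miller_dieker", "17", 100_000, 2_500_000, "DEL", "Miller-Dieker syndrome"),
    SyndromeLocus("15q13_3", "15", 30_900_000, 32_400_000, "DEL", "15q13.3 microdeletion syndrome"),
    SyndromeLocus("15q24", "15", 72_900_000, 75_500_000, "DEL", "15q24 microdeletion syndrome"),
    SyndromeLocus("16p12_1", "16", 21_900_000, 22_400_000, "DEL", "16p12.1 microdeletion syndrome"),
    SyndromeLocus("rcad", "17", 34_800_000, 36_200_000, "DEL", "Renal cysts and diabetes syndrome"),
    SyndromeLocus("leri_weill", "X", 500_000, 800_000, "DEL", "Leri-Weill dyschondrosteosis"),
    SyndromeLocus("cri_du_chat", "5", 100_000, 11_700_000, "DEL", "Cri du Chat syndrome"),
    SyndromeLocus("8p23_1", "8", 8_100_000, 11_800_000, "DEL", "8p23.1 microdeletion syndrome"),
)


@dataclass(frozen=True)
class BenchmarkLocus:
    """A non-syndromic core region exercising one classification tier."""

    region_id: str
    chrom: str
    start: int
    end: int
    tier: str  # tier its canonical event lands in, for simulation truth


#: Extra core regions whose knowledge-base annotations span the benign /
#: likely-benign / likely-pathogenic / VUS tiers.
BENCHMARK_LOCI: tuple[BenchmarkLocus, ...] = (
    # common polymorphic duplication, population frequency >1% -> benign
    BenchmarkLocus("benign_common", "14", 105_000_000, 106_000_000, "benign"),
    # rare CNV in a gene desert (<1% frequency, no genes) -> benign
    BenchmarkLocus("benign_nogene", "4", 60_000_000, 60_500_000, "benign"),
    # alpha-globin locus: gene-containing, recurrent, <1% -> likely benign
    BenchmarkLocus("hba_region", "16", 200_000, 260_000, "likely_benign"),
    # NPHP1 2q13 duplication: gene-containing, recurrent, <1% -> likely benign
    BenchmarkLocus("nphp1", "2", 110_800_000, 110_980_000, "likely_benign"),
    # partially overlaps the 8p23.1 syndrome interval -> likely pathogenic
    BenchmarkLocus("lp_partial_8p23", "8", 10_000_000, 14_000_000, "likely_pathogenic"),
    # contains a gene with suspected (unconfirmed) dosage sensitivity -> LP
    BenchmarkLocus("lp_dosage_gene", "6", 50_000_000, 50_700_000, "likely_pathogenic"),
    # absent from every knowledge-base table -> VUS fall-through
    BenchmarkLocus("vus_novel", "11", 90_000_000, 90_800_000, "vus"),
)

#: region_ids whose canonical events classify as potentially pathogenic.
PPCNV_REGION_IDS: frozenset[str] = frozenset(
    [l.region_id for l in SYNDROME_LOCI]
    + [l.region_id for l in BENCHMARK_LOCI if l.tier == "likely_pathogenic"]
)
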