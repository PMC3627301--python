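"""Reference tables for the zebrafish analyses and worked examples.

Holds an assembly-scale chromosome-length table for the 25 zebrafish
chromosomes and the published per-population summary statistics used in
the worked examples (mtDNA diversity and SNP heterozygosity for 13 wild
populations and three laboratory strains, and the among-clade divergence
triplet).  The chromosome lengths are representative values: they follow
the zebrafish assembly in overall scale and, under the package's 20 Mb
tiling rule (bins tiled from position 1 per chromosome, partial terminal
bin kept), yield the canonical 76 genome bins.
"""

from __future__ import annotations

# 25 chromosomes, lengths in bp.  ceil(L / 20 Mb) summed over chromosomes
# gives 76 bins.
ZEBRAFISH_CHROM_LENGTHS: dict[str, int] = {
    "chr01": 59_600_000,
    "chr02": 59_300_000,
    "chr03": 59_900_000,
    "chr04": 59_500_000,
    "chr05": 75_682_077,
    "chr06": 59_938_731,
    "chr07": 77_276_063,
    "chr08": 56_184_765,
    "chr09": 58_232_459,
    "chr10": 46_591_166,
    "chr11": 46_661_319,
    "chr12": 50_697_278,
    "chr13": 54_093_808,
    "chr14": 53_733_891,
    "chr15": 47_442_429,
    "chr16": 58_780_683,
    "chr17": 53_984_731,
    "chr18": 49_877_488,
    "chr19": 50_254_551,
    "chr20": 55_952_140,
    "chr21": 44_544_065,
    "chr22": 42_261_000,
    "chr23": 46_386_876,
    "chr24": 43_947_580,
    "chr25": 38_499_472,
}

# Mean unbiased expected heterozygosity (H_S) over SNP loci, per population
# or laboratory strain.
SNP_HS_WILD: dict[str, float] = {
    "PAR": 0.154,
    "KHA": 0.060,
    "BER": 0.223,
    "DHO": 0.226,
    "JOR": 0.224,
    "PGM": 0.253,
    "PNS": 0.272,
    "UTR": 0.219,
    "RCH": 0.215,
    "CHT": 0.068,
}
SNP_HS_LAB: dict[str, float] = {
    "AB": 0.142,
    "SJA": 0.027,
    "TM1": 0.235,
}

# mtDNA (cytochrome-b) haplotype diversity h and nucleotide diversity pi
# (percent), per population/strain with a reported value.
MTDNA_H: dict[str, float] = {
    "PAR": 0.87, "KHA": 0.92, "BER": 0.90, "SHK": 0.89, "JOR": 0.64,
    "PGM": 0.92, "PNS": 0.83, "UTR": 0.90, "RCH": 0.89, "CHT": 0.57,
    "AB": 0.0, "SJA": 0.0, "TM1": 0.0,
}
MTDNA_PI_PCT: dict[str, float] = {
    "PAR": 0.88, "KHA": 0.24, "BER": 0.40, "SHK": 0.53, "JOR": 0.26,
    "PGM": 0.55, "PNS": 0.55, "UTR": 0.62, "RCH": 1.30, "CHT": 0.49,
    "AB": 0.0, "SJA": 0.0, "TM1": 0.0,
}

# Mean pairwise nucleotide divergence (percent) among the three mtDNA
# clades (1-2, 1-3, 2-3).
CLADE_DIVERGENCE_PCT: tuple[float, float, float] = (5.4, 5.6, 6.3)

# Genome-wide outlier bookkeeping for the wild-population analysis:
# significant high/low F_ST outliers among the retained SNPs.
N_SNPS_TOTAL = 1832
N_OUTLIERS_HIGH = 62
N_OUTLIERS_LOW = 9

# Hardy-Weinberg testing: total (population, polymorphic locus) tests.
N_HWE_TESTS = 11_593

# Logarithmic LD-decay fit for the AB laboratory strain,
# mean r^2 = a * ln(distance Mb) + b.
AB_LD_FIT_A = -0.065
AB_LD_FIT_B = 0.306

# Hierarchical grouping of the wild populations used for the outlier
# analysis (five groups; the two small southern-India samples excluded).
WILD_POPULATION_GROUPS: dict[str, str] = {
    "PAR": "G1",
    "KHA": "G2",
    "CHT": "G3",
    "BER": "G4",
    "DHO": "G4",
    "JOR": "G4",
    "PGM": "G4",
    "RCH": "G4",
    "PNS": "G5",
    "UTR": "G5",
}
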