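"""Published reference values used as inputs and simulation templates.

These small tables come from the original three-breed study of harness-racing
selection signatures: per-breed allele frequencies for the five top-scan SNPs,
the 7-SNP haplotype block around the focal chromosome-22 marker, the
multi-breed allele-frequency survey for that marker, and the genome-wide mean
Fst levels between the three breeds.  They serve as worked-example inputs and
as calibration truths for the synthetic-data generator.
"""

from __future__ import annotations

BREED_CT = "coldblooded_trotter"
BREED_NSD = "north_swedish_draught"
BREED_SB = "standardbred"
BREEDS = (BREED_CT, BREED_NSD, BREED_SB)

#: The five top-scan SNPs: id, chromosome, position, (allele, other allele),
#: and the first allele's frequency in each of the three breeds
#: (Coldblooded trotter, North-Swedish draught horse, Standardbred).
CANDIDATE_SNPS = [
    {
        "marker_id": "22_45748491", "chromosome": "22", "position_bp": 45748491,
        "allele": "T", "other": "C",
        "freqs": {BREED_CT: 0.80, BREED_NSD: 0.15, BREED_SB: 0.75},
    },
    {
        "marker_id": "7_67498458", "chromosome": "7", "position_bp": 67498458,
        "allele": "T", "other": "C",
        "freqs": {BREED_CT: 0.06, BREED_NSD: 0.74, BREED_SB: 0.25},
    },
    {
        "marker_id": "10_49931991", "chromosome": "10", "position_bp": 49931991,
        "allele": "G", "other": "A",
        "freqs": {BREED_CT: 0.22, BREED_NSD: 0.90, BREED_SB: 0.25},
    },
    {
        "marker_id": "15_88565665", "chromosome": "15", "position_bp": 88565665,
        "allele": "C", "other": "T",
        "freqs": {BREED_CT: 0.95, BREED_NSD: 0.36, BREED_SB: 0.91},
    },
    {
        "marker_id": "11_2517091", "chromosome": "11", "position_bp": 2517091,
        "allele": "T", "other": "G",
        "freqs": {BREED_CT: 0.91, BREED_NSD: 0.34, BREED_SB: 0.75},
    },
]

#: Genome-wide mean Wright Fst between the breed pairs (37k-SNP arrays).
GENOME_FST_TARGETS = {
    (BREED_CT, BREED_SB): 0.082,
    (BREED_CT, BREED_NSD): 0.041,
    (BREED_NSD, BREED_SB): 0.088,
}

#: 7-SNP chromosome-22 haplotype block around the focal marker (third SNP).
LD_BLOCK_CHROMOSOME = "22"
LD_BLOCK_POSITIONS = [
    45732929, 45748082, 45748491, 45748586, 45749526, 45749595, 45752522,
]
LD_BLOCK_FOCAL_INDEX = 2  # 22:45,748,491, the associated SNP
LD_BLOCK_HAPLOTYPES = ["TGTAAAG", "GGTAAAA", "TTCGGGA", "GTCGGGG"]
LD_BLOCK_FREQUENCIES = [0.34, 0.33, 0.19, 0.12]

#: Multi-breed survey of the focal SNP's T-allele frequency: breed, n, f(T).
BREED_SURVEY = [
    ("Arabian Thoroughbred", 91, 1.00),
    ("Thoroughbred", 91, 0.99),
    ("Shire horse", 30, 0.98),
    ("Swedish Warmblood", 77, 0.96),
    ("Quarter horse", 40, 0.93),
    ("American Curly", 87, 0.91),
    ("Standardbred", 250, 0.86),
    ("Coldblooded trotter", 183, 0.70),
    ("American Miniature", 14, 0.61),
    ("Finnhorse", 157, 0.61),
    ("Shetland- and minishetland", 104, 0.42),
    ("Icelandic horse", 167, 0.26),
    ("Ardennes", 47, 0.20),
    ("Gotlandsruss", 153, 0.19),
    ("North-Swedish draught horse", 53, 0.10),
    ("Exmoor", 271, 0.02),
    ("Fjordhorse", 50, 0.01),
    ("Haflinger", 50, 0.01),
]

#: Study sample sizes for the three-breed scan.
SCAN_SAMPLE_SIZES = {BREED_CT: 11, BREED_NSD: 19, BREED_SB: 12}
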