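"""Worked-example inputs: published summary tables of an infant-gut
metagenome survey of bifidobacterial strains.

These small tables (cohort sample counts by SRA bioproject and country,
genome-database composition per species, and per-strain transcriptome
fold-change bin counts) exercise the collection-summary arithmetic, the
database bookkeeping and the up/down response ratio on real published
numbers without requiring any sequence download.
"""

from __future__ import annotations

# SRA sample counts per bioproject cohort of the infant gut metagenome
# collection, with the percentage column as printed in the source survey
# (printed precision varies: one row is given at a single decimal).
BIOPROJECT_SAMPLE_COUNTS: list[tuple[str, int, float]] = [
    ("PRJEB12669", 14, 0.84),
    ("PRJEB24771", 233, 14.00),
    ("PRJEB32135", 65, 3.91),
    ("PRJEB6456", 199, 11.96),
    ("PRJNA287207", 2, 0.12),
    ("PRJNA290380", 394, 23.68),
    ("PRJNA322188", 32, 1.92),
    ("PRJNA339914", 5, 0.30),
    ("PRJNA345144", 125, 7.51),
    ("PRJNA352475", 14, 0.84),
    ("PRJNA422569", 3, 0.18),
    ("PRJNA473126", 56, 3.37),
    ("PRJNA475246", 60, 3.61),
    ("PRJNA524703", 306, 18.39),
    ("PRJNA542703", 14, 0.8),
    ("PRJNA549787", 56, 3.37),
    ("PRJNA557731", 86, 5.17),
]

# the same 1664 samples grouped by country of origin
COUNTRY_SAMPLE_COUNTS: list[tuple[str, int, float]] = [
    ("Europe", 593, 35.64),
    ("USA", 554, 33.29),
    ("Malawian", 233, 14.00),
    ("New Zealand", 125, 7.51),
    ("Canada", 65, 3.91),
    ("South Africa", 56, 3.37),
    ("Italy", 24, 1.44),
    ("China", 14, 0.84),
]

# metagenome-assembled genomes reconstructed per bifidobacterial species
MAG_COUNTS_PER_SPECIES: dict[str, int] = {
    "B. longum": 105,
    "B. bifidum": 47,
    "B. breve": 30,
    "B. pseudocatenulatum": 19,
    "B. dentium": 16,
    "B. adolescentis": 13,
    "B. catenulatum": 9,
}

# the species-specific databases combine the MAGs with publicly available
# genomes and locally isolated, newly sequenced strains
N_PUBLIC_GENOMES = 965
N_LOCAL_ISOLATES = 93

# strains retained per species after the >0.1% collection-prevalence filter
RETAINED_STRAINS_PER_SPECIES: dict[str, int] = {
    "B. longum": 209,
    "B. bifidum": 76,
    "B. breve": 70,
    "B. adolescentis": 48,
    "B. pseudocatenulatum": 47,
    "B. dentium": 21,
    "B. catenulatum": 19,
}

# transcriptome fold-change bin counts (cells on a human cell monolayer vs
# liquid-medium control) per tested strain: (>3, >5, <0.25, <=0.5) gene
# counts, the printed up/down ratio n(>5)/n(<0.25), and the strain label
# (Best = designated local reference, TS = type strain, Worst = most
# dissimilar local strain)
RESPONSE_BIN_COUNTS: list[tuple[str, int, int, int, int, float, str]] = [
    ("PRL2010", 207, 77, 8, 79, 9.6250, "Best"),
    ("39B", 732, 421, 66, 183, 6.3788, "Best"),
    ("1895B", 26, 11, 174, 420, 0.0632, "Best"),
    ("1896B", 91, 49, 58, 303, 0.8448, "Best"),
    ("31L", 179, 40, 92, 265, 0.4348, "Worst"),
    ("209B", 52, 11, 185, 591, 0.0595, "Worst"),
    ("LMG11041", 159, 48, 46, 178, 1.0435, "TS"),
    ("1052B", 80, 29, 54, 398, 0.5370, "Worst"),
    ("LMG13197", 61, 9, 60, 178, 0.1500, "TS"),
    ("LMG13208", 46, 9, 110, 438, 0.0818, "TS"),
    ("324B", 79, 0, 14, 223, 0.0000, "Worst"),
    ("LMG10505", 187, 56, 28, 146, 2.0000, "TS"),
]
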