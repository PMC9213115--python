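"""Shared physical and statistical constants.

All tables here are documented package defaults; every consumer accepts an
override so none of these values is hard-wired into an algorithm.
"""

from __future__ import annotations

AA_LETTERS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 canonical residues, alphabetical one-letter order."""

STOP: str = "*"
"""Symbol used for a translated stop codon throughout the package."""

EARLY_ALPHABET: frozenset[str] = frozenset("ASDGLIPTEV")
"""The 10-residue 'early' prebiotic alphabet (10E)."""

# Average amino-acid frequencies across UniProtKB/Swiss-Prot (release
# statistics, percent of residues). Normalized at point of use.
UNIPROT_FREQUENCIES: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.46, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.08, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.64, "T": 5.35, "W": 1.10, "Y": 2.92, "V": 6.86,
}

# Most frequently used E. coli K-12 codon per residue. Used only to
# reverse-translate fixed construct residues; downstream analyses are
# protein-level so the exact choice is non-critical.
ECOLI_PREFERRED_CODON: dict[str, str] = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}

# Average (chemical) residue masses in Da, i.e. amino acid minus water.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
AVERAGE_WATER_MASS: float = 18.0153

# Monoisotopic residue masses in Da.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
MONOISOTOPIC_WATER_MASS: float = 18.010565
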