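"""Constant lookup tables used by the feature-engineering module."""

from Bio.Data import CodonTable

#: Standard genetic code: codon -> amino acid (sense codons only).
_standard = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_standard.forward_table)
STOP_CODONS: frozenset = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple = tuple(sorted(GENETIC_CODE))
ALL_CODONS: tuple = tuple(sorted(GENETIC_CODE) + sorted(STOP_CODONS))

#: Synonymous families: amino acid -> tuple of codons.
SYNONYMOUS_FAMILIES: dict[str, tuple] = {}
for _codon, _aa in GENETIC_CODE.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: Human codon usage, occurrences per 1000 codons (standard reference
#: compilation).  Default reference for codon-adaptation weights; any
#: positive usage table with the same keys may be supplied instead.
HUMAN_CODON_USAGE_PER_1000: dict[str, float] = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3,
    "CAT": 10.9, "CAC": 15.1, "CAA": 12.3, "CAG": 34.2,
    "AAT": 17.0, "AAC": 19.1, "AAA": 24.4, "AAG": 31.9,
    "GAT": 21.8, "GAC": 25.1, "GAA": 29.0, "GAG": 39.6,
    "TGT": 10.6, "TGC": 12.6, "TGG": 13.2,
    "CGT": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGT": 12.1, "AGC": 19.5, "AGA": 12.2, "AGG": 12.0,
    "GGT": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Ten physicochemical residue classes (fractions reported per protein).
AMINO_ACID_CLASSES: dict[str, frozenset] = {
    "acidic": frozenset("DE"),
    "aromatic": frozenset("FWY"),
    "basic": frozenset("KRH"),
    "charged": frozenset("DEKRH"),
    "helix_affine": frozenset("AELM"),
    "hydrophobic": frozenset("AVILMFWC"),
    "polar": frozenset("STNQCYDEKRH"),
    "uncharged_polar": frozenset("STNQCY"),
    "sheet_affine": frozenset("VIYFWT"),
    "turn_affine": frozenset("GNPSD"),
}
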