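"""Physical-constant tables for protein physicochemical prediction.

Average (isotope-weighted) residue masses in Daltons are the Expasy values:
amino-acid mass minus one water, so a chain of L residues weighs
sum(residue masses) + 18.0153. Selenocysteine (U) is included with its
average residue mass 150.0379 Da.

The pKa set is the classic biochemistry-textbook (Lehninger-style) set of
side-chain and terminal dissociation constants used by spreadsheet pI
calculators; it is a configuration artifact — pass a different mapping to
``theoretical_pi`` to emulate another tool. Selenocysteine's selenol is not
titrated by default (treated as neutral) because reference web calculators
do not document their U handling.
"""

WATER_MW = 18.0153

# Expasy average residue masses (amino acid minus water), Da.
AVG_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326,
    "U": 150.0379,  # selenocysteine
}

# Kyte-Doolittle hydropathy. U defaults to Cys's value (closest chemistry);
# override via the u_value argument of gravy().
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8,
    "R": -4.5,
    "N": -3.5,
    "D": -3.5,
    "C": 2.5,
    "E": -3.5,
    "Q": -3.5,
    "G": -0.4,
    "H": -3.2,
    "I": 4.5,
    "L": 3.8,
    "K": -3.9,
    "M": 1.9,
    "F": 2.8,
    "P": -1.6,
    "S": -0.8,
    "T": -0.7,
    "W": -0.9,
    "Y": -1.3,
    "V": 4.2,
}

# pKa values: positively ionizable groups gain a proton below their pKa,
# negatively ionizable groups lose one above it.
PKA_POSITIVE: dict[str, float] = {
    "Nterm": 9.69,
    "K": 10.53,
    "R": 12.48,
    "H": 6.00,
}
PKA_NEGATIVE: dict[str, float] = {
    "Cterm": 2.34,
    "D": 3.65,
    "E": 4.25,
    "C": 8.33,
    "Y": 10.07,
}

VALID_RESIDUES = frozenset(AVG_RESIDUE_MASS)
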