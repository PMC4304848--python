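"""Published inputs for the E. coli thymidylate synthase (TS) case study.

TS (PDB 1f4b monomer, 1kzi dimer) is the enzyme on which this toolkit's
reference analyses were carried out. The amber-suppression mutagenesis
experiments introduced the same 13 replacement amino acids at 30 targeted
sequence positions, producing 372 single-residue variants (12 per position
whose native residue belongs to the replacement set, 13 otherwise) with
qualitative activity calls: 201 unaffected (U) and 171 detrimentally
affected (A). The contingency tables below summarize the distribution of
TS residues over the quadrants of the CMP-vs-RES correlation plot.
"""

from __future__ import annotations

import numpy as np

#: the 13 amino acids introduced at every targeted TS position
TS_SUBSTITUTION_SET: tuple[str, ...] = tuple("ACEFGHKLPQRSY")

#: the 30 targeted positions with their native residues (author numbering)
TS_POSITIONS: tuple[tuple[int, str], ...] = (
    # completely substitutable exposed surface positions
    (14, "E"), (105, "D"), (121, "N"), (223, "E"),
    # well conserved yet highly substitutable
    (33, "Q"), (35, "R"), (81, "D"), (127, "R"),
    # substrate-binding pocket
    (21, "R"), (80, "W"), (126, "R"), (147, "H"), (166, "R"),
    (169, "D"), (177, "N"),
    # active-site nucleophile
    (146, "C"),
    # structural elements
    (30, "F"), (110, "D"), (151, "Q"), (204, "G"),
    # surface loop covering residues 20-24
    (20, "D"), (22, "T"), (23, "G"), (24, "T"),
    # beta-strand spanning residues 25-35
    (25, "G"), (26, "T"), (27, "L"), (28, "S"), (29, "I"), (31, "G"),
)

#: experimentally determined activity class sizes over the 372 variants
TS_CLASS_SIZES = {"U": 201, "A": 171}

#: distribution of all 263 TS residues over the CMP-RES plot quadrants,
#: cross-tabulated against native-residue polarity
TS_QUADRANT_POLARITY_TABLE = np.array([
    #  apolar  charged  polar
    [8,  6,  21],   # Q1
    [11, 44, 38],   # Q2
    [7,  8,  9],    # Q3
    [77, 1,  33],   # Q4
])
TS_QUADRANT_POLARITY_ROWS = ("Q1", "Q2", "Q3", "Q4")
TS_QUADRANT_POLARITY_COLS = ("apolar", "charged", "polar")

#: distribution of 107 annotated TS residues (buried / catalytic / exposed /
#: dimer-interface) over the same quadrants
TS_QUADRANT_ANNOTATION_TABLE = np.array([
    #  buried  catalytic  exposed  interface
    [0,  2, 0,  7],    # Q1
    [0,  2, 22, 8],    # Q2
    [0,  0, 8,  6],    # Q3
    [34, 4, 2,  12],   # Q4
])
TS_QUADRANT_ANNOTATION_ROWS = ("Q1", "Q2", "Q3", "Q4")
TS_QUADRANT_ANNOTATION_COLS = ("buried", "catalytic", "exposed", "interface")

#: side-chain polarity classes used in the quadrant analyses
POLARITY = {
    "A": "apolar", "V": "apolar", "L": "apolar", "I": "apolar",
    "M": "apolar", "F": "apolar", "W": "apolar", "P": "apolar", "G": "apolar",
    "D": "charged", "E": "charged", "K": "charged", "R": "charged",
    "H": "charged",
    "S": "polar", "T": "polar", "N": "polar", "Q": "polar", "C": "polar",
    "Y": "polar",
}


def ts_variants():
    """The 372-variant TS experimental design as :class:`Variant` objects."""
    from .features import enumerate_variants

    return enumerate_variants(TS_POSITIONS, TS_SUBSTITUTION_SET)
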