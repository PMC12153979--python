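"""Shared physical and sequence constants."""

#: Wild-type amyloid-beta 1-42 amino-acid sequence (1-based positions 1..42).
AB42 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

#: Universal gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987e-3

#: Assay/selection temperature in kelvin used for all energy conversions.
T_KELVIN = 303.0

#: Aggregation-prone region 1 (residues 17-21) and 2 (residues 29-42),
#: inclusive 1-based ranges.
APR1 = (17, 21)
APR2 = (29, 42)

#: Positions mutated in the two combinatorial hydrophobic libraries.
COMB1_POSITIONS = (31, 32, 34, 35, 36, 39, 40, 41)
COMB2_POSITIONS = (19, 20, 24, 31, 32, 34)

#: The 20 proteinogenic amino acids (one-letter).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
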