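"""Physical constants for CHONSP mass arithmetic.

Monoisotopic masses are CODATA/IUPAC values.  All masses in Da.
"""

#: Monoisotopic masses of the elements considered during assignment.
ELEMENT_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376163,
    "S": 31.97207117,
}

#: Mass of a proton; used to neutralize [M-H]- ions (neutral = m/z + proton).
PROTON_MASS: float = 1.00727646

#: 13C - 12C mass difference; spacing of the first isotopologue satellite.
C13_C12_DELTA: float = 1.0033548

#: Monoisotopic mass of a CH2 methylene unit (homologous-series step).
CH2_MASS: float = ELEMENT_MASS["C"] + 2 * ELEMENT_MASS["H"]

#: Nominal and exact mass of the C4H2 Kendrick base unit.  The "printed"
#: value is the one quoted alongside the 50 amu nominal mass in the DOM
#: pyrogenic-carbon literature; it disagrees with the chemical monoisotopic
#: mass of C4H2 and breaks KMD constancy along true C4H2 series, so the
#: chemical value is the default throughout.
C4H2_NOMINAL: float = 50.0
C4H2_MASS_EXACT: float = 4 * ELEMENT_MASS["C"] + 2 * ELEMENT_MASS["H"]
C4H2_MASS_PRINTED: float = 50.0587
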