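"""Physical constants used throughout the package.

Monoisotopic atomic masses are the masses of the most abundant isotope of
each element (CODATA/IUPAC values, stored to at least 6 decimal places).
Extend ``MONOISOTOPIC_MASS`` to support further elements; every consumer
reads this table, so one entry here is enough.
"""

# Da, most abundant isotope per element
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
}

#: electron rest mass in Da; added per negative charge under the
#: include-electron m/z convention
ELECTRON_MASS: float = 0.000548579909

#: monoisotopic mass of one CH2 methylene unit (Da)
CH2_MASS: float = MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["H"]

#: deprotonated glucosyl-sulfated core of glucosinolates, [C7H11O9NS2]-,
#: as its printed reference m/z
GSL_CORE_MZ: float = 316.9881
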