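"""Monoisotopic masses and anion m/z of glucosinolate reference ions.

Glucosinolates ionize as [M-H]- in negative-mode electrospray.  Their
diagnostic fragments and glycosyl-sulfated cores have exact m/z values
that the rest of the workflow matches against; this script computes them
from elemental formulas under the include-electron convention.
"""

from gsltracer import anion_mz, monoisotopic_mass, parse_formula, ppm_error

IONS = {
    "glucosyl-sulfated core [C7H11O9NS2]-": "C7H11O9NS2",
    "hydrogen sulfate HSO4-": "HSO4",
    "sulfite radical SO3-": "SO3",
    "thioglucose fragment C6H11O5S-": "C6H11O5S",
    "rearrangement ion C6H11O9S-": "C6H11O9S",
}

for name, formula in IONS.items():
    f = parse_formula(formula)
    print(f"{name:45s} M = {monoisotopic_mass(f):10.4f} Da   "
          f"m/z = {anion_mz(f):10.4f}")

# a 5 ppm window at m/z 96.9601 spans under a millidalton:
print(f"\n5 ppm at HSO4-: {ppm_error(96.9606, 96.9601):+.2f} ppm for +0.5 mDa")
print("Each m/z is the deprotonated anion's monoisotopic mass plus one "
      "electron mass; these values anchor every matching tolerance downstream.")
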