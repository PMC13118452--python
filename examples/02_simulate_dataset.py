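"""Generate a synthetic glucosinolate LC-MS/MS bundle.

Builds a labeled compound library (glucosinolates assembled from the four
glycosyl-sulfated cores plus side-chain substituents, and range-matched
decoy formulas), then writes the paired MGF / feature-table / truth files
every other stage consumes.
"""

from pathlib import Path

from gsltracer.simulate import synth_feature_bundle, synth_library

out = Path("scratch/example_bundle")
library = synth_library(n_gsl=30, n_decoy=30, seed=42)
paths = synth_feature_bundle(library, out, seed=42)

gsl = [c for c in library if c.label == 0]
print(f"library: {len(library)} compounds ({len(gsl)} glucosinolates)")
print(f"m/z range: {min(c.mz for c in library):.4f} - {max(c.mz for c in library):.4f}")
print("example glucosinolate:", gsl[0].name, gsl[0].formula.hill(),
      f"m/z {gsl[0].mz:.4f}", "composition:", dict(gsl[0].composition))
for key, path in paths.items():
    print(f"wrote {key}: {path}")
print("The truth table carries the generator's labels, so screening "
      "recall and classifier accuracy are measurable without instrument data.")
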