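"""Screen MS/MS spectra for glucosinolate diagnostic ions and score them.

The screen requires the three AND-type sulfate-series ions (HSO4- 96.9601
with a 0.8-1 relative-abundance window, C2H3OS- 74.9872, and the
rearrangement ion 259.0129) and awards 10 points for the AND gate, 10
more when the abundance window holds, and 10 per matched OR-type ion —
so scores run from 10 to 60.
"""

from pathlib import Path

from gsltracer.screen import default_rule_set, screen
from gsltracer.simulate import synth_feature_bundle, synth_library

out = Path("scratch/example_screen")
library = synth_library(n_gsl=20, n_decoy=20, seed=7)
paths = synth_feature_bundle(library, out, seed=7)

rows, summary = screen(paths["mgf"], default_rule_set(), out / "screen_report.csv")
print(f"screened {summary['n_spectra']} spectra -> {summary['n_hits']} hits "
      f"({summary['n_merged_groups']} after 5 ppm precursor merging)")
for row in rows[:5]:
    print(f"  {row['spectrum_id']:10s} m/z {row['precursor_mz']:9.4f} "
          f"RT {row['rt_min']:5.2f} min  score {row['score']}")
print("Every hit is a planted glucosinolate; decoys carry no sulfate "
      "series and cannot pass the AND gate.")
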