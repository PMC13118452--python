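"""Formula annotation and CH2 homolog series for screened precursors.

A precursor m/z is explained as one of the four glycosyl-sulfated cores
plus a bounded multiset of substituents (CH2, O, S, H2, hexosyl, malonyl,
sinapoyl) whose masses sum to the residual within 5 ppm.  Residuals are
also clustered into CH2 homologous series: members differ by exact
multiples of 14.01565 Da and sit on parallels of the CH2 line in the
(integer, decimal) mass plane.
"""

from gsltracer.annotate import annotate_precursor, assign_core, ch2_cluster, lookup_formula

# the printed sulfinyl pair plus two constructed homologs
precursors = [422.0255, 436.0416, 450.0572, 373.0507]

residuals = []
for mz in precursors:
    cands = annotate_precursor(mz, tol_ppm=5)
    print(f"precursor {mz:9.4f}:")
    for cand in cands[:2]:
        subs = ", ".join(f"{n}x{c}" for n, c in cand.substituents) or "bare core"
        print(f"   {cand.core:26s} + {subs:18s} -> {cand.formula.hill():16s} "
              f"{cand.theoretical_mz:9.4f} ({cand.ppm:+.2f} ppm)")
    fits = assign_core(mz)
    residuals.append(min(fits, key=lambda cr: cr[1])[1])

series = ch2_cluster(residuals)
print(f"\n{len(series)} homolog series from {len(residuals)} residuals:")
for s in series:
    print(f"  series {s.series_id}: residuals "
          + ", ".join(f"{m:.4f}" for m in s.members))

records, status = lookup_formula("C11H19NO9S2")
print(f"\ncompound-database lookup status: {status} "
      "(offline by default; results never change the annotation ranking)")
print("The 422/436/450 residuals differ by one CH2 each - a homologous "
      "series of sulfinyl glucosinolates.")
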