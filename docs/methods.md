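# Methods

This note records the models implemented in `gsltracer`, their
assumptions, the defaults that matter, and what the synthetic-data tests
do and do not establish.

## Mass arithmetic

All masses are monoisotopic, summed from a single versioned table of
IUPAC/CODATA atomic masses (`constants.py`, ≥ 6 decimals).  Anion m/z
uses the **include-electron convention** by default,
m/z = (M + z·mₑ)/z with mₑ = 0.000548579909 Da, because that convention
reproduces the reference values used throughout the workflow (HSO₄⁻
96.9601, core C₇H₁₁O₉NS₂⁻ 316.9881) at four decimals.  A flag exposes
the no-electron variant; it is the one consistent with the SO₄ radical
anion value 95.9517 used in the OR rules.  Two reference values for the
C₂H₃OS fragment circulate — 74.9872 in screening lists and the computed
74.9910 — and they differ by far more than any instrument error.  The
screening default follows the published screening value (74.9872); the
formula engine reports 74.9910 as the theoretical value.  Since fragment
matching uses ±0.01 Da windows, a real ion at 74.9910 still matches the
74.9872 target; nothing downstream depends on resolving the discrepancy.

Display rounding is 4 decimals, round-half-even.  `split_mass` uses
floor semantics; negative masses are rejected rather than wrapped, so
callers must pre-filter negative core residuals.

## Mass-defect-filter classifier

**Representation.**  Four features per precursor: integer and decimal
parts of the accurate mass M−H, and of the residual m−H = (M−H) −
316.9881.  Precursors lighter than the core get residual features (0, 0)
— the representation stays strictly four-dimensional, and such ions are
effectively non-GSL.  The premise is that the decimal (mass-defect)
parts are class-informative: GSL side chains are dominated by CH₂ runs
(+0.01565 per unit) anchored at the sulfur-depressed core defect,
whereas generic plant metabolites scatter differently.

**Data.**  Training rows are each theoretical library mass plus
`n_augment` (default 30) uniform perturbations within ±10 ppm; test rows
use ±5 ppm.  The test-side augmentation count is not prescribed anywhere,
so it defaults to 10 — enough to exercise the tolerance band without
dominating runtime.  Classes are balanced by SMOTE (convex combinations
of k = 5 minority neighbors) followed by Tomek-link removal (both
members of each opposite-class mutual-nearest-neighbor pair), implemented
on sklearn `NearestNeighbors`.

**Network.**  4 → 512 → 256 → 128 → 64 → 2, each hidden layer as
Linear → BatchNorm → ReLU → Dropout(0.01) — batch norm before the
activation, the common ordering, since the stated architecture does not
fix it.  Focal loss −α(1−p_t)^γ log p_t with the standard published
defaults α = 0.25, γ = 2.0 (both configurable); Adam at 1e-3 with L2
1e-4 on weight matrices only; batch 64; 100 epochs; the best-test-
accuracy weights are checkpointed (ties broken toward lower test loss).
Inputs are z-scored with statistics of the training set, stored in the
model — the integer features span hundreds of Da while decimals live in
[0,1), and without standardization the first layer is badly conditioned
and convergence on small sets is unreliable.  Train-side epoch metrics
are the running averages over that epoch's minibatches (training mode);
test metrics come from a full inference-mode pass each epoch.  The whole
stack is numpy (float32), seeded from one Generator, so identical seeds
give identical histories; the backward pass, including batch-norm and
the focal-loss gradient, is verified against finite differences in the
test suite.

Explainability is permutation feature importance: mean accuracy drop
over seeded shuffles of each feature column.

## Diagnostic-ion screening

A rule is a target m/z, a tolerance (±0.01 Da default for fragments —
ppm is available per rule), a group (AND/OR) and an abundance window.
Matching for *presence* ignores the abundance window; the closest peak
within tolerance is the match.  Scoring is additive: base 10 iff every
AND rule matches; +10 iff every AND rule that has a non-trivial window
also satisfies it (granted as a single bonus, not per ion, and only when
at least one window is configured); +10 per matched OR rule.  Under the
default rules scores live on {10, 20, …, 60}.  Precursor merging is
single-linkage on m/z at ±5 ppm — sorted chaining, deterministic under
input permutation; the group representative is the highest-scoring
member (ties → lowest RT) and its *observed* m/z is reported, never an
average.  RT plays no role in merging.

## Tracer molecular networking

Filtering requires **all** primary ions (96.95, 74.98; minimum relative
abundance 0.5) and, when secondary ions are configured, **at least one**
of them (259.0128, 240.9657, 192.0194; threshold 0.01) — the
secondary gate is an OR, configurable.  The primary targets are
2-decimal values whose literal ±0.01 Da windows would *exclude* the true
ions (96.9601, 74.9910); the implementation therefore floors the
effective primary tolerance at ±0.0151 Da so the intended ions fall
inside, and logs that widening.  Set `widen_primary=False` for the
literal reading.  Optional neutral-loss rules match precursor-minus-
fragment differences at the same tolerance and are off by default.

The local network stand-in uses the modified cosine: square-root
intensity weighting; peaks pair directly or shifted by the precursor
difference at ±0.01 Da; the optimal one-to-one pairing is solved exactly
with the Hungarian algorithm (verified against brute-force enumeration
on small spectra).  Edge thresholds follow common feature-based
molecular-networking defaults — cosine ≥ 0.7, ≥ 6 matched peaks, and a
top-10 edge cap enforced on **both** endpoints so no node exceeds ten
edges.  Redundancy reduction is 1 − nodes/unfiltered nodes.

## Substituent annotation and CH₂ homologs

Cores: C₇H₁₁O₉NS₂⁻ 316.9880, C₁₃H₂₁O₁₄NS₂⁻ 479.0409, C₁₀H₁₃O₁₂NS₂⁻
402.9885, C₁₈H₂₁O₁₃NS₂⁻ 523.0460; each stored m/z must agree with the
formula within 0.0005 Da (printed values are 4-decimal roundings).  The
substituent library is a reconstruction from the annotated GSL classes
(regular / malonyl / sinapoyl / diglycoside): CH₂ (≤ 20), O, S, H₂,
hexosyl C₆H₁₀O₅, malonyl C₃H₂O₃, sinapoyl C₁₁H₁₀O₄ (each ≤ 2), fully
user-configurable.  Enumeration is depth-first over count vectors with
running-mass pruning, emitted in lexicographic order and tested against
exhaustive grid enumeration; the default tolerance is ±5 ppm of the
precursor.  All fitting cores are reported, ranked by |ppm| of the best
combination — the data cannot adjudicate between cores at equal mass
error, so none is suppressed.

Homolog clustering plots each residual as (integer part, decimal part)
and uses the CH₂ reference line y = (0.01565/14)·x.  Membership is
transitive (union-find) with the **exact mass-difference test as the
authority**: two residuals join when |Δm − k·14.01565| ≤ 5 mDa.  The
perpendicular line distance (tolerance 1 mDa) is enforced only between
points whose integer parts differ by a multiple of 14; when a homolog
step carries the decimal past 1.0 the integer difference becomes 14k+1
and the plane representation misleads, so the distance check is skipped
there.  For true CH₂ series the distances agree identically, since
slope·14 equals the CH₂ decimal increment.

Compound lookup (PubChem REST, by formula) is offline-first: the default
client returns an empty record list with status `offline`, caches
results locally when online, rate-limits, and degrades to offline on any
network failure.  Lookup results never affect annotation ranking.

## Synthetic data: the stated world

`synth_library` builds GSLs as a random core + a CH₂ run of 0–12 +
optional single substituents (O 30%, S 15%, H₂ 20%, hexosyl/malonyl/
sinapoyl 10% each); decoys are random CHNO(S) formulas with plant-like
H/C ratios (0.8–2.0), **range-matched to the GSL m/z distribution** so
mass magnitude alone cannot separate the classes — the mass-defect
structure has to.  `synth_spectrum` plants the three AND ions (HSO₄⁻
drawn in 0.8–1, C₂H₃OS⁻ in 0.5–0.95, the rearrangement ion in
0.05–0.5), each OR ion with probability 0.7, one side-chain fragment,
and 5–20 noise peaks below 0.3 relative abundance; all m/z are jittered
by 2 ppm (Orbitrap-like).  Noise peaks are excluded from ±0.05 Da around
the diagnostic ions, so a decoy can never fake the sulfate series by
chance — decoy rejection in the tests is a property of the stated world,
not of sampling luck.  The generator does not model isotopologues,
adducts other than [M−H]⁻, chromatographic peak shape, or co-isolation
chimeras; a green screening or classification test therefore establishes
correctness of the logic on clean, well-calibrated spectra, not
robustness to those artifacts.

The 1493-compound scale used in the acceptance test (750 GSLs + 743
decoys) mirrors the precursor-ion scale the workflow is designed for.
Because the underlying real compound database is not published, the
classifier criterion is property-based — test accuracy ≥ 0.90 on this
generator — rather than reproduction of a specific printed figure.

## Numerical choices and degenerate inputs

- Fragment matching: Da windows compare |Δ| ≤ tol inclusively; ppm uses
  signed relative error, inclusive.
- Spectra with all-zero intensities normalize to relative abundance 1.0
  for every peak rather than dividing by zero; empty peak lists are
  rejected where normalization is required.
- Batches of size 1 are skipped during training (batch norm undefined).
- SMOTE requires each class to have at least k+1 members; single-class
  datasets are rejected before training.
- `merge_precursors` chains *consecutive* sorted gaps, which on a line
  is exactly single linkage.

## Known limitations

- The MLP is a plain numpy implementation: CPU-only, no early stopping,
  no hyperparameter search.
- The tracer network is a local stand-in for a molecular-networking
  service: no spectral-library matching, no visualization layout.
- Annotation is formula-level only; isomers and positional variants are
  indistinguishable by design, and candidates should be read as
  tentative.
- The MGF reader supports the MZmine-style dialect (TITLE, PEPMASS,
  RTINSECONDS, CHARGE, FEATURE_ID), not the full zoo of MGF variants.
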