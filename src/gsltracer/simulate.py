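"""Seeded generators for synthetic glucosinolate libraries and spectra.

No public glucosinolate LC-MS/MS dataset accompanies the workflow, so the
package carries its own stated world: a theoretical compound library
(glucosinolates assembled as core + substituents, decoys drawn from a
range-matched non-glucosinolate formula space) and MS/MS spectra that
plant the diagnostic sulfate-series ions at realistic relative abundances
plus uniform noise.  Every downstream module — screening, the MDF
classifier, tracer networking, annotation — is testable against the
generator's ground-truth labels.

Decoys are deliberately range-matched in m/z to the glucosinolates so a
classifier cannot separate the classes on mass magnitude alone: the
mass-defect (decimal) structure has to carry the signal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import DEFAULT_CORES, DEFAULT_SUBSTITUENTS, CoreDefinition
from .chem import ElementalFormula, anion_mz, parse_formula
from .msio import FragmentPeak, Ms2Spectrum, write_mgf

__all__ = [
    "SynthCompound",
    "SpectrumParams",
    "synth_library",
    "synth_spectrum",
    "synth_feature_bundle",
]

# diagnostic ions planted in glucosinolate spectra (screening defaults)
AND_IONS = (96.9601, 74.9872, 259.0129)
OR_IONS = (79.9574, 95.9517, 274.9901, 241.0024)
# noise peaks never land within this window of any diagnostic ion, so a
# decoy can never fake the sulfate series by chance
_EXCLUSION_DA = 0.05


@dataclass(frozen=True)
class SynthCompound:
    name: str
    formula: ElementalFormula
    mz: float
    label: int  # 0 = GSL, 1 = other
    composition: tuple[tuple[str, int], ...] | None = None  # core + substituents, GSLs only
    core: str | None = None


@dataclass(frozen=True)
class SpectrumParams:
    """Knobs of the spectrum generator.

    Defaults state the emulated world: fragment and precursor m/z jitter
    of 2 ppm (Orbitrap-like), HSO4- drawn in the 0.8-1 relative-abundance
    band the screening rules expect, the C2H3OS- ion above the tracer
    primary threshold of 0.5, and 5-20 uniform noise peaks below 0.3.
    """

    fragment_jitter_ppm: float = 2.0
    precursor_jitter_ppm: float = 2.0
    abundance_hso4: tuple[float, float] = (0.8, 1.0)
    abundance_c2h3os: tuple[float, float] = (0.5, 0.95)
    abundance_rearrangement: tuple[float, float] = (0.05, 0.5)
    abundance_or: tuple[float, float] = (0.05, 0.6)
    or_ion_prob: float = 0.7
    noise_peaks: tuple[int, int] = (5, 20)
    noise_abundance_max: float = 0.3
    base_intensity: float = 1e6

    def __post_init__(self) -> None:
        if self.fragment_jitter_ppm < 0 or self.precursor_jitter_ppm < 0:
            raise ValueError("jitter must be non-negative")
        for lo, hi in (
            self.abundance_hso4,
            self.abundance_c2h3os,
            self.abundance_rearrangement,
            self.abundance_or,
        ):
            if not 0 <= lo <= hi <= 1:
                raise ValueError("abundance ranges must lie within [0, 1]")


def _gsl_compound(rng: np.random.Generator, index: int,
                  cores: Sequence[CoreDefinition]) -> SynthCompound:
    core = cores[rng.integers(0, len(cores))]
    subs = {s.name: s for s in DEFAULT_SUBSTITUENTS}
    composition: list[tuple[str, int]] = []
    formula = core.formula
    n_ch2 = int(rng.integers(0, 13))
    if n_ch2:
        formula = formula + subs["CH2"].formula * n_ch2
        composition.append(("CH2", n_ch2))
    for name, prob in (("O", 0.3), ("S", 0.15), ("H2", 0.2),
                       ("hexosyl", 0.1), ("malonyl", 0.1), ("sinapoyl", 0.1)):
        if rng.random() < prob:
            formula = formula + subs[name].formula
            composition.append((name, 1))
    return SynthCompound(
        name=f"GSL_{index:04d}",
        formula=formula,
        mz=anion_mz(formula),
        label=0,
        composition=tuple(composition),
        core=core.name,
    )


def _decoy_compound(rng: np.random.Generator, index: int,
                    mz_lo: float, mz_hi: float) -> SynthCompound:
    """A plausible non-glucosinolate organic anion in the same m/z range.

    Random CHNO(S) composition without the sulfated-oxime core: oxygen
    count, optional single N/S, and an H/C ratio typical of plant
    secondary metabolites.
    """
    target = rng.uniform(mz_lo, mz_hi)
    for _ in range(50):
        n_o = int(rng.integers(2, 12))
        n_n = int(rng.integers(0, 3))
        n_s = int(rng.integers(0, 2))
        remaining = target - n_o * 15.9949146196 - n_n * 14.0030740048 - n_s * 31.972071
        if remaining < 24:
            continue
        ratio = rng.uniform(0.8, 2.0)  # H per C
        n_c = int(round(remaining / (12.0 + ratio * 1.00782503207)))
        if n_c < 2:
            continue
        n_h = int(round((remaining - 12.0 * n_c) / 1.00782503207))
        if n_h < 1 or n_h > 2 * n_c + n_n + 2:
            continue
        counts = {"C": n_c, "H": n_h, "O": n_o}
        if n_n:
            counts["N"] = n_n
        if n_s:
            counts["S"] = n_s
        formula = ElementalFormula(counts)
        return SynthCompound(
            name=f"decoy_{index:04d}", formula=formula, mz=anion_mz(formula), label=1
        )
    # fallback: plain carbohydrate-like composition near the target
    n_c = max(int(target // 24), 2)
    formula = parse_formula(f"C{n_c}H{n_c * 2}O{max(int((target - 13 * n_c) / 16), 1)}")
    return SynthCompound(
        name=f"decoy_{index:04d}", formula=formula, mz=anion_mz(formula), label=1
    )


def synth_library(n_gsl: int, n_decoy: int, seed: int = 0) -> list[SynthCompound]:
    """Seeded theoretical compound library: ``n_gsl`` glucosinolates
    (label 0) followed by ``n_decoy`` range-matched decoys (label 1)."""
    if n_gsl < 0 or n_decoy < 0:
        raise ValueError("compound counts must be non-negative")
    rng = np.random.default_rng(seed)
    gsls = [_gsl_compound(rng, i, DEFAULT_CORES) for i in range(n_gsl)]
    if gsls:
        mz_lo = min(c.mz for c in gsls)
        mz_hi = max(c.mz for c in gsls)
    else:
        mz_lo, mz_hi = 300.0, 700.0
    decoys = [_decoy_compound(rng, i, mz_lo, mz_hi) for i in range(n_decoy)]
    return gsls + decoys


def _jitter(mz: float, ppm: float, rng: np.random.Generator) -> float:
    if ppm == 0:
        return mz
    return mz * (1.0 + rng.uniform(-ppm, ppm) * 1e-6)


def _noise_peaks(rng: np.random.Generator, params: SpectrumParams,
                 mz_max: float) -> list[tuple[float, float]]:
    lo, hi = params.noise_peaks
    n = int(rng.integers(lo, hi + 1))
    out: list[tuple[float, float]] = []
    forbidden = AND_IONS + OR_IONS
    while len(out) < n:
        mz = rng.uniform(60.0, mz_max)
        if any(abs(mz - f) < _EXCLUSION_DA for f in forbidden):
            continue
        out.append((mz, rng.uniform(0.01, params.noise_abundance_max)))
    return out


def synth_spectrum(
    compound: SynthCompound,
    params: SpectrumParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> Ms2Spectrum:
    """One MS/MS spectrum for a library compound.

    Glucosinolates carry the three AND diagnostic ions (HSO4- in its
    configured abundance band), a random subset of the OR ions, a
    side-chain fragment, plus noise; decoys carry only non-diagnostic
    fragments and noise.  All m/z values are ppm-jittered.
    """
    params = params or SpectrumParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    precursor = _jitter(compound.mz, params.precursor_jitter_ppm, rng)
    rel: list[tuple[float, float]] = []
    if compound.label == 0:
        bands = (params.abundance_hso4, params.abundance_c2h3os, params.abundance_rearrangement)
        for ion, (lo, hi) in zip(AND_IONS, bands):
            rel.append((_jitter(ion, params.fragment_jitter_ppm, rng), rng.uniform(lo, hi)))
        for ion in OR_IONS:
            if rng.random() < params.or_ion_prob:
                lo, hi = params.abundance_or
                rel.append((_jitter(ion, params.fragment_jitter_ppm, rng), rng.uniform(lo, hi)))
        # one side-chain fragment: loss of the thioglucose-sulfate block
        frag = compound.mz - 259.0129
        if frag > 60:
            rel.append((_jitter(frag, params.fragment_jitter_ppm, rng),
                        rng.uniform(0.1, 0.6)))
    else:
        # decoy backbone fragments: a couple of generic losses
        for loss in (18.010565, 44.997654, 162.05282):
            frag = compound.mz - loss
            if frag > 60 and rng.random() < 0.6:
                rel.append((_jitter(frag, params.fragment_jitter_ppm, rng),
                            rng.uniform(0.2, 1.0)))
    rel.extend(_noise_peaks(rng, params, mz_max=max(precursor - 1.0, 100.0)))
    if not rel:
        rel.append((max(precursor - 18.0, 60.0), 1.0))
    top = max(ra for _, ra in rel)
    peaks = tuple(
        FragmentPeak(mz=mz, intensity=params.base_intensity * ra / top) for mz, ra in rel
    )
    return Ms2Spectrum(
        spectrum_id=compound.name,
        precursor_mz=precursor,
        rt_min=0.0,
        charge=-1,
        peaks=peaks,
    )


def synth_feature_bundle(
    library: Sequence[SynthCompound],
    out_dir: str | Path,
    params: SpectrumParams | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Paired MGF + feature CSV + ground-truth CSV for a library.

    One spectrum and one feature row per compound, ids consistent across
    the three files, retention times strictly increasing.  Identical
    seeds give byte-identical files.
    """
    if not library:
        raise ValueError("library is empty")
    params = params or SpectrumParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rts = np.cumsum(rng.uniform(0.05, 0.25, size=len(library))) + 1.0
    spectra = []
    for compound, rt in zip(library, rts):
        spec = synth_spectrum(compound, params, rng)
        spectra.append(
            Ms2Spectrum(
                spectrum_id=spec.spectrum_id,
                precursor_mz=spec.precursor_mz,
                rt_min=float(rt),
                charge=spec.charge,
                peaks=spec.peaks,
            )
        )
    mgf_path = out_dir / "spectra.mgf"
    write_mgf(spectra, mgf_path)
    features_path = out_dir / "features.csv"
    with features_path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "mz", "rt", "area"])
        for spec in spectra:
            area = float(rng.uniform(1e5, 1e7))
            writer.writerow([spec.spectrum_id, f"{spec.precursor_mz:.4f}",
                             f"{spec.rt_min:.3f}", f"{area:.1f}"])
    truth_path = out_dir / "truth.csv"
    with truth_path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "formula", "mz", "label", "core", "composition"])
        for c in library:
            comp = ";".join(f"{n}x{k}" for n, k in (c.composition or ()))
            writer.writerow([c.name, c.formula.hill(), f"{c.mz:.6f}", c.label,
                             c.core or "", comp])
    return {"mgf": mgf_path, "features": features_path, "truth": truth_path}
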