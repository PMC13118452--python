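"""Automated diagnostic-ion screening for glucosinolate MS/MS spectra.

Glucosinolates fragment along their glucosyl-sulfated core into a small,
highly reproducible set of sulfate-series ions (HSO4- 96.9601, SO3-
79.9574, SO4- 95.9517, C2H3OS- 74.9872, thioglucose rearrangement ions
259.0129 / 274.9901 / 241.0024).  The screen requires all AND-type ions to
be present and awards points additively:

* base 10 when every AND ion matches a peak within tolerance,
* +10 when every configured AND abundance window is also satisfied
  (by default only HSO4- carries a window, 0.8-1),
* +10 per matched OR-type ion.

Matching for presence deliberately ignores the abundance window: a
spectrum with HSO4- at 0.5 still passes the AND gate (score 10) but does
not earn the abundance bonus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .chem import within_tol
from .msio import Ms2Spectrum, read_mgf, write_screen_report

__all__ = [
    "DiagnosticIonRule",
    "ScreenRuleSet",
    "ScreenHit",
    "MergedHit",
    "normalize_abundance",
    "score_spectrum",
    "merge_precursors",
    "screen",
]


@dataclass(frozen=True)
class DiagnosticIonRule:
    """One diagnostic ion: target m/z, tolerance, group and abundance window."""

    target_mz: float
    tolerance: float = 0.01
    unit: str = "da"  # "da" | "ppm"
    group: str = "AND"  # "AND" | "OR"
    abundance_min: float = 0.0
    abundance_max: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.unit not in ("da", "ppm"):
            raise ValueError(f"tolerance unit must be 'da' or 'ppm', got {self.unit!r}")
        if self.group not in ("AND", "OR"):
            raise ValueError(f"rule group must be 'AND' or 'OR', got {self.group!r}")
        if not 0 <= self.abundance_min <= self.abundance_max <= 1:
            raise ValueError("abundance window must satisfy 0 <= min <= max <= 1")
        if not self.label:
            object.__setattr__(self, "label", f"mz_{self.target_mz:.4f}")

    def matches(self, mz: float) -> bool:
        if self.unit == "da":
            return abs(mz - self.target_mz) <= self.tolerance
        return within_tol(mz, self.target_mz, self.tolerance)

    @property
    def has_window(self) -> bool:
        return (self.abundance_min, self.abundance_max) != (0.0, 1.0)


def default_rule_set() -> "ScreenRuleSet":
    """The glucosinolate defaults: three AND ions (HSO4- with a 0.8-1
    abundance window, C2H3OS-, the 259.0129 rearrangement ion) and four
    OR ions (SO3-, SO4-, 274.9901, 241.0024)."""
    return ScreenRuleSet(
        and_rules=(
            DiagnosticIonRule(96.9601, abundance_min=0.8, abundance_max=1.0, label="HSO4"),
            DiagnosticIonRule(74.9872, label="C2H3OS"),
            DiagnosticIonRule(259.0129, label="C6H11O9S"),
        ),
        or_rules=(
            DiagnosticIonRule(79.9574, group="OR", label="SO3"),
            DiagnosticIonRule(95.9517, group="OR", label="SO4"),
            DiagnosticIonRule(274.9901, group="OR", label="C6H11O8S2"),
            DiagnosticIonRule(241.0024, group="OR", label="C6H9O8S"),
        ),
    )


@dataclass(frozen=True)
class ScreenRuleSet:
    and_rules: tuple[DiagnosticIonRule, ...] = ()
    or_rules: tuple[DiagnosticIonRule, ...] = ()
    base_score: int = 10
    abundance_bonus: int = 10
    or_bonus_per_ion: int = 10
    merge_tol_ppm: float = 5.0

    def __post_init__(self) -> None:
        for rule in self.and_rules:
            if rule.group != "AND":
                raise ValueError(f"rule {rule.label} in and_rules has group {rule.group}")
        for rule in self.or_rules:
            if rule.group != "OR":
                raise ValueError(f"rule {rule.label} in or_rules has group {rule.group}")
        if min(self.base_score, self.abundance_bonus, self.or_bonus_per_ion, 0) < 0:
            raise ValueError("score constants must be non-negative")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.and_rules + self.or_rules)


@dataclass(frozen=True)
class ScreenHit:
    spectrum_id: str
    precursor_mz: float
    charge: int
    rt_min: float
    matched: dict[str, tuple[float, float]]  # rule label -> (peak m/z, rel abundance)
    score: int

    def as_report_row(self) -> dict[str, object]:
        return {
            "spectrum_id": self.spectrum_id,
            "precursor_mz": self.precursor_mz,
            "charge": self.charge,
            "rt_min": self.rt_min,
            "matched": self.matched,
            "score": self.score,
        }


@dataclass(frozen=True)
class MergedHit:
    representative_mz: float
    members: tuple[ScreenHit, ...]
    best_score: int


def normalize_abundance(spectrum: Ms2Spectrum) -> Ms2Spectrum:
    """Base-peak normalization: relative abundance = intensity / max."""
    return spectrum.normalize()


def _closest_match(rule: DiagnosticIonRule, spectrum: Ms2Spectrum):
    """Closest peak within the rule's tolerance, or None."""
    best = None
    for peak in spectrum.peaks:
        if rule.matches(peak.mz):
            if best is None or abs(peak.mz - rule.target_mz) < abs(best.mz - rule.target_mz):
                best = peak
    return best


def score_spectrum(spectrum: Ms2Spectrum, rules: ScreenRuleSet) -> ScreenHit | None:
    """Apply the AND/OR logic and scoring to one normalized spectrum.

    Returns None unless every AND rule matches a peak within tolerance.
    """
    if spectrum.peaks and spectrum.peaks[0].relative_abundance is None:
        spectrum = spectrum.normalize()
    matched: dict[str, tuple[float, float]] = {}
    windows_ok = True
    for rule in rules.and_rules:
        peak = _closest_match(rule, spectrum)
        if peak is None:
            return None
        ra = peak.relative_abundance or 0.0
        matched[rule.label] = (peak.mz, ra)
        if rule.has_window and not (rule.abundance_min <= ra <= rule.abundance_max):
            windows_ok = False
    score = rules.base_score
    if rules.and_rules and windows_ok and any(r.has_window for r in rules.and_rules):
        score += rules.abundance_bonus
    for rule in rules.or_rules:
        peak = _closest_match(rule, spectrum)
        if peak is not None:
            matched[rule.label] = (peak.mz, peak.relative_abundance or 0.0)
            score += rules.or_bonus_per_ion
    return ScreenHit(
        spectrum_id=spectrum.spectrum_id,
        precursor_mz=spectrum.precursor_mz,
        charge=spectrum.charge,
        rt_min=spectrum.rt_min,
        matched=matched,
        score=score,
    )


def merge_precursors(hits: Sequence[ScreenHit], tol_ppm: float = 5.0) -> list[MergedHit]:
    """Single-linkage grouping of hits on precursor m/z at ``tol_ppm``.

    Deterministic under input permutation: hits are sorted by m/z and
    chained while consecutive gaps stay within tolerance.  The group
    representative is the member with the highest score, ties broken by
    the lowest retention time, and its observed m/z is reported unchanged.
    """
    if not hits:
        return []
    ordered = sorted(hits, key=lambda h: (h.precursor_mz, h.rt_min, h.spectrum_id))
    groups: list[list[ScreenHit]] = [[ordered[0]]]
    for hit in ordered[1:]:
        prev = groups[-1][-1]
        if within_tol(hit.precursor_mz, prev.precursor_mz, tol_ppm):
            groups[-1].append(hit)
        else:
            groups.append([hit])
    merged: list[MergedHit] = []
    for group in groups:
        rep = min(group, key=lambda h: (-h.score, h.rt_min, h.spectrum_id))
        merged.append(
            MergedHit(
                representative_mz=rep.precursor_mz,
                members=tuple(group),
                best_score=rep.score,
            )
        )
    return merged


def screen(
    mgf_path: str | Path,
    rules: ScreenRuleSet | None = None,
    report_path: str | Path | None = None,
    report_format: str = "csv",
) -> tuple[list[dict[str, object]], dict[str, int]]:
    """Full screening pipeline: read -> normalize -> score -> merge -> report.

    Returns the report rows (ordered by retention time) and a summary with
    spectrum, hit and merged-group counts.
    """
    rules = rules or default_rule_set()
    spectra = read_mgf(mgf_path)
    hits: list[ScreenHit] = []
    for spec in spectra:
        if not spec.peaks:
            continue
        hit = score_spectrum(spec.normalize(), rules)
        if hit is not None:
            hits.append(hit)
    merged = merge_precursors(hits, rules.merge_tol_ppm)
    rows = [h.as_report_row() for h in sorted(hits, key=lambda h: (h.rt_min, h.spectrum_id))]
    if report_path is not None:
        write_screen_report(rows, report_path, fmt=report_format, ion_labels=rules.labels)
    summary = {"n_spectra": len(spectra), "n_hits": len(hits), "n_merged_groups": len(merged)}
    return rows, summary
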