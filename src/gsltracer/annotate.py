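"""Core assignment, substituent enumeration and CH2 homolog clustering.

A glucosinolate precursor [M-H]- decomposes into one of four glycosyl-
sulfated cores plus a side-chain residual mass.  The residual is explained
as a bounded multiset of substituent mass deltas (CH2 runs, oxygenation,
saturation changes, hexosyl / malonyl / sinapoyl groups), and the full
anion formula is reassembled as core + sum of substituents.  Residuals
are also clustered into CH2 homologous series: plotted as (integer part,
decimal part), members of a series sit on parallels of the CH2 reference
line y = (0.01565 / 14) x and differ by exact multiples of 14.01565 Da.

Compound lookup against the public PubChem REST interface is strictly
optional: offline is the default and the annotation scores never depend
on lookup results.
"""

from __future__ import annotations

import json
import logging
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .chem import (
    ElementalFormula,
    anion_mz,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    split_mass,
)
from .constants import CH2_MASS

logger = logging.getLogger(__name__)

__all__ = [
    "CoreDefinition",
    "SubstituentDefinition",
    "AnnotationCandidate",
    "HomologSeries",
    "DEFAULT_CORES",
    "DEFAULT_SUBSTITUENTS",
    "assign_core",
    "enumerate_substituents",
    "assemble_formula",
    "annotate_precursor",
    "ch2_cluster",
    "lookup_formula",
]

#: slope of the CH2 reference line in the (integer, decimal) mass plane:
#: one CH2 advances the integer part by 14 and the decimal part by 0.01565
CH2_LINE_SLOPE = (CH2_MASS - 14.0) / 14.0


@dataclass(frozen=True)
class CoreDefinition:
    name: str
    formula: ElementalFormula
    mz: float

    def __post_init__(self) -> None:
        computed = anion_mz(self.formula)
        if abs(computed - self.mz) > 0.0005:
            raise ValueError(
                f"core {self.name}: stored m/z {self.mz} disagrees with computed "
                f"{computed:.4f} by more than 0.0005 Da"
            )


@dataclass(frozen=True)
class SubstituentDefinition:
    name: str
    formula: ElementalFormula
    max_count: int

    def __post_init__(self) -> None:
        if self.max_count < 0:
            raise ValueError("max_count must be non-negative")

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


def _core(name: str, formula: str, mz: float) -> CoreDefinition:
    return CoreDefinition(name=name, formula=parse_formula(formula), mz=mz)


#: the four glycosyl-sulfated cores, as deprotonated anions
DEFAULT_CORES: tuple[CoreDefinition, ...] = (
    _core("glucosyl-sulfated", "C7H11O9NS2", 316.9880),
    _core("diglycosyl-sulfated", "C13H21O14NS2", 479.0409),
    _core("malonyl-glucosyl-sulfated", "C10H13O12NS2", 402.9885),
    _core("sinapoyl-glucosyl-sulfated", "C18H21O13NS2", 523.0460),
)


def _sub(name: str, formula: str, max_count: int) -> SubstituentDefinition:
    return SubstituentDefinition(name=name, formula=parse_formula(formula), max_count=max_count)


#: common side-chain building blocks; user-configurable
DEFAULT_SUBSTITUENTS: tuple[SubstituentDefinition, ...] = (
    _sub("CH2", "CH2", 20),
    _sub("O", "O", 2),
    _sub("S", "S", 2),
    _sub("H2", "H2", 2),
    _sub("hexosyl", "C6H10O5", 2),
    _sub("malonyl", "C3H2O3", 2),
    _sub("sinapoyl", "C11H10O4", 2),
)


@dataclass(frozen=True)
class AnnotationCandidate:
    precursor_mz: float
    core: str
    substituents: tuple[tuple[str, int], ...]  # (name, count), library order
    formula: ElementalFormula
    theoretical_mz: float
    ppm: float


@dataclass(frozen=True)
class HomologSeries:
    series_id: int
    members: tuple[float, ...]  # residual masses, ascending
    points: tuple[tuple[int, float], ...]  # (integer, decimal) per member
    line_distance: float  # mean signed perpendicular distance to the CH2 line


def assign_core(
    precursor_mz: float, cores: Sequence[CoreDefinition] = DEFAULT_CORES
) -> list[tuple[CoreDefinition, float]]:
    """All cores with a non-negative residual = precursor - core m/z."""
    if precursor_mz <= 0:
        raise ValueError(f"precursor m/z must be positive, got {precursor_mz}")
    out = []
    for core in cores:
        residual = precursor_mz - core.mz
        if residual >= 0:
            out.append((core, residual))
    return out


def enumerate_substituents(
    residual: float,
    library: Sequence[SubstituentDefinition] = DEFAULT_SUBSTITUENTS,
    tol_da: float = 0.005,
) -> list[tuple[tuple[str, int], ...]]:
    """All bounded substituent multisets whose mass sums to ``residual``.

    Depth-first search over count vectors c (0 <= c_i <= max_count_i)
    with running-mass pruning; a vector is emitted when
    |residual - sum c_i * m_i| <= tol_da.  Output order is lexicographic
    in the count vector, so results are deterministic for a fixed library.
    """
    if residual < 0:
        raise ValueError(f"residual mass must be non-negative, got {residual}")
    if not library:
        raise ValueError("substituent library is empty")
    masses = [s.mass for s in library]
    # max attainable mass from position i onward, for pruning
    suffix_max = [0.0] * (len(library) + 1)
    for i in range(len(library) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + masses[i] * library[i].max_count

    results: list[tuple[tuple[str, int], ...]] = []
    counts = [0] * len(library)

    def dfs(i: int, remaining: float) -> None:
        if remaining < -tol_da:
            return
        if i == len(library):
            if abs(remaining) <= tol_da:
                results.append(
                    tuple((s.name, c) for s, c in zip(library, counts) if c > 0)
                )
            return
        if remaining - suffix_max[i] > tol_da:
            return  # even maxing every remaining substituent cannot reach
        for c in range(library[i].max_count + 1):
            used = c * masses[i]
            if remaining - used < -tol_da:
                break
            counts[i] = c
            dfs(i + 1, remaining - used)
        counts[i] = 0

    dfs(0, residual)
    return results


def assemble_formula(
    core: CoreDefinition,
    multiset: Sequence[tuple[str, int]],
    library: Sequence[SubstituentDefinition] = DEFAULT_SUBSTITUENTS,
) -> tuple[ElementalFormula, float]:
    """Element-wise sum of the core and substituent formulas, with its
    theoretical anion m/z."""
    by_name = {s.name: s for s in library}
    formula = core.formula
    for name, count in multiset:
        if count <= 0:
            continue
        formula = formula + by_name[name].formula * count
    return formula, anion_mz(formula)


def annotate_precursor(
    precursor_mz: float,
    cores: Sequence[CoreDefinition] = DEFAULT_CORES,
    library: Sequence[SubstituentDefinition] = DEFAULT_SUBSTITUENTS,
    tol_ppm: float = 5.0,
) -> list[AnnotationCandidate]:
    """Full annotation of one precursor: every fitting core is tried,
    candidates are ranked by absolute ppm error of the assembled formula."""
    tol_da = tol_ppm * 1e-6 * precursor_mz
    candidates: list[AnnotationCandidate] = []
    for core, residual in assign_core(precursor_mz, cores):
        for multiset in enumerate_substituents(residual, library, tol_da):
            formula, theo = assemble_formula(core, multiset, library)
            ppm = ppm_error(precursor_mz, theo)
            if abs(ppm) <= tol_ppm:
                candidates.append(
                    AnnotationCandidate(
                        precursor_mz=precursor_mz,
                        core=core.name,
                        substituents=multiset,
                        formula=formula,
                        theoretical_mz=theo,
                        ppm=ppm,
                    )
                )
    candidates.sort(key=lambda c: (abs(c.ppm), c.core, c.substituents))
    return candidates


def _line_distance(integer: int, decimal: float) -> float:
    """Signed perpendicular distance from (x, y) to y = slope * x."""
    s = CH2_LINE_SLOPE
    return (decimal - s * integer) / (1.0 + s * s) ** 0.5


def ch2_cluster(
    residuals: Sequence[float],
    distance_tol: float = 0.001,
    diff_tol: float = 0.005,
) -> list[HomologSeries]:
    """Group residual masses into CH2 homologous series.

    Two residuals belong to the same series when their exact mass
    difference is within ``diff_tol`` of an integer multiple of 14.01565
    (the authoritative test, robust to the decimal wrapping past 1.0) and,
    whenever no wrap occurred, their signed distances to the CH2 reference
    line agree within ``distance_tol``.  Grouping is transitive
    (union-find), so chains of CH2 steps form one series.
    """
    n = len(residuals)
    for r in residuals:
        if r < 0:
            raise ValueError(f"residual masses must be non-negative, got {r}")
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    splits = [split_mass(r) for r in residuals]
    dists = [_line_distance(sp.integer_part, sp.decimal_part) for sp in splits]
    for i in range(n):
        for j in range(i + 1, n):
            delta = abs(residuals[i] - residuals[j])
            k = round(delta / CH2_MASS)
            if k == 0 and i != j and delta > diff_tol:
                continue
            if abs(delta - k * CH2_MASS) > diff_tol:
                continue
            int_diff = abs(splits[i].integer_part - splits[j].integer_part)
            if int_diff % 14 == 0:
                # no decimal wrap: the plane distances must agree too
                if abs(dists[i] - dists[j]) > distance_tol + 1e-12:
                    continue
            union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    series: list[HomologSeries] = []
    for sid, members in enumerate(sorted(groups.values(), key=lambda g: min(residuals[i] for i in g))):
        ordered = sorted(members, key=lambda i: residuals[i])
        series.append(
            HomologSeries(
                series_id=sid,
                members=tuple(residuals[i] for i in ordered),
                points=tuple((splits[i].integer_part, splits[i].decimal_part) for i in ordered),
                line_distance=sum(dists[i] for i in ordered) / len(ordered),
            )
        )
    return series


# ----------------------------------------------------------------------
# optional PubChem lookup (offline-first)

_PUBCHEM_URL = (
    "https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/fastformula/{formula}/"
    "property/Title,MolecularWeight,CanonicalSMILES/JSON"
)


@dataclass
class FormulaLookup:
    """Compound-database lookup by molecular formula with a local cache.

    ``online=False`` (the default) never touches the network and returns
    an empty record list with status ``"offline"``.  Online failures
    degrade to the offline result rather than aborting a run.
    """

    online: bool = False
    cache_path: Path | None = None
    min_interval_s: float = 0.25
    _cache: dict[str, list[dict]] = field(default_factory=dict)
    _last_call: float = 0.0

    def __post_init__(self) -> None:
        if self.cache_path and Path(self.cache_path).exists():
            self._cache = json.loads(Path(self.cache_path).read_text())

    def lookup(self, formula: ElementalFormula | str) -> tuple[list[dict], str]:
        if isinstance(formula, str):
            formula = parse_formula(formula)  # raises on malformed input
        key = formula.hill()
        if key in self._cache:
            return self._cache[key], "cached"
        if not self.online:
            return [], "offline"
        wait = self.min_interval_s - (time.monotonic() - self._last_call)
        if wait > 0:
            time.sleep(wait)
        try:
            url = _PUBCHEM_URL.format(formula=urllib.parse.quote(key))
            with urllib.request.urlopen(url, timeout=10) as resp:
                payload = json.loads(resp.read().decode())
            self._last_call = time.monotonic()
            records = [
                {
                    "name": p.get("Title"),
                    "molecular_weight": p.get("MolecularWeight"),
                    "smiles": p.get("CanonicalSMILES"),
                }
                for p in payload.get("PropertyTable", {}).get("Properties", [])
            ]
        except Exception as exc:  # pragma: no cover - network path
            logger.warning("formula lookup failed (%s); continuing offline", exc)
            return [], "offline"
        self._cache[key] = records
        if self.cache_path:
            Path(self.cache_path).write_text(json.dumps(self._cache))
        return records, "online"


def lookup_formula(
    formula: ElementalFormula | str, client: FormulaLookup | None = None
) -> tuple[list[dict], str]:
    """Module-level convenience around :class:`FormulaLookup` (offline by
    default)."""
    client = client or FormulaLookup(online=False)
    return client.lookup(formula)
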