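"""Readers and writers for MGF spectra, feature tables and screen reports.

The MGF dialect accepted here is the one emitted by MZmine-style feature
finders: ``BEGIN IONS`` / ``END IONS`` blocks with ``TITLE``, ``PEPMASS``,
``RTINSECONDS``, ``CHARGE`` (``1-`` style) and optionally ``FEATURE_ID``
headers, followed by ``m/z intensity`` peak lines.  Retention times are
stored internally in minutes.

Feature quantification tables are plain CSV with at least an id, an m/z
and an RT column; header names are remappable so alternate export dialects
load without editing the file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentPeak",
    "Ms2Spectrum",
    "FeatureRecord",
    "MgfError",
    "read_mgf",
    "write_mgf",
    "read_feature_table",
    "write_screen_report",
    "link_spectra_to_features",
]


class MgfError(ValueError):
    """Raised for malformed MGF blocks."""


@dataclass(frozen=True)
class FragmentPeak:
    mz: float
    intensity: float
    relative_abundance: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"fragment m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be non-negative, got {self.intensity}")


@dataclass(frozen=True)
class Ms2Spectrum:
    """One MS/MS spectrum: precursor plus fragment peak list.

    Peaks are kept sorted ascending by m/z.  ``relative_abundance`` on the
    peaks is filled by base-peak normalization (see ``normalize``).
    """

    spectrum_id: str
    precursor_mz: float
    rt_min: float
    charge: int = -1
    peaks: tuple[FragmentPeak, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor m/z must be positive, got {self.precursor_mz}")
        ordered = tuple(sorted(self.peaks, key=lambda p: p.mz))
        object.__setattr__(self, "peaks", ordered)

    def normalize(self) -> "Ms2Spectrum":
        """Return a copy with relative abundances = intensity / base peak."""
        if not self.peaks:
            raise ValueError(f"spectrum {self.spectrum_id!r} has no peaks to normalize")
        base = max(p.intensity for p in self.peaks)
        if base == 0:
            norm = tuple(replace(p, relative_abundance=1.0) for p in self.peaks)
        else:
            norm = tuple(
                replace(p, relative_abundance=p.intensity / base) for p in self.peaks
            )
        return replace(self, peaks=norm)


@dataclass(frozen=True)
class FeatureRecord:
    feature_id: str
    mz: float
    rt_min: float
    abundance: float = 0.0


def _parse_charge(text: str) -> int:
    text = text.strip()
    if text.endswith("-"):
        return -int(text[:-1] or 1)
    if text.endswith("+"):
        return int(text[:-1] or 1)
    return int(text)


def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    """Parse an MGF file into a list of spectra.

    Blocks without a parseable PEPMASS are skipped with a warning counted
    in the log; structurally malformed blocks raise :class:`MgfError`
    naming the block index.
    """
    path = Path(path)
    spectra: list[Ms2Spectrum] = []
    block: dict[str, str] | None = None
    peaks: list[FragmentPeak] = []
    block_index = 0
    skipped = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if block is not None:
                    raise MgfError(f"block {block_index}: nested BEGIN IONS at line {lineno}")
                block_index += 1
                block, peaks = {}, []
            elif line == "END IONS":
                if block is None:
                    raise MgfError(f"stray END IONS at line {lineno}")
                spec = _finish_block(block, peaks, block_index)
                if spec is None:
                    skipped += 1
                else:
                    spectra.append(spec)
                block = None
            elif block is None:
                continue  # tolerate global headers outside blocks
            elif "=" in line:
                key, value = line.split("=", 1)
                block[key.strip().upper()] = value.strip()
            else:
                cols = line.split()
                if len(cols) < 2:
                    raise MgfError(
                        f"block {block_index}: malformed peak line {line!r} at line {lineno}"
                    )
                try:
                    peaks.append(FragmentPeak(mz=float(cols[0]), intensity=float(cols[1])))
                except ValueError as exc:
                    raise MgfError(
                        f"block {block_index}: bad peak values at line {lineno}: {exc}"
                    ) from exc
    if block is not None:
        raise MgfError(f"block {block_index}: unterminated BEGIN IONS block")
    if skipped:
        logger.warning("read_mgf(%s): skipped %d block(s) without precursor mass", path, skipped)
    return spectra


def _finish_block(
    headers: Mapping[str, str], peaks: list[FragmentPeak], index: int
) -> Ms2Spectrum | None:
    pepmass = headers.get("PEPMASS")
    if pepmass is None:
        return None
    try:
        precursor_mz = float(pepmass.split()[0])
    except ValueError:
        return None
    spectrum_id = headers.get("FEATURE_ID") or headers.get("TITLE") or f"scan_{index}"
    rt_min = 0.0
    if "RTINSECONDS" in headers:
        rt_min = float(headers["RTINSECONDS"]) / 60.0
    elif "RTINMINUTES" in headers:
        rt_min = float(headers["RTINMINUTES"])
    charge = -1
    if "CHARGE" in headers:
        try:
            charge = _parse_charge(headers["CHARGE"])
        except ValueError as exc:
            raise MgfError(f"block {index}: bad CHARGE {headers['CHARGE']!r}") from exc
    return Ms2Spectrum(
        spectrum_id=str(spectrum_id),
        precursor_mz=precursor_mz,
        rt_min=rt_min,
        charge=charge,
        peaks=tuple(peaks),
    )


def write_mgf(spectra: Iterable[Ms2Spectrum], path: str | Path) -> Path:
    """Write spectra as MGF; inverse of :func:`read_mgf` within tolerance."""
    path = Path(path)
    with path.open("w") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"FEATURE_ID={spec.spectrum_id}\n")
            fh.write(f"TITLE={spec.spectrum_id}\n")
            fh.write(f"PEPMASS={spec.precursor_mz:.4f}\n")
            fh.write(f"RTINSECONDS={spec.rt_min * 60.0:.3f}\n")
            sign = "-" if spec.charge < 0 else "+"
            fh.write(f"CHARGE={abs(spec.charge)}{sign}\n")
            for p in spec.peaks:
                fh.write(f"{p.mz:.4f} {p.intensity:.3f}\n")
            fh.write("END IONS\n")
    return path


DEFAULT_COLUMN_MAP = {
    "feature_id": ("id", "row id", "feature_id", "row_id"),
    "mz": ("mz", "m/z", "row m/z", "row mz"),
    "rt_min": ("rt", "rt_min", "row retention time", "retention time"),
    "abundance": ("area", "height", "abundance", "intensity"),
}


def read_feature_table(
    path: str | Path,
    column_map: Mapping[str, Sequence[str]] | None = None,
) -> list[FeatureRecord]:
    """Load an aligned feature quantification table (CSV).

    ``column_map`` maps the canonical field names (feature_id, mz, rt_min,
    abundance) to acceptable header aliases, letting alternate CSV dialects
    load unchanged.  Rows whose m/z or RT fail to parse are dropped with a
    logged count; duplicate feature ids are an error.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update({k: tuple(v) for k, v in column_map.items()})
    df = pd.read_csv(path)
    lowered = {c.lower().strip(): c for c in df.columns}

    def find(fieldname: str, required: bool) -> str | None:
        for alias in cmap[fieldname]:
            if alias.lower() in lowered:
                return lowered[alias.lower()]
        if required:
            raise ValueError(
                f"feature table {path} is missing a {fieldname!r} column "
                f"(accepted aliases: {cmap[fieldname]})"
            )
        return None

    id_col = find("feature_id", required=True)
    mz_col = find("mz", required=True)
    rt_col = find("rt_min", required=True)
    ab_col = find("abundance", required=False)

    ids_raw = df[id_col].tolist()
    mzs = pd.to_numeric(df[mz_col], errors="coerce")
    rts = pd.to_numeric(df[rt_col], errors="coerce")
    abundances = (
        pd.to_numeric(df[ab_col], errors="coerce").fillna(0.0)
        if ab_col is not None
        else pd.Series(0.0, index=df.index)
    )
    records: list[FeatureRecord] = []
    dropped = 0
    for fid, mz, rt, ab in zip(ids_raw, mzs, rts, abundances):
        if pd.isna(mz) or pd.isna(rt):
            dropped += 1
            continue
        records.append(
            FeatureRecord(feature_id=str(fid), mz=float(mz), rt_min=float(rt), abundance=float(ab))
        )
    if dropped:
        logger.warning("read_feature_table(%s): dropped %d unparseable row(s)", path, dropped)
    ids = [r.feature_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate feature ids in {path}: {dupes}")
    return records


def write_screen_report(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    fmt: str = "csv",
    ion_labels: Sequence[str] | None = None,
) -> Path:
    """Write screening hits with one (matched m/z, relative abundance)
    column pair per diagnostic ion, then the score.

    ``rows`` are mappings as produced by ``diagnostic screening``:
    spectrum_id, precursor_mz, charge, rt_min, matched (label -> (mz, ra))
    and score.  ``ion_labels`` fixes column order; by default the union of
    matched labels in first-seen order.
    """
    path = Path(path)
    if ion_labels is None:
        seen: list[str] = []
        for row in rows:
            for label in row.get("matched", {}):  # type: ignore[union-attr]
                if label not in seen:
                    seen.append(label)
        ion_labels = seen
    columns = ["spectrum_id", "precursor_mz", "charge", "rt_min"]
    for label in ion_labels:
        columns += [f"{label}_mz", f"{label}_abundance"]
    columns.append("score")

    table: list[dict[str, object]] = []
    for row in rows:
        out: dict[str, object] = {
            "spectrum_id": row["spectrum_id"],
            "precursor_mz": round(float(row["precursor_mz"]), 4),
            "charge": row["charge"],
            "rt_min": round(float(row["rt_min"]), 3),
            "score": row["score"],
        }
        matched: Mapping[str, tuple[float, float]] = row.get("matched", {})  # type: ignore[assignment]
        for label in ion_labels:
            if label in matched:
                mz, ra = matched[label]
                out[f"{label}_mz"] = round(mz, 4)
                out[f"{label}_abundance"] = round(ra, 4)
            else:
                out[f"{label}_mz"] = ""
                out[f"{label}_abundance"] = ""
        table.append(out)
    df = pd.DataFrame(table, columns=columns)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise ValueError(f"unsupported report format {fmt!r} (use 'csv' or 'xlsx')")
    return path


def link_spectra_to_features(
    spectra: Sequence[Ms2Spectrum],
    features: Sequence[FeatureRecord],
    mz_tol: float = 0.01,
    rt_tol_min: float = 0.1,
) -> dict[str, FeatureRecord]:
    """Join spectra to feature rows.

    The key is the spectrum id when it equals a feature id; otherwise the
    nearest feature within ``mz_tol`` Da and ``rt_tol_min`` minutes, ties
    resolved to the closest m/z.  Returns spectrum_id -> FeatureRecord for
    every spectrum that linked.
    """
    by_id = {f.feature_id: f for f in features}
    links: dict[str, FeatureRecord] = {}
    for spec in spectra:
        if spec.spectrum_id in by_id:
            links[spec.spectrum_id] = by_id[spec.spectrum_id]
            continue
        candidates = [
            f
            for f in features
            if abs(f.mz - spec.precursor_mz) <= mz_tol
            and abs(f.rt_min - spec.rt_min) <= rt_tol_min
        ]
        if candidates:
            best = min(candidates, key=lambda f: abs(f.mz - spec.precursor_mz))
            links[spec.spectrum_id] = best
    return links
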